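#!/usr/bin/env python
"""Drought and recovery contrasts on organic-N process rates.

Summarizes the seasonwise two-way ANOVAs (climate scenario x drought) and
the Tukey compact-letter displays from the statistics stage: the May
sampling is the pre-drought control, July the peak-drought contrast, and
October the post-rewetting recovery.
"""

from pathlib import Path

import pandas as pd

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    anova = pd.read_csv(OUTDIR / "anova.csv")
    tukey = pd.read_csv(OUTDIR / "tukey.csv")
    dep = anova[(anova.response == "depolymerization")
                & (anova.term == "drought")]
    print("drought main effect on depolymerization, by season:")
    for row in dep.itertuples():
        print(f"  {row.season}: F={row.F:.2f}, p={row.p:.4g}")

    jul = tukey[(tukey.response == "depolymerization")
                & (tukey.season == "Jul")]
    print("\nJuly group means with Tukey letters:")
    for row in jul.itertuples():
        print(f"  {row.group:18s} {row.mean:7.1f} ug N g-1 dm d-1  {row.letters}")

    jul_means = jul.set_index("group")["mean"]
    for climate in ("ambient", "future"):
        ctrl = jul_means[f"{climate}/control"]
        dr = jul_means[f"{climate}/drought"]
        print(f"{climate}: drought changed depolymerization by "
              f"{100 * (dr / ctrl - 1):+.0f}%")


if __name__ == "__main__":
    main()
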