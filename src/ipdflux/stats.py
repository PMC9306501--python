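"""Inference chain: GLS reduction, seasonwise ANOVA + Tukey HSD, rmcorr.

Four pieces sit on top of :mod:`ipdflux.gls`:

* backward model reduction under the marginality principle;
* seasonwise two-way ANOVA (Type-II sums of squares) with Tukey–Kramer
  pairwise contrasts and a compact letter display;
* repeated-measures correlation (the common within-subject correlation,
  estimated by subject-mean centering / ANCOVA adjustment) with parametric
  and subject-resampling bootstrap p-values;
* Shapiro–Wilk / Levene assumption checks (advisory flags only).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .gls import (  # noqa: F401  (re-exported surface)
    ALL_TERMS,
    ModelFitResult,
    ModelSpec,
    TERM_PARENTS,
    fit_gls,
    is_marginality_closed,
    marginality_closure,
)

#: responses the analysis log-transforms by default before modeling
DEFAULT_LOG_RESPONSES = frozenset(
    {"gross_mineralization", "faa_pool", "mean_residence_time_h"}
)


def default_transform(response: str) -> str:
    return "log" if response in DEFAULT_LOG_RESPONSES else "none"


def fit_rs_gls(
    df: pd.DataFrame, spec: ModelSpec, reml: bool = True, **kwargs
) -> ModelFitResult:
    """Fit the quadratic response-surface GLS model (see :func:`ipdflux.gls.fit_gls`)."""
    return fit_gls(df, spec, reml=reml, **kwargs)


def reduce_by_marginality(
    df: pd.DataFrame,
    spec: ModelSpec,
    alpha: float | None = None,
    reml: bool = True,
) -> ModelFitResult:
    """Backward-eliminate nonsignificant terms respecting marginality.

    At each step, only terms with no retained higher-order term may be
    dropped; among those with p > alpha the one with the largest p is removed
    and the model refit.  The full trail of (dropped term, F, p) is recorded
    on the returned fit.
    """
    alpha = spec.alpha if alpha is None else alpha
    terms = list(spec.terms)
    trail: list[dict] = []
    fit = fit_rs_gls(df, spec, reml=reml)
    while True:
        current = set(terms)
        removable = [
            t for t in terms
            if not any(t in marginality_closure({o}) - {o} for o in current)
        ]
        candidates = [
            (fit.term_p(t), t) for t in removable if fit.term_p(t) > alpha
        ]
        if not candidates:
            break
        p_drop, term_drop = max(candidates)
        row = fit.anova[fit.anova.term == term_drop].iloc[0]
        trail.append(
            {"term": term_drop, "F": float(row.F), "p": float(row.p)}
        )
        terms.remove(term_drop)
        new_spec = ModelSpec(
            response=spec.response,
            terms=tuple(terms),
            transform=spec.transform,
            alpha=spec.alpha,
            subject=spec.subject,
            season_col=spec.season_col,
            temp_col=spec.temp_col,
            co2_col=spec.co2_col,
        )
        fit = fit_rs_gls(df, new_spec, reml=reml)
    fit.reduction_trail = trail
    return fit


# ---------------------------------------------------------------------------
# Seasonwise ANOVA + Tukey

def two_way_anova(
    df: pd.DataFrame, response: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Two-way ANOVA with interaction, Type-II sums of squares.

    Returns a tidy table (term, sum_sq, df, F, p).  With balanced cells
    Type II coincides with Type I/III.
    """
    model = smf.ols(
        f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))",
        data=df.dropna(subset=[response]),
    ).fit()
    table = sm.stats.anova_lm(model, typ=2).reset_index()
    table.columns = ["term", "sum_sq", "df", "F", "p"]
    rename = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": f"{factor_a}:{factor_b}",
    }
    table["term"] = table["term"].map(lambda t: rename.get(t, t))
    return table


def compact_letter_display(
    levels, pvalues: dict[tuple, float], means: dict, alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display: levels share a letter iff not significantly
    different (adjusted p ≥ alpha).

    Implemented as the maximal cliques of the nonsignificance graph; cliques
    are lettered in descending order of their mean response.
    """
    g = nx.Graph()
    g.add_nodes_from(levels)
    for (a, b), p in pvalues.items():
        if p >= alpha:
            g.add_edge(a, b)
    cliques = sorted(
        nx.find_cliques(g),
        key=lambda c: -float(np.mean([means[l] for l in c])),
    )
    letters: dict[str, list[str]] = {l: [] for l in levels}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for level in clique:
            letters[level].append(letter)
    return {l: "".join(sorted(v)) for l, v in letters.items()}


@dataclass
class TukeyResult:
    contrasts: pd.DataFrame  # group1, group2, meandiff, p_adj, lower, upper, reject
    letters: dict[str, str]
    group_means: dict[str, float]
    alpha: float


def tukey_hsd(
    df: pd.DataFrame, response: str, group_col: str, alpha: float = 0.05
) -> TukeyResult:
    """Tukey–Kramer all-pairs comparison with a compact letter display."""
    res = pairwise_tukeyhsd(
        df[response].to_numpy(float), df[group_col].astype(str), alpha=alpha
    )
    contrasts = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    )
    contrasts = contrasts.rename(columns={"p-adj": "p_adj"})
    contrasts["p_adj"] = res.pvalues
    means = df.groupby(group_col)[response].mean().to_dict()
    pvals = {
        (row.group1, row.group2): float(row.p_adj)
        for row in contrasts.itertuples()
    }
    letters = compact_letter_display(
        sorted(means), pvals, means, alpha=alpha
    )
    return TukeyResult(
        contrasts=contrasts, letters=letters, group_means=means, alpha=alpha
    )


# ---------------------------------------------------------------------------
# Repeated-measures correlation

@dataclass
class RmCorrResult:
    """Common within-subject correlation with parametric and bootstrap p."""

    r: float
    df: int
    p: float
    ci: tuple[float, float]
    p_boot: float | None
    n_obs: int
    n_subjects: int
    flags: tuple[str, ...] = field(default_factory=tuple)


def _centered(df: pd.DataFrame, subject: str, x: str, y: str):
    gx = df.groupby(subject)[x].transform("mean")
    gy = df.groupby(subject)[y].transform("mean")
    return (df[x] - gx).to_numpy(float), (df[y] - gy).to_numpy(float)


def _rm_r(df: pd.DataFrame, subject: str, x: str, y: str) -> float:
    cx, cy = _centered(df, subject, x, y)
    sx = float(np.sqrt(np.sum(cx * cx)))
    sy = float(np.sqrt(np.sum(cy * cy)))
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.sum(cx * cy) / (sx * sy))


def rmcorr(
    df: pd.DataFrame,
    subject: str,
    x: str,
    y: str,
    n_boot: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> RmCorrResult:
    """Repeated-measures correlation (ANCOVA / subject-mean-centering form).

    r_rm is the Pearson correlation of the within-subject centered x and y;
    the error df is N − k − 1 for N observations on k subjects, matching the
    ANCOVA with subject as a categorical covariate.  The parametric p comes
    from t(df); the bootstrap p resamples subjects with replacement (two-
    sided sign test of the bootstrap distribution against zero).

    Subjects with fewer than 2 complete observations are excluded with a
    warning; zero within-subject variance yields an undefined-result flag.
    """
    data = df[[subject, x, y]].dropna()
    counts = data.groupby(subject).size()
    bad = counts[counts < 2].index
    flags: list[str] = []
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} subject(s) with < 2 observations: "
            f"{sorted(map(str, bad))}"
        )
        data = data[~data[subject].isin(bad)]
        flags.append("SUBJECTS_EXCLUDED")
    n = len(data)
    k = data[subject].nunique()
    dof = n - k - 1
    if dof < 1:
        raise ValueError(f"not enough error df (N={n}, k={k})")

    r = _rm_r(data, subject, x, y)
    if np.isnan(r):
        flags.append("ZERO_WITHIN_SUBJECT_VARIANCE")
        return RmCorrResult(
            r=np.nan, df=dof, p=np.nan, ci=(np.nan, np.nan), p_boot=None,
            n_obs=n, n_subjects=k, flags=tuple(flags),
        )

    with np.errstate(divide="ignore"):
        t_stat = r * np.sqrt(dof / max(1e-300, 1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t_stat), dof))

    # Fisher-z interval with the rmcorr error df
    zcrit = sps.norm.ppf(1 - alpha / 2)
    se = 1.0 / np.sqrt(max(dof - 1, 1))
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    ci = (float(np.tanh(zr - zcrit * se)), float(np.tanh(zr + zcrit * se)))

    p_boot = None
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        subjects = data[subject].unique()
        groups = {s: g[[x, y]].to_numpy(float) for s, g in data.groupby(subject)}
        boot = np.empty(n_boot)
        for b in range(n_boot):
            chosen = rng.choice(subjects, size=len(subjects), replace=True)
            cx_parts, cy_parts = [], []
            for sub in chosen:
                arr = groups[sub]
                cx_parts.append(arr[:, 0] - arr[:, 0].mean())
                cy_parts.append(arr[:, 1] - arr[:, 1].mean())
            cx = np.concatenate(cx_parts)
            cy = np.concatenate(cy_parts)
            sx = np.sqrt(np.sum(cx * cx))
            sy = np.sqrt(np.sum(cy * cy))
            boot[b] = np.sum(cx * cy) / (sx * sy) if sx > 0 and sy > 0 else np.nan
        boot = boot[~np.isnan(boot)]
        if len(boot):
            frac_le = float(np.mean(boot <= 0))
            frac_ge = float(np.mean(boot >= 0))
            p_boot = min(1.0, 2.0 * min(frac_le, frac_ge))

    return RmCorrResult(
        r=float(r), df=dof, p=p, ci=ci, p_boot=p_boot,
        n_obs=n, n_subjects=k, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Assumption checks

def assumption_checks(
    residuals, groups=None, alpha: float = 0.05
) -> dict[str, float | bool]:
    """Shapiro–Wilk normality and (if groups given) Levene homoscedasticity.

    Advisory only: returns statistics, p-values, and boolean violation flags;
    never transforms data.
    """
    residuals = np.asarray(residuals, float)
    sw_stat, sw_p = sps.shapiro(residuals)
    out: dict[str, float | bool] = {
        "shapiro_stat": float(sw_stat),
        "shapiro_p": float(sw_p),
        "normality_violation": bool(sw_p < alpha),
    }
    if groups is not None:
        groups = np.asarray(groups)
        samples = [residuals[groups == g] for g in np.unique(groups)]
        lev_stat, lev_p = sps.levene(*samples, center="median")
        out.update(
            levene_stat=float(lev_stat),
            levene_p=float(lev_p),
            homoscedasticity_violation=bool(lev_p < alpha),
        )
    return out
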