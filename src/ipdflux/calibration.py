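"""Assay calibration: raw fluorimetric/colorimetric signals to soil pools.

Free amino acids are quantified fluorimetrically (OPAME derivatization) and
ammonium colorimetrically in the same 1 M KCl extracts.  The pipeline from a
raw plate signal to a dry-mass-normalized pool concentration is:

    blank subtraction -> ammonium-fluorescence interference correction
    -> quench (spike-recovery) correction -> calibration inverse prediction
    -> extract-to-soil mass balance on a dry-mass basis

Each step is a pure function; :func:`process_batch` applies them in the
documented order to a batch table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line of blank-corrected signal on standard concentration."""

    standard_concentrations: tuple[float, ...]
    signals: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float
    blank_signal: float = 0.0

    def predict_signal(self, concentration):
        return self.intercept + self.slope * np.asarray(concentration, float)

    def predict_concentration(self, signal):
        """Inverse prediction: concentration from a blank-corrected signal."""
        return (np.asarray(signal, float) - self.intercept) / self.slope


@dataclass(frozen=True)
class ExtractRecord:
    """Extraction metadata for one soil sample.

    fresh_mass in g, extract_volume in ml, fw_dw_ratio = fresh/dry mass (>1
    for moist soil), spike_recovery dimensionless (signal recovered / signal
    expected for the spiking standard).
    """

    fresh_mass_g: float
    extract_volume_ml: float
    fw_dw_ratio: float
    spike_recovery: float = 1.0
    qc_warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("fresh_mass_g", "extract_volume_ml", "fw_dw_ratio"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.spike_recovery > 0:
            raise ValueError("spike_recovery must be > 0")
        if not 0.5 < self.spike_recovery < 1.5:
            object.__setattr__(
                self,
                "qc_warnings",
                self.qc_warnings + ("SPIKE_RECOVERY_OUT_OF_RANGE",),
            )

    @property
    def dry_mass_g(self) -> float:
        return self.fresh_mass_g / self.fw_dw_ratio


def fit_linear_calibration(
    standard_concentrations,
    signals,
    blank_signal: float = 0.0,
) -> CalibrationCurve:
    """Fit the calibration line (OLS of blank-corrected signal on conc).

    Requires at least three distinct standard levels with nonzero spread.
    """
    conc = np.asarray(standard_concentrations, float)
    sig = np.asarray(signals, float) - blank_signal
    if conc.shape != sig.shape:
        raise ValueError("standards and signals must have equal length")
    if len(np.unique(conc)) < 3:
        raise ValueError("need >= 3 distinct standard concentration levels")
    if np.ptp(conc) == 0:
        raise ValueError("standards have zero concentration spread")
    res = sps.linregress(conc, sig)
    if not res.slope > 0:
        raise ValueError(f"calibration slope must be > 0, got {res.slope:.4g}")
    return CalibrationCurve(
        standard_concentrations=tuple(conc),
        signals=tuple(sig),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        blank_signal=blank_signal,
    )


def quench_correction(measured, spike_measured, spike_expected):
    """Rescale a signal by the spike recovery (measured/expected spike).

    Fluorescence quenching by the soil matrix attenuates all signals in a
    sample proportionally; dividing by the recovery of a known spiking
    standard undoes it.
    """
    spike_expected = np.asarray(spike_expected, float)
    if np.any(spike_expected <= 0):
        raise ValueError("spike_expected must be > 0")
    recovery = np.asarray(spike_measured, float) / spike_expected
    if np.any(recovery <= 0):
        raise ValueError("spike recovery must be > 0")
    return np.asarray(measured, float) / recovery


def ammonium_interference_correction(
    faa_signal, nh4_concentration, nh4_response_slope
):
    """Subtract the ammonium contribution from an amino-acid fluorescence signal.

    ``nh4_response_slope`` (signal per unit NH4 concentration) is a per-batch
    calibration input.  Negative corrected signals are floored at 0 and
    flagged; returns ``(corrected, floored_mask)``.
    """
    slope = np.asarray(nh4_response_slope, float)
    if np.any(slope < 0):
        raise ValueError("nh4_response_slope must be >= 0")
    corrected = np.asarray(faa_signal, float) - np.asarray(
        nh4_concentration, float
    ) * slope
    floored = corrected < 0
    return np.where(floored, 0.0, corrected), floored


def to_dry_mass(extract_concentration, record: ExtractRecord):
    """Convert an extract concentration (µg ml⁻¹) to µg N g⁻¹ dry mass.

    Mass balance: total analyte = conc × extract volume, normalized by the
    dry mass of the extracted aliquot (fresh mass / fw:dw ratio).
    """
    conc = np.asarray(extract_concentration, float)
    if np.any(conc < 0):
        raise ValueError("extract_concentration must be >= 0")
    return conc * record.extract_volume_ml / record.dry_mass_g


def process_batch(
    batch: pd.DataFrame,
    curve: CalibrationCurve,
    nh4_response_slope: float = 0.0,
    spike_expected: float | None = None,
) -> pd.DataFrame:
    """Run the full documented correction chain on a batch table.

    ``batch`` columns: sample_id, raw_signal, nh4_concentration (extract
    units), spike_measured (optional), fresh_mass_g, extract_volume_ml,
    fw_dw_ratio.  Returns a tidy table with the blank-corrected, interference-
    corrected, quench-corrected signal, the extract concentration, and the
    dry-mass pool concentration.
    """
    out = batch.copy()
    signal = out["raw_signal"].to_numpy(float) - curve.blank_signal
    signal, floored = ammonium_interference_correction(
        signal, out["nh4_concentration"].to_numpy(float), nh4_response_slope
    )
    if spike_expected is not None and "spike_measured" in out:
        signal = quench_correction(
            signal, out["spike_measured"].to_numpy(float), spike_expected
        )
    extract_conc = curve.predict_concentration(signal)
    dm = []
    warnings = []
    for i, row in enumerate(out.itertuples()):
        rec = ExtractRecord(
            fresh_mass_g=row.fresh_mass_g,
            extract_volume_ml=row.extract_volume_ml,
            fw_dw_ratio=row.fw_dw_ratio,
            spike_recovery=(
                row.spike_measured / spike_expected
                if spike_expected is not None and hasattr(row, "spike_measured")
                else 1.0
            ),
        )
        dm.append(float(to_dry_mass(max(extract_conc[i], 0.0), rec)))
        flags = list(rec.qc_warnings)
        if floored[i]:
            flags.append("SIGNAL_FLOORED_AT_ZERO")
        warnings.append(";".join(flags))
    out["corrected_signal"] = signal
    out["extract_conc"] = extract_conc
    out["conc_ugN_per_gdm"] = dm
    out["qc_warnings"] = warnings
    return out
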