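# ipdflux

Gross soil nitrogen fluxes by ¹⁵N isotope pool dilution, and the inference
chain of a multifactor (warming × CO₂ × drought) grassland experiment —
estimators, assay calibration, experimental layout, a calibrated
synthetic-data generator, and the downstream statistics, as one tested
pipeline.

## The scientific problem

Most soil nitrogen is locked in high-molecular-weight organic polymers
(largely proteins). The step that makes it bioavailable — enzymatic
**protein depolymerization** to free amino acids (FAA) — is the bottleneck
of the soil N cycle, yet net concentration changes cannot reveal it: the
FAA pool turns over in hours, with large gross fluxes in and out that
nearly cancel. **Isotope pool dilution (IPD)** solves this by spiking the
pool with a highly ¹⁵N-enriched tracer and following the *dilution of the
enrichment* between two stop times: influx at natural abundance dilutes the
label, efflux removes it at the pool's current enrichment.

This package is for soil biogeochemists and biostatisticians who run
two-timepoint IPD assays (free amino acids, ammonium, nitrate) and analyze
them on multi-level climate-manipulation designs: it implements the flux
estimators and their exact forward model, the signal-to-concentration
calibration chain, the 3 × 3 temperature × CO₂ response-surface layout with
a drought subset, and the repeated-measures statistics, plus a synthetic
generator that emulates the whole study so every stage is testable without
field data.

## The estimators

With pool concentrations C (µg N g⁻¹ dry mass) and atom% excesses
APE = atom%¹⁵N − background at stop times t₁ < t₂ (Δt in days), the
isotope-mass-balance (Kirkham–Bartholomew) estimators under zero-order
kinetics are

    GI = (C₂ − C₁)/Δt · ln(APE₁/APE₂) / ln(C₂/C₁)          (gross influx)
    GE = (C₁ − C₂)/Δt · [1 + ln(APE₂/APE₁) / ln(C₂/C₁)]     (gross efflux)

which always satisfy GI − GE = ΔC/Δt and exactly invert the zero-order
forward model (implemented in `simulate_ipd`, with a numeric ODE oracle in
the tests). Near C₂ = C₁ the implementation switches to the analytic
constant-pool limit; GI is evaluated through the logarithmic-mean form,
which is algebraically identical and numerically stable. The amino-acid
**mean residence time** is

    MRT (h) = pool size / [(GI + GE)/2] · 24.

Downstream, treatment effects are inferred with a quadratic response-surface
GLS (compound symmetry across seasons within plot, season-specific
variances, backward reduction under the marginality principle), seasonwise
two-way ANOVAs with Tukey HSD letters for the drought contrast, and
repeated-measures correlations (ANCOVA / within-plot centering) with
bootstrap p-values.

## Worked example

```python
from ipdflux import IPDPair, PoolMeasurement, gross_rates, mean_residence_time

pair = IPDPair(
    PoolMeasurement("FAA", 15, 5.0, 10.0),   # t=15 min: 5.0 µg N/g, 10 atom%
    PoolMeasurement("FAA", 60, 4.5, 8.0),    # t=60 min: 4.5 µg N/g, 8 atom%
    background_atom_pct=0.0,
)
r = gross_rates(pair)
print(round(r.gross_influx, 3), round(r.gross_efflux, 3))
print(round(mean_residence_time(4.75, r.gross_influx, r.gross_efflux), 3))
```

prints `33.886 49.886` and `2.722`: the pool shrank by 0.5 µg N g⁻¹ in
45 min while its enrichment fell from 10 to 8 atom%, which is only possible
if 33.9 µg N g⁻¹ d⁻¹ entered at natural abundance while 49.9 left — a mean
residence time of 2.7 h for a 4.75 µg N g⁻¹ pool.

The full study emulation runs as numbered drivers (or `ipdflux all`):

```bash
python analysis/01_generate_dataset.py   # design + synthetic measurements
python analysis/02_estimate_rates.py     # gross fluxes per plot x season
python analysis/03_response_surface_gls.py
python analysis/04_drought_contrasts.py
python analysis/05_depolymerization_correlates.py
```

`02` prints seasonal mean depolymerization of 96.9 / 70.1 / 55.8
µg N g⁻¹ dm d⁻¹ (May/Jul/Oct, drought plots included) with residence times
around 2–2.6 h; `03` retains a strong season × temperature interaction for
depolymerization (F = 11.6, p < 0.0001: warming lowers spring rates and
raises autumn rates); `04` shows the July drought contrast (F = 29.8,
p = 0.0003, drought plots carrying distinct Tukey letters, roughly a
doubling of rates); `05` reports the within-plot correlation of
depolymerization with soil water content (r_rm = −0.71) and ANPP.
Tables land under `results/run/`.

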