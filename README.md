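# stratext

Quantitative extinction dynamics for bed-resolved stratigraphic sections.

`stratext` is for paleobiologists working with sections like Meishan
(Zhejiang, China), where every bed and sub-bed is numbered and decades of
fossil occurrence records and geochemical proxy measurements can be placed on
one stratigraphic grid. It answers two questions statistically rather than by
eye:

1. **What is the shape of an extinction event?** A single pulse, several
   pulses, or a continuous interval of loss — inferred from last appearance
   data (LADs) while accounting for the Signor–Lipps effect (incomplete
   sampling drags observed LADs below true extinction horizons).
2. **Which environmental changes track the biodiversity loss?** State shifts
   in geochemical proxies (δ¹⁸O_apatite, δ¹¹⁴/¹¹⁰Cd, δ¹³C_carb, iron
   speciation, …) are detected with segmented regression, and proxy–diversity
   and proxy–composition relationships are quantified with Poisson GLMs and
   partial distance-based redundancy analysis.

## The statistical core

**Pulse inference.** A taxon that truly dies at pulse horizon *P* but is last
seen in bed *l* was present-but-missed in every intervening bed. With per-bed
recovery probabilities *p_b*, a taxon's likelihood is

    L(t) = p_lad(t) · ∏_{b : lad(t) < b ≤ P(t)} (1 − p_b)

for a k-pulse model (each taxon assigned to its nearest pulse at-or-above its
LAD), and the uniform average of the same expression over an extinction bed
drawn from [lo, hi] for the interval model (k = 0). Pulse positions are
profiled by exhaustive search over observed LAD beds; the pulse count is
selected by BIC with a parametric-bootstrap likelihood-ratio confirmation
between adjacent pulse counts. Singletons (one-horizon taxa) carry no timing
information and are excluded.

**Range confidence intervals.** Classical uniform-recovery (Strauss–Sadler)
extensions: with H horizons over range length r, the range extends above the
LAD by `r·((1−C)^(−1/(H−1)) − 1)` at confidence C.

**Segmented regression.** Continuous piecewise-linear fits
`E[y] = b0 + b1·x + Σ d_j (x − ψ_j)₊` estimated by Muggeo-style iterative
linearization with multi-start, breakpoint count by BIC. The fitted curve
doubles as the imputation rule for proxy values at unsampled beds, and
MAD-based residual flags separate transient spikes (volcanism tracers such as
Hg/TOC) from persistent state shifts.

**Association models.** Collinearity-screened (VIF) design matrices of
bed-level proxies; log-link Poisson GLMs of range-through richness, run as a
*pair* of models when two focal proxies are too correlated to share one fit;
partial dbRDA (the capscale construction: Gower-centred −d²/2, residualized
on conditioning variables, projected on constraints) of Jaccard distances
between bed assemblages, with permutation pseudo-F tests.

## Worked example

The bundled deterministic fixture is a 12-bed section with 40 taxa whose true
extinction happens in two pulses (beds 6 and 11) under 90% per-bed recovery,
plus four synthetic proxies — one with a real state shift at the first pulse
horizon (2.75 m).

```python
from stratext.pipeline import AnalysisConfig, run_full_analysis
from stratext.synthetic_data import fixture_mini_meishan

cfg = AnalysisConfig(seed=7, window=("1", "12"),
                     focal_pair=("proxy_break", "proxy_trend"))
report = run_full_analysis(cfg, data=fixture_mini_meishan())

pooled = report["pulses"]["pooled"]
print(f"pooled extinction model: k={pooled.k} pulses at beds {pooled.pulse_beds} "
      f"(heights {[round(h, 2) for h in pooled.pulse_heights]} m)")
fit = report["segmented_fits"]["proxy_break"]
print(f"proxy_break: {fit.n_breakpoints} state shift at {fit.breakpoints[0]:.2f} m, "
      f"segment slopes {[round(float(s), 2) for s in fit.segment_slopes]}")
```

prints

```
pooled extinction model: k=2 pulses at beds ['6', '11'] (heights [2.75, 5.25] m)
proxy_break: 1 state shift at 2.78 m, segment slopes [0.19, -1.99]
```

— the two constructed pulse horizons are recovered exactly (bed midpoints
2.75 m and 5.25 m), and the proxy breakpoint lands within 3 cm of the
constructed shift with the constructed slopes (0.2, then −2.0). The same
report carries the paired GLMs (`AIC 117.3 keeping proxy_break vs 122.7
keeping proxy_trend` — the proxy that actually drives richness wins) and the
partial dbRDA (`53% of assemblage inertia constrained, permutation
p = 0.010`).

The CLI exposes the same stages (`stratext run --config cfg.yaml --out dir`,
plus `vet`, `ranges`, `pulses`, `proxies`, `segmented`, `assoc`, `simulate`).
A full run writes `fig2_pulses.tsv` (per-clade pulse models),
`fig3_breakpoints.tsv` (per-proxy state shifts), `table1_glm.tsv` (GLM
coefficients), `fig4_scores.csv` (ordination scores) and `run_log.json`.

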