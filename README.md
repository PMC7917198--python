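# woundtrack

Quantification of leukocyte migration in larval-zebrafish tail-wound
assays. Given per-cell, per-frame 2D position tables (e.g. the Fiji
manual-tracking export) plus the wound geometry, the package computes the
standard per-track statistics, classifies cells relative to the wound,
fits a persistent-random-walk model to the cohort mean squared
displacement, analyses velocity along the anteroposterior body axis, and
compares groups (e.g. genotypes) statistically. It also ships a synthetic
cohort generator (correlated random walkers with optional wound-directed
chemotactic bias and retention at the wound) and a minimal Viterbi
global-linking tracker, so the whole pipeline can be exercised and
validated without microscopy data.

Intended users: groups quantifying neutrophil/macrophage recruitment in
live-imaging wound assays, and anyone needing a tested reference
implementation of these track measures.

## The model and the measures

For a track p₁ … p_N sampled every Δt minutes (positions in μm):

- net displacement d_net = d(p₁, p_N)
- total displacement d_tot = Σᵢ d(pᵢ, pᵢ₊₁)
- meandering index M.I. = d_net / d_tot ∈ [0, 1]
- mean speed v̄ = d_tot / elapsed time (μm/min)
- V_AP — per-step velocity projected on the anteroposterior body axis,
  positive toward the wound; the cohort time course averages all cells'
  steps over three consecutive frames.

The cohort MSD is *anchored*: MSD(t) = (1/K) Σᵢ d(p_{i,1}, p_{i,1+t})²,
averaging over the K cells still tracked at lag t. For a persistent
random walker Fürth's formula gives

    MSD(t) = 2v²τt − 2(vτ)²(1 − e^(−t/τ)),

with v the intrinsic speed and τ the persistence time; nonlinear least
squares on the measured curve yields v and τ, and the cell diffusivity
follows as D = v²τ/2 (μm²/min, from D = (1/2n)·dMSD/dt with n = 2).

Wound-relative rules: cells starting further than 200 μm from the wound
edge are *distant*, within 200 μm (inclusive) *local resident*; a cell
*arrives* when it comes within 20 μm of the edge and *stays* if it never
leaves that band again; recruited-cell counts use the 200 μm band.

## Worked example

```python
import woundtrack as wt

# a chemotactic cohort: 50 walkers, 2 h at 1 frame/min, wound-directed
cfg = wt.SimulationConfig(seed=1, n_cells=50, bias=0.5, speed_cv=0.3)
cohort = wt.simulate_cohort(cfg)

summary = wt.summarize_cohort(cohort, cfg.wound)
print(summary["arrived"].mean())          # 1.0   (all cells reach the wound)
print(round(summary["mean_speed"].mean(), 2))       # 9.96 μm/min
print(round(summary["meandering_index"].mean(), 2)) # 0.35

# persistent-random-walk fit on an unbiased cohort
free = wt.simulate_cohort(wt.SimulationConfig(seed=1, n_cells=50, bias=0.0))
res = wt.PRWModel.from_cohort(free, fit_window=40.0).fit()
print(res.summary())
```

```
Persistent random walk fit (Fürth MSD, 2D)
==============================================
lags fitted                40  (window 40 min)
speed v               10.5104  ± 0.0680 μm/min
persistence τ          4.1914  ± 0.0771 min
diffusivity D        231.5064  μm²/min  (v²τ/2)
residual norm            2641  μm²
```

The generating truth here is v = 10 μm/min, τ = 5 min (D = 250 μm²/min):
the fit recovers the speed within ~5% and the persistence within ~16% on
this seed, within the stochastic scatter of a 50-cell anchored MSD.
Real-data workflows start from `wt.read_tracks(path, dialect=...,
scale=...)` and a `wt.load_config(...)` wound description instead of the
simulator, and end with `wt.compare_groups` / `wt.render_report` for the
genotype comparison tables and SEM-shaded curves.

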