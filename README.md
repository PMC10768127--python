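# phsupply

Spatial-inequality analysis of regional **public-health-service (PHS) supply**
from a prefecture-city × year × indicator panel: how well supplied each city
is, how the spatial pattern of supply moves over time, how unequal the
regions are and why.

The package is built for the canonical intra-provincial setting — 21
prefecture-level cities grouped into four macro-regions, observed annually
over 17 years on ~20 directional service indicators — but every stage is
generic in the number of units, years, regions and indicators.

## What it computes

1. **Composite index (entropy weighting).** Indicators are min-max
   standardized respecting their direction (benefit `+` / cost `−`),
   `x' = (x − x_min)/(x_max − x_min)` or `(x_max − x)/(x_max − x_min)`;
   weights come from Shannon entropy over the m unit-year rows,
   `e_j = −(1/ln m) Σ_i p_ij ln p_ij`, `w_j ∝ 1 − e_j`; the score is
   `PHS_it = Σ_j w_j x'_itj ∈ [0, 1]`.
2. **Standard deviation ellipse.** Score-weighted mean center, orthogonal
   axis standard deviations, azimuth θ (clockwise from north) and area of
   the spatial point pattern, per year, plus the drift track of the center
   of gravity.
3. **Kernel-density distribution dynamics.** Gaussian KDE per year and
   region with shape descriptors: main-peak location/height, FWHM, peak
   count, tail masses, and a polarization label.
4. **Markov chains.** Pooled-quantile class discretization, the K×K
   transition matrix `E_pq = k_pq / k_p`, and the spatial variant: K
   conditional matrices indexed by the class of the neighbor-weighted
   average score (the spatial lag), whose counts sum back exactly to the
   unconditional counts.
5. **Dagum Gini decomposition.** `G = G_w + G_nb + G_t`: within-region,
   net between-region, and transvariation (overlap) components with
   contribution rates, per year.
6. **Panel regression.** Pooled OLS, fixed effects (within) and random
   effects (Swamy–Arora GLS) of the score on lnPGDP, fiscal
   decentralization, log density, urbanization and tertiary-industry
   share, with cluster-robust errors and the F / Breusch–Pagan LM /
   Hausman specification battery.
7. **Threshold regression (Hansen).** Fixed-effects grid-search estimation
   of 1–3 thresholds in lnPGDP for the urbanization / fiscal regimes, with
   residual-bootstrap F tests and likelihood-ratio confidence sets.

A calibrated synthetic-data generator (`phsupply.synthetic_data`) emulates
the study conditions — region-clustered geography with Delaunay contiguity,
spatially autocorrelated unit effects, regional trends, covariates matching
the published summary moments, and planted regression/threshold effects —
so the entire pipeline runs and is testable with no external data.

## Worked example

```sh
python analysis/01_simulate_province.py   # synthetic inputs -> results/inputs/
python analysis/02_entropy_index.py       # weights + scores
python analysis/05_markov_chains.py       # transition matrices
python analysis/06_gini_decomposition.py  # Dagum series
```

prints (seed 11):

```
entropy weights: sum=1.000000, range [0.0292, 0.0620]
provincial mean score rose 0.4034 -> 0.6632 over 2005-2021
quartile cuts: [0.3633, 0.5632, 0.6809]
persistence diagonal: ['85.23%', '75.00%', '67.44%', '85.90%']
upward moves 50 vs downward 23 (counts conserved across tensor slices: True)
synthetic province: G 0.2519 -> 0.1496 (+40.61% decline)
published provincial endpoints 0.0978 -> 0.0583 give 40.39% decline
between-region contribution: mean 84.2%, transvariation: max 9.1%
decomposition identity gap (max over years): 8.33e-17
```

The weight sum of 1 and the decomposition identity gap at machine precision
are exact properties; the ~40% Gini decline, the dominant persistence
diagonal (club convergence) and the between-region component carrying most
of the inequality mirror the qualitative structure the generator plants.
The same stages are available as a CLI (`phsupply simulate|index|sde|kde|
markov|gini|panel|threshold|run`) and as one orchestrated run from a YAML
config (`phsupply run --config ...`).

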