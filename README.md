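# cryptclones

Clonal dynamics, mutation clone calling and spatial-neighbourhood scoring for
colitis-associated tumorigenesis.

Chronic intestinal inflammation reshapes the clonal landscape of the colonic
epithelium: tissue repair drives neutral clonal expansion through crypt
fission, and the cellular neighbourhood a mutant clone arises in helps decide
whether it stays benign or seeds a tumour. `cryptclones` implements the
computational layer of that analysis for researchers working with mouse
colitis models and spatially resolved mutation data:

- **`lattice`** — an on-lattice voter-type simulator of crypt dynamics. Each
  site of an M×M hexagonally connected periodic lattice is one crypt in state
  s ∈ {−1 (unlabelled), 0 (empty), +1 (labelled)}, updated by random
  single-site events with per-state fission (ρ_s), fusion (f_s) and
  monoclonal-fixation (P_s) probabilities. Supports acute-damage experiments
  (emptying the right half) and fission-bias scenarios (ρ₊₁ = 0.95 vs 0.5).
- **`aggregation`** — the distinct-neighbour-pair statistic: with α the
  number of occupied neighbour links whose states differ and β all occupied
  neighbour links, concentration C = α/β and site aggregation 1 − C measures
  spatial clustering of same-state crypts (domain coarsening).
- **`fission`** — hierarchical Bayesian inference of effective crypt-fission
  rates ρᵢ (1/days) from clone-size counts via the Yule–Furry pure-birth
  likelihood f_n(ρ,t) = e^(−ρt)(1 − e^(−ρt))^(n−1), with
  ρᵢ ~ StudentT(ν, μ, σ) truncated at zero, μ ~ N(0, 0.1),
  σ ~ HalfNormal(0.1), ν ~ Gamma(2, 0.1), and multinomial region counts
  gᵢ ~ Multinomial(f(ρᵢ, tᵢ)). Sampled with a differential-evolution
  ensemble sampler; split-R̂/ESS diagnostics attached.
- **`clones`** — spatial clone calling from biopsy-level SNV tables:
  dual-replicate log-ratio filtering with a 0.01% VAF floor, periodic
  Voronoi adjacency of 2 mm biopsies on the opened colon (radial axis
  wraps at the circumference; tiles adjacent when they share boundary or
  centres are within 2 mm), and connected-component clone calling per
  mutation key.
- **`neighbourhoods`** — integration with spatial-transcriptomic cluster
  labels: barcode→biopsy mapping, per-sample cluster coverage, Kendall
  coverage correlations, tumour-associated mutation classification (≥5
  tumour-cluster barcodes in the biopsy), per-gene malignancy scores,
  barcode cluster probabilities and coverage regressions.
- **`synth`** — generators for every input with planted ground truth
  (fission rates, clone footprints, repair-cluster enrichment), so the whole
  pipeline is testable end-to-end without animal data.

## Worked example

Damage-repair simulations with and without a fission-biased labelled
population (M = 50, 100 replicates, damage at step 30,000), followed by
fission-rate recovery on synthetic clone sizes:

```python
import numpy as np
from cryptclones.lattice import SimParams, run_replicates
from cryptclones.fission import FissionModelConfig, fit_fission_model
from cryptclones.synth import gen_clone_sizes

params = SimParams(lattice_size=50, damage_step=30_000, total_steps=200_000,
                   record_every=100, n_replicates=100, seed=1)
neutral = run_replicates(params)
biased = run_replicates(SimParams(**{**params.__dict__, "fission_labelled": 0.95}))
t_n = np.mean([r.repair_steps for r in neutral if r.repair_steps])
t_b = np.mean([r.repair_steps for r in biased if r.repair_steps])
print(f"mean repair time: neutral {t_n:.0f} steps, fission-biased {t_b:.0f} steps")

data = [gen_clone_sizes(rho, 210.0, 200, seed=s, region_id=r, n_max=30)
        for r, rho, s in [("low", 0.002, 11), ("mid", 0.01, 12), ("high", 0.02, 13)]]
post = fit_fission_model(data, FissionModelConfig(lam=0.0, seed=1))
print(post.summary.round(4).to_string())
print(f"converged: {post.converged} (max split R-hat {post.max_rhat:.4f})")
```

prints

```
mean repair time: neutral 20311 steps, fission-biased 10880 steps
              mean   median   ci2.5   ci97.5    rhat   ess_bulk
parameter
mu         -0.0765  -0.0690 -0.2112   0.0130  1.0039  4979.2101
sigma       0.0318   0.0272  0.0051   0.0866  1.0074  4549.6636
nu         21.1956  18.3490  4.5045  53.2435  1.0066  5460.7757
rho[low]    0.0019   0.0019  0.0015   0.0022  1.0042  5497.9143
rho[mid]    0.0102   0.0102  0.0096   0.0108  1.0049  5193.5963
rho[high]   0.0201   0.0201  0.0191   0.0212  1.0041  5919.6218
converged: True (max split R-hat 1.0074)
```

A fission advantage roughly halves the repair time of the damaged half, and
the hierarchical model recovers the planted rates (0.002, 0.01, 0.02 /day)
inside tight credible intervals with converged chains.

The same analyses are available from the shell:

```sh
cryptclones synth --out-dir data --seed 0          # all inputs + truth.json
cryptclones call-clones --biopsies data/biopsies.tsv \
    --calls data/mutation_calls.tsv --out data/clones.tsv
cryptclones simulate --size 50 --damage-step 30000 --steps 200000 \
    --replicates 100 --seed 1 --out sim.csv
cryptclones infer-fission --input data/clone_sizes.tsv --seed 1 --out-prefix fit
cryptclones integrate --biopsies data/biopsies.tsv --calls data/mutation_calls.tsv \
    --barcodes data/barcodes.csv --out-dir integ
cryptclones score --biopsies data/biopsies.tsv --calls data/mutation_calls.tsv \
    --barcodes data/barcodes.csv --out-dir scores
cryptclones run-all --out-dir pipeline --seed 0    # everything + manifest.json
```

See `docs/methods.md` for the models, priors, numerical choices and known
limitations.

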