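# fivehit

A five-hit multitype branching-process model of colorectal carcinogenesis,
for biostatisticians and modellers who want to relate the *order* of driver
gene mutations to age-specific cancer incidence.

Colorectal tumours carrying all three major driver alterations need five
mutational hits: activation of the oncogene *KRAS* (one hit) and biallelic
inactivation of the tumour suppressors *APC* and *TP53* (two ordered hits
each).  A pool of N normal stem cells seeds the first premalignant
compartment at rate μ_N per cell-year; a stage-i cell divides at α_i, dies
at β_i (net growth λ_i = α_i − β_i) and spawns one stage-(i+1) daughter at
μ_i; the fifth hit creates a persistent malignant cell, detected clinically
after a fixed lag T_lag.  The package provides:

- **`fivehit.pathways`** — enumeration of all 30 legal hit orderings, their
  six gene orders and five growth-rate cases, and the eleven
  incidence-supported pathways as a curated constant.
- **`fivehit.rates` / `fivehit.fitted`** — the stage growth/death-rate
  assignment (division every 5 days ⇒ 73/y; +0.07/y net for KRAS⁺, +0.2/y
  for APC⁻ᐟ⁻, additive; nothing for heterozygous hits or TP53⁻ᐟ⁻) and the
  published fitted mutation rates per pathway.
- **`fivehit.hazard`** — the hazard h(t) of clinical detection by two
  routes: the clone-expectation approximation h ≈ μ_p4·E[P₄(t−T_lag)]
  (linear cascade; closed residue form for distinct λ), and the exact
  solution via the Kolmogorov backward equations for the process'
  probability generating functions, h = N·μ_N·(1 − Φ₁(t−T_lag)), by
  fixed-step RK4.  Also expected clone sizes by genotype class.
- **`fivehit.gillespie`** — an exact event-driven simulator of the same
  process, used as ground truth for the solvers.
- **`fivehit.synthetic`** — registry-like age–incidence series (ages 0–84,
  rate per 100,000, optional Poisson counting noise) generated from the
  model.
- **`fivehit.abcfit`** — sequential approximate Bayesian computation with a
  smoothed simulated-likelihood kernel, estimating Θ = (v, μ_p1..μ_p4)
  with v = N·μ_N from an incidence curve, with weighted quartile summaries.

## Worked example

Enumerate the pathway catalog and compute both hazard solutions for the
KRAS-first pathway at its published rates:

```bash
fivehit enumerate --out catalog.tsv
fivehit hazard --pathway "K,A1,A2,T1,T2" --solver both --out hazard.tsv
```

`catalog.tsv` holds one row per ordering (case, gene order, accepted flag);
`hazard.tsv` begins:

```
# pathway = K,A1,A2,T1,T2
# v = 0.893; mu = (0.0047, 0.00199, 0.000699, 0.000252); Tlag = 5.0
age     hazard_approx   hazard_exact    difference
...
54      0.002678056976  3.276214088e-05 0.002645294836
84      16.31723112     0.0003734949828 16.31685762
```

At these biological division rates (≈73/y) the clone-expectation
approximation overshoots the exact hazard by orders of magnitude — the
exact per-person risk at age 84 is 3.7×10⁻⁴/y (37 per 100,000), while the
mean-clone-size calculation, blind to the fact that a clone's chance of
ever transforming saturates, reports a "hazard" above 16/y.  This is why
the exact generating-function solution is used for all fitting.

Closing the loop — generate a noise-free synthetic incidence curve from
the same truth and re-estimate the rates by ABC:

```python
import numpy as np, fivehit as fh
from fivehit.abcfit import ABCConfig, fit, summarize

seq    = fh.MutationSequence.from_id("K,A1,A2,T1,T2")
truth  = fh.fitted_for(seq.id)                        # published medians
params = fh.build_model_parameters(seq, truth.theta, N=1e8, Tlag=5.0)
series = fh.generate(fh.SyntheticConfig(truth=params, pathway=seq,
                                        ages=np.arange(1.0, 85.0),
                                        fraction_triple_mutant=1.0, seed=1))
post = fit(series, seq, config=ABCConfig(), seed=1)   # ~10 s
for row in summarize(post):
    print(row["parameter"], f"{row['median']:.3e}",
          f"[{row['ci_low']:.2e}, {row['ci_high']:.2e}]")
```

prints (truth in parentheses):

```
v    8.736e-01 [6.20e-01, 1.86e+00]    (0.893  = N·μ_N, so μ_N ≈ 8.7e-9/cell/y)
mu1  5.006e-03 [1.43e-03, 9.46e-03]    (4.70e-3)
mu2  2.029e-03 [1.10e-03, 4.25e-03]    (1.99e-3)
mu3  6.570e-04 [4.11e-04, 9.42e-04]    (6.99e-4)
mu4  2.716e-04 [1.99e-04, 3.93e-04]    (2.52e-4)
```

— every stage rate recovered within a few tens of percent and the
initiating rate v/N within ~2%, from the incidence curve alone.

The same pipeline is available from the shell as `fivehit generate` and
`fivehit fit`, and `fivehit simulate` writes single stochastic
trajectories (at down-scaled rates) as event logs.

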