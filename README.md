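# alleledyn

Stochastic-model analysis of mono- and bi-allelic gene activation from
two-color single-cell fluorescence data.

When each allele of a gene is tagged with a distinguishable fluorescent
reporter (YFP / mCherry), a developing cell population decomposes into four
observable classes — non-expressing, mono-allelic (either color), and
bi-allelic — and the time evolution of those fractions, together with their
distribution across clonal lineages, discriminates between mechanisms of
gene activation. `alleledyn` is for researchers analyzing such data (e.g.
allele-resolved reporters of lineage-commitment genes in T-cell
progenitors). It provides:

- **Hidden-state Markov models** of activation: a *cis*-only scheme (each
  allele switches independently at rate k_C), a *sequential* scheme (a
  shared *trans* step at rate k_T must precede any cis switching), and a
  *parallel* scheme (trans and cis proceed independently; expression
  requires both). Population fractions are solved exactly via the matrix
  exponential of the generator.
- **Mixture quantification**: time-resolved class fractions f_i^obs(t) with
  uncertainties δf_i^obs from intensity tables, by the constrained
  two-step four-component bivariate Gaussian histogram fit (non-expressing
  component anchored on an early time window).
- **Delay-corrected fitting and comparison**: per-class detection delays
  τ_i (fluorophore maturation), weighted least squares of f_i(t−τ_i) to the
  observed series, reduced-χ² scoring, and F-tests between models.
- **Monte-Carlo clonal lineage simulation** (division every 20 h, five
  generations) with exact within-generation path observation, clone
  classification (single mono-allelic / mixed mono-allelic / bi-allelic
  only), and the clone-level χ² test.
- **Perturbation phase-space analysis**: endpoints (F_n, F_m, F_b) of
  populations started from non-, mono-, or bi-allelic states under graded
  cis or trans perturbations (forward-rate reduction + added reverse rate,
  attenuated on bi-allelic transitions).
- **A synthetic-data generator** emulating timelapse tracks and endpoint
  snapshots (continuous-time switching, division, maturation lag,
  class-conditional intensity noise) so the whole pipeline is testable
  without external data.

See `docs/methods.md` for the models, estimators, and numerical choices.

## Worked example

```python
import numpy as np
from alleledyn import (RateParams, naive_init, population_fractions,
                       clone_class_distribution, clone_class_chi2,
                       CloneSimConfig)
from alleledyn.clone_sim import CloneClass

rates = RateParams(kC=0.0042, kT=0.016)   # per hour

# exact class fractions of a naive population over time
traj = population_fractions("parallel", rates, naive_init("parallel"),
                            np.array([0.0, 50.0, 100.0]))
print(np.round(traj.fractions, 4))
# [[1.     0.     0.     0.    ]
#  [0.8111 0.0845 0.0845 0.0198]
#  [0.5464 0.1798 0.1798 0.0939]]

# clone-class distribution over 30,000 simulated lineages
cfg = CloneSimConfig(n_clones=30_000, rng_seed=1)
dist = clone_class_distribution("parallel", rates, naive_init("parallel"), cfg)
print({k.value: round(v, 3) for k, v in dist.fractions.items()})
# {'single_mono_allelic': 0.486, 'mixed_mono_allelic': 0.504,
#  'bi_allelic_only': 0.01}

# observed 7 of 9 single-mono clones vs this prediction
stat, p = clone_class_chi2(7, 9, dist.fractions[CloneClass.SINGLE_MONO])
print(round(stat, 2), round(p, 4))   # 1.58 0.2094
```

The columns of `traj.fractions` are (none, monoY, monoR, bi): starting from
a fully naive population, mono-allelic intermediates appear first (8.5% per
allele at 50 h) and bi-allelic cells lag quadratically — the kinetic
signature of independent per-allele switching. The clone simulation says
48.6% of expressing clones would show mono-allelic expression from only one
specific allele; observing 7 of 9 such clones is compatible with that
prediction (χ² = 1.58, p ≈ 0.21, 1 d.f.).

A command-line pipeline wraps the same stages:

```bash
alleledyn synth    --n-clones 200 --seed 1 --out out/synth
alleledyn quantify --tracks out/synth/tracks.tsv --out out/quantify
alleledyn fit      --fractions out/quantify/fractions.tsv --out out/fit
alleledyn clone-sim --model parallel --kc 0.0042 --kt 0.016 \
                    --n-clones 30000 --seed 1 --out out/clones
alleledyn phase-sweep --model parallel --kc 0.0042 --kt 0.016 \
                      --perturb trans --out out/sweep
alleledyn run-all  --config config.yaml --out out
```

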