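# Methods

`alleledyn` models the stochastic activation of a developmentally controlled
gene whose two alleles are tagged with distinguishable fluorescent reporters
(YFP on one chromosome, mCherry on the other), as in two-color reporter
studies of T-cell lineage commitment. This note records the models, the
estimation procedures, the numerical choices, and the known limitations.

## Hidden-state models

A cell's latent state is a triple `(trans, cisY, cisR)`: whether a shared
*trans*-acting step (e.g. activation of a required transcription factor) has
completed, and whether each allele has undergone its *cis*-epigenetic
activation. All switches are first-order (exponential waiting times) with
rates

| parameter | meaning | unit | default |
|---|---|---|---|
| `kC` | cis-activation rate, per allele | /hr | fit from data (~4e-3) |
| `kT` | trans-activation rate | /hr | fit from data |
| `kC_rev`, `kT_rev` | reverse rates | /hr | 0 (irreversible baseline) |

Three architectures are supported, differing in how trans and cis interact:

- **cis-only** (4 states): no trans requirement; each allele switches
  independently. Closed form: with s = exp(−kC·t), the class fractions are
  (s², s(1−s), s(1−s), (1−s)²).
- **sequential** (5 states): cis-activation is only possible after the trans
  step; the trans-off cis-open states do not exist.
- **parallel** (8 states): trans and cis proceed independently; expression
  requires both.

A cell's observable class is `none`, `monoY`, `monoR`, or `bi`: a channel is
expressed iff the trans step is done *and* that allele is cis-open. The
8-state/5-state encodings are our reconstruction of the three schemes from
their verbal/diagrammatic description; they are the minimal chains consistent
with first-order, allele-symmetric switching.

Population dynamics are solved with the exact matrix exponential of the
generator (state spaces ≤ 8, cost negligible); `population_fractions_ode`
provides an LSODA cross-check at rtol 1e-9. Initial conditions are
distributions over the model's *non-expressing* states (1, 2, and 5 states
respectively), matching sorted non-expressing starting populations whose
hidden sub-state composition is unknown and therefore fitted.

### Perturbations

A perturbation targets either the cis or the trans step and does two things:
multiplies the targeted forward rate by `forward_factor` ∈ [0,1] and adds
`reverse_rate` to the targeted reverse reaction (cis: open→closed per allele;
trans: on→off). `bi_attenuation` ∈ [0,1] linearly interpolates each modified
rate between its unperturbed (0) and fully perturbed (1) value on transitions
whose source or destination class is bi-allelic; the default 0.4 encodes the
observation that signal withdrawal inactivates bi-allelic expressers roughly
2.5-fold less often than mono-allelic ones (~6% vs ~15–18%). Graded sweeps
interpolate both modifications linearly in a magnitude parameter.

The reverse-reaction mapping (cis → allele closing, trans → factor loss) is
the only one consistent with the observed route structure: trans reversal
hides both alleles at once (direct bi→none reversion), while cis reversal
must silence one allele at a time. `classify_reversion_path` verifies this
exactly by augmenting the chain with a "visited a mono-allelic state" flag.
In the sequential scheme the trans reversal exists only in the naive state
(cis-open trans-off states are outside the space), so expressing cells are
exactly untouched by a trans perturbation — the property that
discriminates that scheme.

## Mixture quantification

Class fractions over time are estimated from (mCherry, YFP) intensity tables
by a constrained four-component bivariate Gaussian histogram fit:

1. The non-expressing component's shape (means, SDs, correlation) is fitted
   to cells from an early window (default t < 10 h) and frozen ("anchor").
2. Each time bin's 2-D histogram (default 64×64 bins on linear intensities,
   over one global intensity window for the whole run) is fitted by
   unweighted nonlinear least squares with the anchor's shape fixed (weight
   free) and the three expressing components bounded.

Numerical choices that matter, found necessary for stability:

- **Unweighted residuals.** Poisson-style weights (1/√count) let the many
  near-empty histogram bins dominate and allow a wide "expressing" component
  to invade the non-expressing blob; unweighted least squares penalizes that
  directly at the blob's peak.
- **Global histogram window and global bounds.** Per-bin windows let a
  component hide its mass outside the fitted region; per-bin bounds are
  meaningless in bins with no expressing cells. Both are derived once from
  the whole run.
- **Expressing-component boxes.** Channel thresholds sit at anchor mean + 3
  SD; an expressing component's active-channel mean is bounded below by
  anchor mean + 4 SD and around the matured population's location, estimated
  as the histogram mode of above-threshold intensities with scale from their
  upper tail (97.5th percentile) — both insensitive to the one-sided smear of
  still-maturing cells. SDs are capped at 1.5× that scale (2× the anchor SD
  when no expressing population is observed).
- **Linear intensities by default.** The generator's class-conditional noise
  is Gaussian on the linear scale, so fit and data share a coordinate
  system; an `arcsinh` option is provided for flow-style data.

Fractions are normalized weights f_i = N_i/ΣN_j. Weight uncertainties come
from the least-squares covariance (JᵀJ)⁻¹ scaled by residual variance and are
propagated as δf_i = f_i·sqrt((δN_i/N_i)² + ΣδN_j²/(ΣN_j)²); components with
N_i = 0 use only the additive term. When cell identities are present,
δN is additionally scaled by sqrt(rows/distinct cells) in each bin, because
successive frames of one cell are nearly identical measurements, not
independent cells. Fits where two active components collapse onto each other
are flagged, as are bins below a minimum cell count; optimizer
non-convergence raises.

## Delay-corrected fitting and model comparison

Fluorescent reporters need ~15–20 h to accumulate to detectability, so each
expressing class's measured fraction lags the state dynamics. The delay τ_i
is estimated as the first bin center where f_i > z·δf_i (default z = 2) in
that bin and the next (persistence guard); classes that never cross are
assigned the last bin and flagged. Delays are held fixed during rate
fitting. The model prediction for class i at time t is the undelayed model
at t − τ_i (initial condition for t < τ_i), with the non-expressing class
rebuilt as one minus the expressing classes.

Rates and free initial weights are fitted by bounded trust-region least
squares on standardized residuals over the three expressing classes
(optionally including `none`), excluding each class's pre-delay points and
any point with zero uncertainty. Free parameters: kC (cis-only); kC, kT and
one initial weight (sequential); kC, kT and four initial weights
(parallel), the latter parametrized as u_i ≥ 0 with w_i = u_i/(1+Σu) so the
simplex constraint is smooth and box-boundable. The optimizer restarts from
20 Latin-hypercube points with log-uniform rate draws, because the
likelihood has plateaus at extreme trans rates. Reduced chi-squared is the
minimized sum over degrees of freedom (points entering the sum minus free
parameters); models are compared by the ratio of reduced chi-squared values
(worse model in the numerator) against the F distribution with the two
fits' degrees of freedom.

## Clonal lineage simulation

Clones grow by synchronous divisions every 20 h, observed to 100 h (five
divisions, 63 cells). Each cell's state evolves over its lifetime by the
continuous-time chain; both daughters inherit the division-time state and
diverge afterwards — the exact coarse-graining of a continuous-time lineage,
under which daughters' next-boundary states are independent given the
parent's division state. Per-generation dynamics use exp(Q·Δt).

Clone scoring records every observed class a cell *visits* during its
lifetime, computed exactly by augmenting the chain with a bitmask of visited
classes (the augmented generator's exponential preserves the state
marginals). This matters: with boundary-only sampling a sequential-model
cell can hop none→bi within one 20 h generation unseen, producing ~0.5%
spurious "bi-allelic-only" clones, whereas in continuous time (and in ~1 h
timelapse data) the mono intermediate is always visible. Boundary-only
sampling remains available via `observe="boundaries"`.

Clones are classified by the set of expressing classes observed:
single mono-allelic (one mono class, bi optional), mixed mono-allelic (both
mono classes), bi-allelic only, or non-expressing; the class distribution is
reported over expressing clones with the non-expressing count alongside.
The clone-level goodness-of-fit statistic is the one-category
(O−E)²/E with E = n·p against chi-squared with 1 d.f.; the two-category
Pearson form (equal to the one-category statistic divided by 1−p) is also
available. For the reference counts (7 of 9 observed single-mono clones vs
predicted 20.1% and 63.9%) the one-category form gives 14.9 and 0.27, the
Pearson form 18.64 and 0.75.

**Validity domain of the clone-class signature.** At *identical* rates, the
parallel model produces a larger single-mono fraction than the sequential
model throughout the study-relevant regime (switching times of tens of
hours; verified exactly by a signature-DP enumeration over kC, kT ∈ [0.004,
0.016]/hr), but the ordering reverses where cis saturates within one
generation while trans is very slow (kC·Δt ≳ 0.4 with kT ≪ kC). The
scientifically meaningful comparison constrains both models to the same
bulk time course (each at its own best fit); under that matched-marginals
protocol the parallel model's single-mono excess holds in both cross-fit
directions we test.

## Synthetic data generator

`generate_movie` emulates segmented timelapse data: clonal lineages with
continuous-time switching (exact exponential waiting times, so onset times
are continuous), division every 20 h, ~200 starting clones, 105 h horizon,
1 h frames. Intensities are drawn per frame from class-conditional
Gaussians; after a channel's expression onset its mean rises as
1 − exp(−(t−t_on)/τ_m) from the non-expressing level to the active level
(τ_m = 23 h by default, which with the default intensity geometry yields an
effective detection lag near 16 h, inside the observed 15–20 h band).
Intensity units are arbitrary with the active levels 10 non-expressing SDs
above background.

The default starting population is *not* fully naive: sorting on
fluorescence cannot exclude hidden pre-activated sub-states, and the study
system shows expressing cells discernible within hours while population
fractions lag by the maturation time — features only reproduced when part
of the starting population already carries a cis-activated allele or an
active trans factor. The default places 55% in the fully naive state, 7% on
each single cis-open state, 3% on the doubly cis-open state, and 28% on the
trans-active cis-closed state; all are non-expressing. These weights were
chosen once for qualitative agreement with those features and are not
otherwise calibrated.

What the generator does *not* emulate: cell movement, tracking gaps,
segmentation errors, feeder-cell autofluorescence, asynchronous or variable
cell cycles, cell death, spectral overlap. Passing the round-trip tests
therefore shows the estimators are consistent under the model's own
assumptions, not that they are robust to those artifacts.

`generate_snapshot` draws endpoint class labels from the exact phase-space
distribution and intensities at full maturation, emulating flow-style
endpoint measurements.

## Problem sizes used in the test suite

Chosen to match the study scale while keeping runs reproducible on a single
CPU: movies with 200 clones / 105 h / 5 h analysis bins; 10 generator seeds
for the recovery median; 1,600 clones (≈51,000 leaf cells) for
marginal-agreement checks; 10,000–30,000 clones for clone-class
distributions; mixtures of 20,000 cells for weight-recovery checks.

## Known limitations

- kC recovered through the full pipeline carries a modest downward bias
  (median ≈ 20% at study scale): the exponential maturation smear is
  approximated by a sharp per-class delay, which compresses the apparent
  early rise. The bias is within the quoted 25% recovery band and vanishes
  on noiseless model-generated series (recovery to 1e-4).
- kT is only weakly identified from bulk fraction series when the trans
  step is fast (likelihood plateau); clone-level data are the informative
  observable for it.
- Histogram-based δN treats bins as independent; with strongly correlated
  frames the sqrt(rows/cells) correction is a first-order fix, not an exact
  error model.
- The delay estimator conflates detectability (statistical significance)
  with maturation when underlying fractions rise slowly from zero; delays
  are then upper bounds on the maturation lag.
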