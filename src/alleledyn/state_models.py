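"""Continuous-time Markov models of mono- and bi-allelic gene activation.

A cell carries two reporter-tagged copies (alleles) of the gene, read out in
two fluorescence channels (YFP and mCherry).  Each allele switches from a
silent to an activatable epigenetic state by a stochastic first-order
*cis*-acting event (rate ``kC`` per allele per hour).  Expression may in
addition require a *trans*-acting step (rate ``kT``) shared by both alleles.
Three candidate architectures are supported:

``cis_only``
    No trans requirement; each allele activates independently.  4 hidden
    states over (cisY, cisR).
``sequential``
    The trans step must complete before either allele can cis-activate.
    5 hidden states: the trans-off naive state plus trans-on x 4 cis combos.
``parallel``
    Trans and cis steps proceed independently; expression requires both.
    All 8 combinations of (trans, cisY, cisR) are reachable.

The observable is the four-way allelic expression class
(:class:`ObservedClass`): non-expressing, mono-allelic YFP, mono-allelic
mCherry, or bi-allelic.  A cell is scored as expressing a channel only when
the trans step is done *and* that allele is cis-activated.

Population dynamics are solved exactly by the matrix exponential of the
generator (state spaces are at most 8x8); :func:`population_fractions_ode`
provides an independent ODE cross-check.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.integrate import solve_ivp


class ModelKind(str, enum.Enum):
    CIS_ONLY = "cis_only"
    SEQUENTIAL = "sequential"
    PARALLEL = "parallel"


class ObservedClass(enum.IntEnum):
    """Fluorescence-detectable allelic expression class."""

    NONE = 0
    MONO_Y = 1
    MONO_R = 2
    BI = 3


#: Fixed class order used in every array/table the package emits.
CLASS_LABELS = ("none", "monoY", "monoR", "bi")

EXPRESSING_CLASSES = (ObservedClass.MONO_Y, ObservedClass.MONO_R, ObservedClass.BI)


@dataclass(frozen=True, order=True)
class HiddenState:
    """Latent cell state: trans step done, and cis state of each allele."""

    trans: bool
    cisY: bool
    cisR: bool

    @property
    def observed_class(self) -> ObservedClass:
        """Detectable class: expression requires trans AND a cis-open allele."""
        if not self.trans:
            return ObservedClass.NONE
        if self.cisY and self.cisR:
            return ObservedClass.BI
        if self.cisY:
            return ObservedClass.MONO_Y
        if self.cisR:
            return ObservedClass.MONO_R
        return ObservedClass.NONE

    def label(self) -> str:
        return "t%d_y%d_r%d" % (self.trans, self.cisY, self.cisR)


def _coerce_kind(model_kind: ModelKind | str) -> ModelKind:
    try:
        return ModelKind(model_kind)
    except ValueError:
        raise ValueError(f"unknown model kind: {model_kind!r}") from None


def state_space(model_kind: ModelKind | str) -> tuple[HiddenState, ...]:
    """Ordered hidden-state space of a model.

    cis_only fixes the trans flag true (4 states); sequential forbids cis-open
    trans-off states (5 states); parallel allows all 8 combinations.
    """
    kind = _coerce_kind(model_kind)
    combos = [(False, False), (True, False), (False, True), (True, True)]
    if kind is ModelKind.CIS_ONLY:
        return tuple(HiddenState(True, y, r) for y, r in combos)
    if kind is ModelKind.SEQUENTIAL:
        return (HiddenState(False, False, False),) + tuple(
            HiddenState(True, y, r) for y, r in combos
        )
    return tuple(HiddenState(t, y, r) for t in (False, True) for y, r in combos)


def state_index(model_kind: ModelKind | str) -> dict[HiddenState, int]:
    return {s: i for i, s in enumerate(state_space(model_kind))}


def class_projection(model_kind: ModelKind | str) -> np.ndarray:
    """(n_states, 4) 0/1 matrix marginalizing hidden states onto classes."""
    states = state_space(model_kind)
    proj = np.zeros((len(states), 4))
    for i, s in enumerate(states):
        proj[i, int(s.observed_class)] = 1.0
    return proj


@dataclass(frozen=True)
class RateParams:
    """First-order switching rates, per hour.

    ``kC`` applies identically to both alleles (allele symmetry); reverse
    rates default to zero, matching the observed irreversibility of
    activation under unperturbed conditions.
    """

    kC: float
    kT: float = 0.0
    kC_rev: float = 0.0
    kT_rev: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kC", "kT", "kC_rev", "kT_rev"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")


@dataclass(frozen=True)
class PerturbationSpec:
    """Graded perturbation of one reaction step (cis or trans).

    The targeted forward rate is multiplied by ``forward_factor`` and the
    targeted reverse rate increased by ``reverse_rate``.  ``bi_attenuation``
    linearly interpolates each modified rate between its unperturbed (0) and
    fully perturbed (1) value on transitions whose source or destination
    observed class is bi-allelic, reflecting the weaker effect of signal
    withdrawal on bi-allelically expressing cells.
    """

    target: str  # "cis" or "trans"
    forward_factor: float = 1.0
    reverse_rate: float = 0.0
    bi_attenuation: float = 0.4

    def __post_init__(self) -> None:
        if self.target not in ("cis", "trans"):
            raise ValueError("perturbation target must be 'cis' or 'trans'")
        if not 0.0 <= self.forward_factor <= 1.0:
            raise ValueError("forward_factor must be in [0, 1]")
        if self.reverse_rate < 0:
            raise ValueError("reverse_rate must be >= 0")
        if not 0.0 <= self.bi_attenuation <= 1.0:
            raise ValueError("bi_attenuation must be in [0, 1]")

    def scaled(self, magnitude: float) -> "PerturbationSpec":
        """Perturbation at fractional strength ``magnitude`` in [0, 1]."""
        if not 0.0 <= magnitude <= 1.0:
            raise ValueError("magnitude must be in [0, 1]")
        return PerturbationSpec(
            target=self.target,
            forward_factor=1.0 - magnitude * (1.0 - self.forward_factor),
            reverse_rate=magnitude * self.reverse_rate,
            bi_attenuation=self.bi_attenuation,
        )


@dataclass(frozen=True)
class InitialStateDistribution:
    """Distribution over the model's non-expressing hidden states at t=0."""

    model_kind: ModelKind
    weights: dict[HiddenState, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = state_index(self.model_kind)
        total = 0.0
        for s, w in self.weights.items():
            if s not in idx:
                raise ValueError(f"state {s} outside {self.model_kind.value} space")
            if s.observed_class is not ObservedClass.NONE:
                raise ValueError(f"initial state {s} is expressing")
            if w < 0:
                raise ValueError("initial weights must be >= 0")
            total += w
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial weights sum to {total}, expected 1")

    def as_vector(self) -> np.ndarray:
        idx = state_index(self.model_kind)
        p0 = np.zeros(len(idx))
        for s, w in self.weights.items():
            p0[idx[s]] = w
        return p0


def naive_init(model_kind: ModelKind | str) -> InitialStateDistribution:
    """All mass on the fully unswitched state (cis_only: trans fixed on)."""
    kind = _coerce_kind(model_kind)
    naive = HiddenState(kind is ModelKind.CIS_ONLY, False, False)
    return InitialStateDistribution(kind, {naive: 1.0})


def nonexpressing_states(model_kind: ModelKind | str) -> tuple[HiddenState, ...]:
    return tuple(
        s for s in state_space(model_kind) if s.observed_class is ObservedClass.NONE
    )


def _elementary_rate(
    src: HiddenState,
    dst: HiddenState,
    rates: RateParams,
    perturbation: PerturbationSpec | None,
) -> float:
    """Rate of the single-flag transition src -> dst (0 if not elementary)."""
    flips = (src.trans != dst.trans, src.cisY != dst.cisY, src.cisR != dst.cisR)
    if sum(flips) != 1:
        return 0.0
    if flips[0]:
        step, base = "trans", (rates.kT if dst.trans else rates.kT_rev)
        forward = dst.trans
    else:
        opened = dst.cisY if flips[1] else dst.cisR
        step, base = "cis", (rates.kC if opened else rates.kC_rev)
        forward = opened
    if perturbation is None or perturbation.target != step:
        return base
    perturbed = base * perturbation.forward_factor if forward else base + perturbation.reverse_rate
    bi = ObservedClass.BI
    if src.observed_class is bi or dst.observed_class is bi:
        return base + perturbation.bi_attenuation * (perturbed - base)
    return perturbed


def build_rate_matrix(
    model_kind: ModelKind | str,
    rates: RateParams,
    perturbation: PerturbationSpec | None = None,
) -> np.ndarray:
    """Generator matrix Q over the model's hidden-state space.

    Off-diagonal Q[i, j] is the rate of the elementary transition i -> j;
    rows sum to zero.  Sequential-model cis transitions out of trans-off
    states are structurally absent (the target states are outside the space),
    as are trans reversals out of cis-open states.
    """
    states = state_space(model_kind)
    n = len(states)
    Q = np.zeros((n, n))
    for i, src in enumerate(states):
        for j, dst in enumerate(states):
            if i != j:
                Q[i, j] = _elementary_rate(src, dst, rates, perturbation)
        Q[i, i] = -Q[i].sum()
    return Q


@dataclass(frozen=True)
class PopulationTrajectory:
    """Observed-class fractions over time (columns in CLASS_LABELS order)."""

    times: np.ndarray
    fractions: np.ndarray  # shape (len(times), 4)

    def __post_init__(self) -> None:
        if self.fractions.shape != (len(self.times), 4):
            raise ValueError("fractions must have shape (n_times, 4)")

    def column(self, cls: ObservedClass) -> np.ndarray:
        return self.fractions[:, int(cls)]


def hidden_state_occupancy(
    model_kind: ModelKind | str,
    rates: RateParams,
    init: InitialStateDistribution,
    times: np.ndarray,
    perturbation: PerturbationSpec | None = None,
) -> np.ndarray:
    """Exact hidden-state occupancies p(t) = p0 expm(Q t), shape (n_t, n_states)."""
    kind = _coerce_kind(model_kind)
    if init.model_kind is not kind:
        raise ValueError("initial distribution is for a different model")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(times < 0):
        raise ValueError("times must be a 1-D array of non-negative hours")
    Q = build_rate_matrix(kind, rates, perturbation)
    p0 = init.as_vector()
    # scipy expm broadcasts over stacked matrices
    Ps = expm(Q[None, :, :] * times[:, None, None])
    return np.einsum("i,tij->tj", p0, Ps)


def population_fractions(
    model_kind: ModelKind | str,
    rates: RateParams,
    init: InitialStateDistribution,
    times: np.ndarray,
    perturbation: PerturbationSpec | None = None,
) -> PopulationTrajectory:
    """Observed-class fractions over time (matrix-exponential solution)."""
    occ = hidden_state_occupancy(model_kind, rates, init, times, perturbation)
    fractions = occ @ class_projection(model_kind)
    return PopulationTrajectory(np.asarray(times, dtype=float), fractions)


def population_fractions_ode(
    model_kind: ModelKind | str,
    rates: RateParams,
    init: InitialStateDistribution,
    times: np.ndarray,
    perturbation: PerturbationSpec | None = None,
    rtol: float = 1e-9,
) -> PopulationTrajectory:
    """ODE-solver cross-check of :func:`population_fractions` (dp/dt = p Q)."""
    kind = _coerce_kind(model_kind)
    Q = build_rate_matrix(kind, rates, perturbation)
    times = np.asarray(times, dtype=float)
    sol = solve_ivp(
        lambda _t, p: p @ Q,
        (0.0, max(times.max(), 1e-12)),
        init.as_vector(),
        t_eval=times,
        rtol=rtol,
        atol=1e-12,
        method="LSODA",
    )
    fractions = sol.y.T @ class_projection(kind)
    return PopulationTrajectory(times, fractions)


def closed_form_cis_only(kC: float, t: float | np.ndarray) -> np.ndarray:
    """Analytic class fractions for two independent first-order switches.

    With each allele opening at rate ``kC`` and survival s = exp(-kC t):
    none = s^2, each mono class = s (1 - s), bi = (1 - s)^2.
    Returns an array (..., 4) in CLASS_LABELS order.
    """
    if kC < 0:
        raise ValueError("kC must be >= 0")
    t = np.asarray(t, dtype=float)
    s = np.exp(-kC * t)
    return np.stack([s * s, s * (1 - s), s * (1 - s), (1 - s) ** 2], axis=-1)


def rates_from_config(cfg: dict) -> tuple[ModelKind, RateParams, InitialStateDistribution, PerturbationSpec | None]:
    """Parse a {model, kC, kT, ..., init, perturbation} config mapping."""
    kind = _coerce_kind(cfg["model"])
    rates = RateParams(
        kC=float(cfg.get("kC", 0.0)),
        kT=float(cfg.get("kT", 0.0)),
        kC_rev=float(cfg.get("kC_rev", 0.0)),
        kT_rev=float(cfg.get("kT_rev", 0.0)),
    )
    if "init" in cfg and cfg["init"]:
        by_label = {s.label(): s for s in state_space(kind)}
        weights = {by_label[k]: float(v) for k, v in cfg["init"].items()}
        init = InitialStateDistribution(kind, weights)
    else:
        init = naive_init(kind)
    pert = None
    if cfg.get("perturbation"):
        p = cfg["perturbation"]
        pert = PerturbationSpec(
            target=p["target"],
            forward_factor=float(p.get("forward_factor", 1.0)),
            reverse_rate=float(p.get("reverse_rate", 0.0)),
            bi_attenuation=float(p.get("bi_attenuation", 0.4)),
        )
    return kind, rates, init, pert
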