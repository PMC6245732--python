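"""Phase-space analysis of perturbed activation dynamics.

A population's composition is summarized as a point in the triangle
(F_n, F_m, F_b): the fractions of non-expressing, mono-allelic (both
channels combined), and bi-allelic cells.  Starting populations sorted by
allelic state (none / mono / bi) are evolved to a fixed horizon under
unperturbed or perturbed dynamics; a perturbation of the cis or the trans
step both scales its forward rate down and adds a reverse rate, with a
graded attenuation on transitions touching the bi-allelic class.

The endpoint shifts discriminate where a signal acts: reducing the per-allele
cis rate depletes bi-allelic cells faster than mono-allelic ones (raising
F_m / F_b), whereas a uniform trans perturbation rescales expression of both
classes together and leaves F_m / F_b unchanged.  Reversal routes also
differ: losing the trans factor hides both alleles at once (direct bi -> none
reversion), while cis reversal must silence one allele at a time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .state_models import (
    HiddenState,
    InitialStateDistribution,
    ModelKind,
    ObservedClass,
    PerturbationSpec,
    RateParams,
    build_rate_matrix,
    naive_init,
    state_index,
    state_space,
)

START_LABELS = ("none", "mono", "bi")


@dataclass(frozen=True)
class PhasePoint:
    """Population composition: non-, mono- (combined), and bi-allelic."""

    F_n: float
    F_m: float
    F_b: float

    def __post_init__(self) -> None:
        for v in (self.F_n, self.F_m, self.F_b):
            if v < -1e-9:
                raise ValueError("phase-point fractions must be >= 0")
        if abs(self.F_n + self.F_m + self.F_b - 1.0) > 1e-9:
            raise ValueError("phase-point fractions must sum to 1")

    @property
    def mono_to_bi_ratio(self) -> float:
        return self.F_m / self.F_b if self.F_b > 0 else float("inf")


def start_distribution(
    model_kind: ModelKind | str, label: str
) -> dict[HiddenState, float]:
    """Hidden-state distribution of a sorted starting population.

    ``none`` starts fully naive; ``mono`` splits 50/50 between the two
    single-allele expressing states (trans on, as expressing requires);
    ``bi`` is the doubly cis-open, trans-on state.
    """
    kind = ModelKind(model_kind)
    if label == "none":
        return dict(naive_init(kind).weights)
    if label == "mono":
        return {HiddenState(True, True, False): 0.5, HiddenState(True, False, True): 0.5}
    if label == "bi":
        return {HiddenState(True, True, True): 1.0}
    raise ValueError(f"unknown start label: {label!r}")


def _evolve(
    model_kind: ModelKind | str,
    rates: RateParams,
    start: dict[HiddenState, float],
    perturbation: PerturbationSpec | None,
    horizon_h: float,
) -> np.ndarray:
    kind = ModelKind(model_kind)
    idx = state_index(kind)
    p0 = np.zeros(len(idx))
    for s, w in start.items():
        if s not in idx:
            raise ValueError(f"start state {s} inconsistent with {kind.value} model")
        p0[idx[s]] = w
    Q = build_rate_matrix(kind, rates, perturbation)
    return p0 @ expm(Q * horizon_h)


def phase_endpoint(
    model_kind: ModelKind | str,
    rates: RateParams,
    start: str | dict[HiddenState, float],
    perturbation: PerturbationSpec | None = None,
    horizon_h: float = 96.0,
) -> PhasePoint:
    """Evolve a starting population to the horizon and marginalize.

    The default 96 h horizon mirrors a 4-day culture endpoint.
    """
    if horizon_h <= 0:
        raise ValueError("horizon_h must be > 0")
    if isinstance(start, str):
        start = start_distribution(model_kind, start)
    p = _evolve(model_kind, rates, start, perturbation, horizon_h)
    states = state_space(model_kind)
    F = np.zeros(4)
    for i, s in enumerate(states):
        F[int(s.observed_class)] += p[i]
    F = np.clip(F, 0.0, None)
    F /= F.sum()
    return PhasePoint(F_n=float(F[0]), F_m=float(F[1] + F[2]), F_b=float(F[3]))


def class_endpoint_probabilities(
    model_kind: ModelKind | str,
    rates: RateParams,
    start: str | dict[HiddenState, float],
    perturbation: PerturbationSpec | None = None,
    horizon_h: float = 96.0,
) -> np.ndarray:
    """Four-way observed-class probabilities at the horizon (CLASS order)."""
    if isinstance(start, str):
        start = start_distribution(model_kind, start)
    p = _evolve(model_kind, rates, start, perturbation, horizon_h)
    states = state_space(model_kind)
    F = np.zeros(4)
    for i, s in enumerate(states):
        F[int(s.observed_class)] += p[i]
    F = np.clip(F, 0.0, None)
    return F / F.sum()


def perturbation_sweep(
    model_kind: ModelKind | str,
    rates: RateParams,
    starts: tuple[str, ...] = START_LABELS,
    perturbation: PerturbationSpec | None = None,
    magnitudes: np.ndarray | None = None,
    horizon_h: float = 96.0,
) -> pd.DataFrame:
    """Endpoints for a graded series of perturbation strengths.

    ``perturbation`` is the full-strength template; magnitude m in [0, 1]
    interpolates its forward reduction and reverse addition linearly (m = 0
    is unperturbed).  Returns a tidy frame (start, magnitude, F_n, F_m, F_b).
    """
    if perturbation is None:
        raise ValueError("a perturbation template is required")
    if magnitudes is None:
        magnitudes = np.linspace(0.0, 1.0, 6)
    rows = []
    for label in starts:
        for m in magnitudes:
            pt = phase_endpoint(
                model_kind, rates, label, perturbation.scaled(float(m)), horizon_h
            )
            rows.append(
                {"start": label, "magnitude": float(m), "F_n": pt.F_n, "F_m": pt.F_m, "F_b": pt.F_b}
            )
    return pd.DataFrame(rows)


def classify_reversion_path(
    model_kind: ModelKind | str,
    rates: RateParams,
    perturbation: PerturbationSpec,
    start: str | dict[HiddenState, float] = "bi",
    horizon_h: float = 96.0,
) -> dict[str, float]:
    """Decompose reversion to non-expression by route.

    The hidden chain is augmented with a "visited a mono-allelic state" flag
    (set on entering any mono-allelic observed state); probability mass in
    non-expressing states at the horizon is then split into mass that
    reverted directly (flag off) versus via a mono-allelic intermediate
    (flag on).
    """
    kind = ModelKind(model_kind)
    states = state_space(kind)
    n = len(states)
    Q = build_rate_matrix(kind, rates, perturbation)
    mono = {ObservedClass.MONO_Y, ObservedClass.MONO_R}

    # augmented space: index = state + flag * n
    Qa = np.zeros((2 * n, 2 * n))
    for i in range(n):
        for j in range(n):
            if i == j or Q[i, j] == 0.0:
                continue
            enters_mono = states[j].observed_class in mono
            # flag 0 source
            j0 = j + n if enters_mono else j
            Qa[i, j0] += Q[i, j]
            # flag 1 source stays flagged
            Qa[i + n, j + n] += Q[i, j]
    for i in range(2 * n):
        Qa[i, i] = -(Qa[i].sum() - Qa[i, i])

    if isinstance(start, str):
        start = start_distribution(kind, start)
    idx = state_index(kind)
    p0 = np.zeros(2 * n)
    for s, w in start.items():
        offset = n if s.observed_class in mono else 0
        p0[idx[s] + offset] = w
    p = p0 @ expm(Qa * horizon_h)

    direct = via_mono = 0.0
    for i, s in enumerate(states):
        if s.observed_class is ObservedClass.NONE:
            direct += p[i]
            via_mono += p[i + n]
    return {
        "direct": float(direct),
        "via_mono": float(via_mono),
        "total": float(direct + via_mono),
    }
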