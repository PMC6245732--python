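"""Monte-Carlo simulation of clonal proliferating lineages.

A clone grows from one progenitor by synchronous divisions every
``division_time`` hours.  Hidden-state switching within a generation is
summarized by the discrete transition matrix P = exp(Q * division_time);
the two daughters of a cell draw their next-generation states independently
from the parent's row of P, consistent with the first-order kinetics of the
underlying switches.

Each clone is scored by the set of observed allelic classes any of its cells
ever exhibits at a generation boundary, and classified as:

- ``single_mono_allelic``: mono-allelic expression from exactly one allele
  (bi-allelic cells may also occur),
- ``mixed_mono_allelic``: mono-allelic expression from both alleles,
- ``bi_allelic_only``: bi-allelic expression without mono-allelic cells,
- ``non_expressing``: no expressing cell observed.

The distribution over the three expressing classes distinguishes the
sequential from the parallel trans-cis architecture even when their bulk
kinetics agree: a parallel-model clone can inherit a cis-activated but
trans-silent allele, predisposing descendants to mono-allelic expression
from that same allele.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
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
    state_space,
)


class CloneClass(str, enum.Enum):
    SINGLE_MONO = "single_mono_allelic"
    MIXED_MONO = "mixed_mono_allelic"
    BI_ONLY = "bi_allelic_only"
    NON_EXPRESSING = "non_expressing"


EXPRESSING_CLONE_CLASSES = (CloneClass.SINGLE_MONO, CloneClass.MIXED_MONO, CloneClass.BI_ONLY)


@dataclass(frozen=True)
class CloneSimConfig:
    division_time: float = 20.0
    n_generations: int = 5
    observe_until: float = 100.0
    n_clones: int = 30_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.division_time <= 0:
            raise ValueError("division_time must be > 0")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")

    @property
    def observed_generations(self) -> int:
        """Number of generation boundaries observed (0 .. G inclusive)."""
        return min(self.n_generations, int(self.observe_until // self.division_time))


def per_generation_transition_matrix(Q: np.ndarray, division_time: float) -> np.ndarray:
    """Discrete per-division transition matrix P = exp(Q * division_time)."""
    if division_time <= 0:
        raise ValueError("division_time must be > 0")
    P = expm(np.asarray(Q, dtype=float) * division_time)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


@dataclass
class CloneRecord:
    """One simulated lineage tree with per-generation hidden states."""

    cells: list[dict]  # cell_id, parent_id, birth_h, division_h, state
    observed_classes: set[ObservedClass]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "cell_id": c["cell_id"],
                    "parent_id": c["parent_id"],
                    "birth_h": c["birth_h"],
                    "division_h": c["division_h"],
                    "state_label": c["state"].label(),
                    "observed_class": c["state"].observed_class.name.lower(),
                }
            )
        return pd.DataFrame(rows)

    def to_indented_text(self) -> str:
        children: dict[int, list[dict]] = {}
        for c in self.cells:
            children.setdefault(c["parent_id"], []).append(c)
        lines: list[str] = []

        def walk(cell, depth):
            lines.append(
                "  " * depth
                + f"cell {cell['cell_id']} [{cell['birth_h']:.0f}-{cell['division_h']:.0f} h] "
                + cell["state"].label()
            )
            for ch in children.get(cell["cell_id"], []):
                walk(ch, depth + 1)

        walk(children[-1][0], 0)
        return "\n".join(lines)


def _sample_rows(P_cum: np.ndarray, states: np.ndarray, rng) -> np.ndarray:
    """Draw one categorical sample per entry of ``states`` from P's rows."""
    u = rng.random(states.shape)
    return (u[..., None] > P_cum[states]).sum(axis=-1)


def path_observation_matrix(
    model_kind: ModelKind | str,
    Q: np.ndarray,
    division_time: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint law of (end state, classes visited) over one generation.

    The hidden chain is augmented with a bitmask of observed classes visited
    since the cell's birth (its birth class included); the augmented
    generator's exponential gives, for each birth state, the exact joint
    distribution of the division-time state and every class the cell passed
    through on the way.  Marginalizing over the mask recovers exp(Q dt), so
    per-generation state dynamics are unchanged; the mask is what lets clone
    scoring see transient intermediates (e.g. a mono-allelic passage on the
    way from silent to bi-allelic), as near-continuous timelapse sampling
    would.

    Returns (P_start, end_state, mask): ``P_start`` is an (n_states, M) row
    distribution over joint outcomes for each birth state; ``end_state`` and
    ``mask`` map outcome columns to their components.
    """
    states = state_space(model_kind)
    n = len(states)
    classes = np.array([int(s.observed_class) for s in states])
    # augmented index: a = s * 16 + mask
    Qa = np.zeros((16 * n, 16 * n))
    for i in range(n):
        for j in range(n):
            if i == j or Q[i, j] == 0.0:
                continue
            for m in range(16):
                Qa[i * 16 + m, j * 16 + (m | (1 << classes[j]))] += Q[i, j]
    np.fill_diagonal(Qa, 0.0)
    Qa[np.arange(16 * n), np.arange(16 * n)] = -Qa.sum(axis=1)
    Pa = expm(Qa * division_time)
    start_rows = np.array([i * 16 + (1 << classes[i]) for i in range(n)])
    P_start = np.clip(Pa[start_rows], 0.0, None)
    P_start /= P_start.sum(axis=1, keepdims=True)
    end_state = np.repeat(np.arange(n), 16)
    mask = np.tile(np.arange(16), n)
    return P_start, end_state, mask


def _simulate_class_flags(
    model_kind: ModelKind | str,
    rates: RateParams,
    init: InitialStateDistribution,
    config: CloneSimConfig,
    perturbation: PerturbationSpec | None = None,
    collect_marginals: bool = False,
    observe: str = "path",
):
    """Vectorized clone simulation.

    Returns (flags, marginals): ``flags`` is a boolean (n_clones, 4) array of
    observed classes seen per clone; ``marginals`` (optional) holds the
    per-generation observed-class cell counts at the generation boundaries,
    shape (G+1, 4).  ``observe='path'`` scores every class a cell visits
    within a generation; ``observe='boundaries'`` scores only the synchronous
    generation-boundary states.
    """
    kind = ModelKind(model_kind)
    states = state_space(kind)
    n = len(states)
    classes = np.array([int(s.observed_class) for s in states])
    Q = build_rate_matrix(kind, rates, perturbation)
    rng = np.random.default_rng(config.rng_seed)
    if observe == "path":
        P_start, end_state, mask = path_observation_matrix(kind, Q, config.division_time)
    elif observe == "boundaries":
        P = per_generation_transition_matrix(Q, config.division_time)
        P_start, end_state = P, np.arange(n)
        mask = 1 << classes
    else:
        raise ValueError("observe must be 'path' or 'boundaries'")
    P_cum = np.cumsum(P_start, axis=1)
    P_cum[:, -1] = 1.0

    p0 = init.as_vector()
    cur = rng.choice(n, size=(config.n_clones, 1), p=p0)
    flags = np.zeros((config.n_clones, 4), dtype=bool)
    G = config.observed_generations
    marginals = np.zeros((G + 1, 4)) if collect_marginals else None

    for g in range(G + 1):
        cls = classes[cur]
        for c in range(4):
            flags[:, c] |= (cls == c).any(axis=1)
        if collect_marginals:
            marginals[g] = np.bincount(cls.ravel(), minlength=4)
        if g < G:
            # the dividing cell's within-generation path is shared by both
            # daughters' histories: sample it once, then the daughters'
            # states at the next boundary are iid given the division state
            outcome = _sample_rows(P_cum, cur, rng)
            seen = mask[outcome]
            for c in range(4):
                flags[:, c] |= ((seen >> c) & 1).astype(bool).any(axis=1)
            cur = np.repeat(end_state[outcome], 2, axis=1)
    return flags, marginals


def simulate_clone(
    model_kind: ModelKind | str,
    rates: RateParams,
    init: InitialStateDistribution,
    config: CloneSimConfig,
    perturbation: PerturbationSpec | None = None,
) -> CloneRecord:
    """Simulate a single lineage tree, keeping the full cell records."""
    kind = ModelKind(model_kind)
    states = state_space(kind)
    Q = build_rate_matrix(kind, rates, perturbation)
    P_start, end_state, mask = path_observation_matrix(kind, Q, config.division_time)
    P_cum = np.cumsum(P_start, axis=1)
    P_cum[:, -1] = 1.0
    rng = np.random.default_rng(config.rng_seed)

    root_state = int(rng.choice(len(states), p=init.as_vector()))
    G = config.observed_generations
    dt = config.division_time
    cells: list[dict] = []
    observed: set[ObservedClass] = set()
    next_id = [0]

    frontier = [(root_state, -1, 0.0)]
    for g in range(G + 1):
        new_frontier = []
        for s, parent, birth in frontier:
            cid = next_id[0]
            next_id[0] += 1
            division = min(birth + dt, config.observe_until)
            cells.append(
                {
                    "cell_id": cid,
                    "parent_id": parent,
                    "birth_h": birth,
                    "division_h": division,
                    "state": states[s],
                }
            )
            observed.add(states[s].observed_class)
            if g < G:
                # one within-generation path per cell; both daughters are
                # born with the division-time state and diverge afterwards
                outcome = int((rng.random() > P_cum[s]).sum())
                for c in range(4):
                    if (mask[outcome] >> c) & 1:
                        observed.add(ObservedClass(c))
                for _ in range(2):
                    new_frontier.append((int(end_state[outcome]), cid, birth + dt))
        frontier = new_frontier
    observed.discard(ObservedClass.NONE)
    return CloneRecord(cells=cells, observed_classes=observed)


def classify_observed(saw_monoY: bool, saw_monoR: bool, saw_bi: bool) -> CloneClass:
    if saw_monoY and saw_monoR:
        return CloneClass.MIXED_MONO
    if saw_monoY or saw_monoR:
        return CloneClass.SINGLE_MONO
    if saw_bi:
        return CloneClass.BI_ONLY
    return CloneClass.NON_EXPRESSING


def classify_clone(record: CloneRecord) -> CloneClass:
    """Score a clone by the expressing classes any cell ever exhibited."""
    seen = record.observed_classes
    return classify_observed(
        ObservedClass.MONO_Y in seen,
        ObservedClass.MONO_R in seen,
        ObservedClass.BI in seen,
    )


@dataclass(frozen=True)
class CloneClassDistribution:
    """Clone-class composition among expressing clones.

    ``fractions`` are over the three expressing classes only; clones with no
    expressing cell are excluded from them but reported in
    ``n_non_expressing``.
    """

    counts: dict[CloneClass, int]
    n_total: int

    @property
    def n_non_expressing(self) -> int:
        return self.counts.get(CloneClass.NON_EXPRESSING, 0)

    @property
    def n_expressing(self) -> int:
        return self.n_total - self.n_non_expressing

    @property
    def fractions(self) -> dict[CloneClass, float]:
        n = self.n_expressing
        if n == 0:
            raise ValueError("no expressing clones; class distribution undefined")
        return {c: self.counts.get(c, 0) / n for c in EXPRESSING_CLONE_CLASSES}

    def to_dict(self) -> dict:
        out = {
            "n_total": self.n_total,
            "n_non_expressing": self.n_non_expressing,
            "counts": {c.value: self.counts.get(c, 0) for c in CloneClass},
        }
        if self.n_expressing > 0:
            out["fractions_expressing"] = {
                c.value: f for c, f in self.fractions.items()
            }
        return out


def clone_class_distribution(
    model_kind: ModelKind | str,
    rates: RateParams,
    init: InitialStateDistribution | None = None,
    config: CloneSimConfig | None = None,
    perturbation: PerturbationSpec | None = None,
    observe: str = "path",
) -> CloneClassDistribution:
    """Class distribution over ``config.n_clones`` simulated clones."""
    if init is None:
        init = naive_init(model_kind)
    if config is None:
        config = CloneSimConfig()
    flags, _ = _simulate_class_flags(
        model_kind, rates, init, config, perturbation, observe=observe
    )
    saw_y, saw_r, saw_b = flags[:, 1], flags[:, 2], flags[:, 3]
    counts = {
        CloneClass.MIXED_MONO: int((saw_y & saw_r).sum()),
        CloneClass.SINGLE_MONO: int((saw_y ^ saw_r).sum()),
        CloneClass.BI_ONLY: int((~saw_y & ~saw_r & saw_b).sum()),
    }
    counts[CloneClass.NON_EXPRESSING] = config.n_clones - sum(counts.values())
    return CloneClassDistribution(counts=counts, n_total=config.n_clones)


def simulated_cell_marginals(
    model_kind: ModelKind | str,
    rates: RateParams,
    init: InitialStateDistribution,
    config: CloneSimConfig,
    perturbation: PerturbationSpec | None = None,
) -> np.ndarray:
    """Observed-class cell-count fractions per generation, shape (G+1, 4).

    The lineage simulator and the matrix-exponential population solution
    describe the same Markov process, so these marginals agree with
    :func:`alleledyn.state_models.population_fractions` at the generation
    boundary times up to Monte-Carlo error.
    """
    _, marg = _simulate_class_flags(
        model_kind, rates, init, config, perturbation, collect_marginals=True
    )
    return marg / marg.sum(axis=1, keepdims=True)


def clone_class_chi2(
    observed_count: int,
    n_clones_observed: int,
    expected_fraction: float,
    form: str = "single",
) -> tuple[float, float]:
    """Goodness-of-fit statistic for an observed clone-class count.

    ``form='single'`` is the one-category statistic (O - E)^2 / E with
    E = n * p, compared against chi-squared with 1 d.f.; ``form='pearson'``
    adds the complementary category's term.  The one-category form is the
    default; the Pearson form is provided for comparison (the two differ by
    the factor 1/(1-p)).  Returns (statistic, p_value).
    """
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected_fraction must be strictly between 0 and 1")
    if not 0 <= observed_count <= n_clones_observed:
        raise ValueError("observed_count must be between 0 and n_clones_observed")
    E = n_clones_observed * expected_fraction
    stat = (observed_count - E) ** 2 / E
    if form == "pearson":
        E2 = n_clones_observed - E
        stat += (n_clones_observed - observed_count - E2) ** 2 / E2
    elif form != "single":
        raise ValueError("form must be 'single' or 'pearson'")
    p = float(stats.chi2.sf(stat, df=1))
    return float(stat), p
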