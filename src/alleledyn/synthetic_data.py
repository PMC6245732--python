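"""Synthetic two-color timelapse and snapshot data generator.

Emulates the statistical structure of segmented single-cell imaging data of
a two-color allelic reporter: clonal lineages dividing every ~20 h, each
cell's hidden allelic state switching in continuous time with exact
exponential waiting times, and per-frame (YFP, mCherry) intensities drawn
from class-conditional Gaussians.  After an allele's expression onset, its
channel's mean intensity rises toward the active level as
1 - exp(-(t - t_on) / maturation_tau), emulating fluorescent-protein
accumulation; this is what produces the ~15-20 h detection delay the
analysis pipeline must estimate and correct for.

The generator shares its hidden-state dynamics with
:mod:`alleledyn.state_models`, so every downstream stage can be validated
against exact ground truth.  It does not emulate cell movement, tracking
gaps, segmentation errors, or feeder-cell autofluorescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixture_quantify import GaussianComponent
from .perturbation_phase import class_endpoint_probabilities
from .state_models import (
    CLASS_LABELS,
    HiddenState,
    InitialStateDistribution,
    ModelKind,
    PerturbationSpec,
    RateParams,
    build_rate_matrix,
    naive_init,
    state_index,
    state_space,
)


def default_class_components() -> dict[str, GaussianComponent]:
    """Intensity components in arbitrary units.

    The non-expressing component sits near the origin; active channels are
    10 of its SDs away, matching clearly separable reporter populations.
    """
    lo, hi = 100.0, 400.0
    s_lo, s_hi = 30.0, 60.0
    return {
        "none": GaussianComponent(1.0, lo, lo, s_lo, s_lo),
        "monoY": GaussianComponent(1.0, lo, hi, s_lo, s_hi),
        "monoR": GaussianComponent(1.0, hi, lo, s_hi, s_lo),
        "bi": GaussianComponent(1.0, hi, hi, s_hi, s_hi),
    }


@dataclass(frozen=True)
class FluorescenceModel:
    """Class-conditional intensity model with maturation kinetics.

    ``maturation_tau`` (hours) is the exponential-approach time constant for
    intensity rise after expression onset; with the default intensity scale
    it induces an effective detection lag near ``detect_lag_target``.
    """

    class_components: dict[str, GaussianComponent] = field(
        default_factory=default_class_components
    )
    maturation_tau: float = 23.0
    detect_lag_target: float = 16.0

    def __post_init__(self) -> None:
        missing = [c for c in CLASS_LABELS if c not in self.class_components]
        if missing:
            raise ValueError(f"class_components missing classes: {missing}")
        if self.maturation_tau < 0:
            raise ValueError("maturation_tau must be >= 0")


def default_movie_init() -> InitialStateDistribution:
    """Starting population of sorted non-expressing progenitors.

    Sorting on fluorescence cannot exclude hidden pre-activated sub-states:
    some cells already carry a cis-activated allele (or an active trans
    factor) without detectable reporter signal.  This is what makes the
    earliest expressing cells discernible within hours of plating while the
    measured population fractions still lag by the fluorophore maturation
    time.  Weights are a realistic mix for a progenitor stage in which
    activation is already under way; all states are non-expressing.
    """
    return InitialStateDistribution(
        ModelKind.PARALLEL,
        {
            HiddenState(False, False, False): 0.55,
            HiddenState(False, True, False): 0.07,
            HiddenState(False, False, True): 0.07,
            HiddenState(False, True, True): 0.03,
            HiddenState(True, False, False): 0.28,
        },
    )


@dataclass(frozen=True)
class MovieSpec:
    """Study-condition defaults: ~200 starting clones followed for 105 h at
    ~1 h frame intervals, dividing every 20 h."""

    model_kind: ModelKind = ModelKind.PARALLEL
    rates: RateParams = field(default_factory=lambda: RateParams(kC=0.004, kT=0.012))
    init: InitialStateDistribution | None = None
    division_time: float = 20.0
    horizon_h: float = 105.0
    frame_interval_h: float = 1.0
    n_clones: int = 200
    rng_seed: int = 0
    fluorescence: FluorescenceModel = field(default_factory=FluorescenceModel)

    def __post_init__(self) -> None:
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be > 0")
        if self.init is None:
            if ModelKind(self.model_kind) is ModelKind.PARALLEL:
                object.__setattr__(self, "init", default_movie_init())
            else:
                object.__setattr__(self, "init", naive_init(self.model_kind))


def _gillespie_path(state_i, t0, t1, Q, rng):
    """Exact jump path of one cell over [t0, t1]; list of (time, state)."""
    path = [(t0, state_i)]
    t, s = t0, state_i
    while True:
        exit_rate = -Q[s, s]
        if exit_rate <= 0:
            break
        t = t + rng.exponential(1.0 / exit_rate)
        if t >= t1:
            break
        probs = np.clip(Q[s], 0.0, None)
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(len(probs), p=probs))
        path.append((t, s))
    return path


def _channel_on_time(path, states, channel: str) -> float:
    """First time the cell's state expresses the channel, inf if never."""
    for t, si in path:
        s = states[si]
        on = s.trans and (s.cisY if channel == "yfp" else s.cisR)
        if on:
            return t
    return np.inf


def generate_movie(spec: MovieSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a timelapse movie; returns (tracks, ground_truth).

    ``tracks`` has one row per live cell per frame: clone_id, cell_id,
    parent_id, time_h, yfp, mch.  ``ground_truth`` has one row per cell per
    constant-state interval, with the hidden flags, observed class, and the
    cell's channel onset times.  Two runs with the same spec are identical.
    """
    kind = ModelKind(spec.model_kind)
    states = state_space(kind)
    Q = build_rate_matrix(kind, spec.rates)
    rng = np.random.default_rng(spec.rng_seed)
    fluo = spec.fluorescence
    comp = fluo.class_components
    mu_off = np.array([comp["none"].mu_y, comp["none"].mu_r])
    mu_on = np.array([comp["monoY"].mu_y, comp["monoR"].mu_r])
    sd_off = np.array([comp["none"].sigma_y, comp["none"].sigma_r])
    sd_on = np.array([comp["monoY"].sigma_y, comp["monoR"].sigma_r])

    p0 = spec.init.as_vector()
    frame_times = np.arange(0.0, spec.horizon_h + 1e-9, spec.frame_interval_h)
    track_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    for clone in range(spec.n_clones):
        root = int(rng.choice(len(states), p=p0))
        next_id = [0]
        # frontier entries: (state, parent_id, birth, inherited channel on-times)
        frontier = [(root, -1, 0.0, np.array([np.inf, np.inf]))]
        while frontier:
            new_frontier = []
            for s, parent, birth, t_on in frontier:
                if birth >= spec.horizon_h:
                    continue
                cid = next_id[0]
                next_id[0] += 1
                end = min(birth + spec.division_time, spec.horizon_h)
                path = _gillespie_path(s, birth, end, Q, rng)
                t_on = t_on.copy()
                for ch_i, ch in enumerate(("yfp", "mch")):
                    if not np.isfinite(t_on[ch_i]):
                        t_on[ch_i] = _channel_on_time(path, states, ch)
                # ground truth: one row per constant-state interval
                for k, (t_k, si) in enumerate(path):
                    t_next = path[k + 1][0] if k + 1 < len(path) else end
                    st = states[si]
                    truth_rows.append(
                        (clone, cid, parent, t_k, t_next, int(st.trans), int(st.cisY),
                         int(st.cisR), CLASS_LABELS[int(st.observed_class)],
                         t_on[0] if np.isfinite(t_on[0]) else np.nan,
                         t_on[1] if np.isfinite(t_on[1]) else np.nan)
                    )
                # frames while this cell is alive
                mask = (frame_times >= birth) & (frame_times < end)
                ft = frame_times[mask]
                if len(ft):
                    if fluo.maturation_tau > 0:
                        frac = 1.0 - np.exp(
                            -np.clip(ft[:, None] - t_on[None, :], 0.0, None)
                            / fluo.maturation_tau
                        )
                    else:
                        frac = (ft[:, None] >= t_on[None, :]).astype(float)
                    frac[~np.isfinite(np.broadcast_to(t_on, frac.shape))] = 0.0
                    mean = mu_off + frac * (mu_on - mu_off)
                    sd = sd_off + frac * (sd_on - sd_off)
                    noise = rng.standard_normal(mean.shape)
                    inten = mean + sd * noise
                    for f_i, t_f in enumerate(ft):
                        track_rows.append(
                            (clone, cid, parent, float(t_f),
                             float(inten[f_i, 0]), float(inten[f_i, 1]))
                        )
                if end < spec.horizon_h:
                    s_end = path[-1][1]
                    for _ in range(2):
                        new_frontier.append((s_end, cid, end, t_on.copy()))
            frontier = new_frontier

    tracks = pd.DataFrame(
        track_rows,
        columns=["clone_id", "cell_id", "parent_id", "time_h", "yfp", "mch"],
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "clone_id", "cell_id", "parent_id", "t_start_h", "t_end_h",
            "trans", "cisY", "cisR", "observed_class", "t_on_yfp", "t_on_mch",
        ],
    )
    return tracks, truth


def true_class_fractions(truth: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    """Ground-truth observed-class fractions at given times, shape (n_t, 4)."""
    out = np.zeros((len(times), 4))
    cls_idx = {c: i for i, c in enumerate(CLASS_LABELS)}
    t_start = truth["t_start_h"].to_numpy(float)
    t_end = truth["t_end_h"].to_numpy(float)
    cls = truth["observed_class"].map(cls_idx).to_numpy(int)
    for k, t in enumerate(np.asarray(times, dtype=float)):
        alive = (t_start <= t) & (t < t_end)
        if alive.sum() == 0:
            continue
        out[k] = np.bincount(cls[alive], minlength=4) / alive.sum()
    return out


def generate_snapshot(
    model_kind: ModelKind | str,
    rates: RateParams,
    start: str = "none",
    horizon_h: float = 96.0,
    n_cells: int = 10_000,
    fluorescence: FluorescenceModel | None = None,
    rng_seed: int = 0,
    perturbation: PerturbationSpec | None = None,
) -> pd.DataFrame:
    """Endpoint snapshot table (flow-cytometry-like), one row per cell.

    Terminal class labels are drawn from the exact endpoint distribution;
    intensities come from the class components at full maturation.
    Columns: yfp, mch, true_class.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if fluorescence is None:
        fluorescence = FluorescenceModel()
    probs = class_endpoint_probabilities(
        model_kind, rates, start, perturbation, horizon_h
    )
    rng = np.random.default_rng(rng_seed)
    labels = rng.choice(4, size=n_cells, p=probs)
    yfp = np.empty(n_cells)
    mch = np.empty(n_cells)
    for i, name in enumerate(CLASS_LABELS):
        m = labels == i
        if not m.any():
            continue
        c = fluorescence.class_components[name]
        z = rng.standard_normal((m.sum(), 2))
        z2 = c.rho * z[:, 0] + np.sqrt(1 - c.rho**2) * z[:, 1]
        mch[m] = c.mu_r + c.sigma_r * z[:, 0]
        yfp[m] = c.mu_y + c.sigma_y * z2
    return pd.DataFrame(
        {
            "yfp": yfp,
            "mch": mch,
            "true_class": [CLASS_LABELS[i] for i in labels],
        }
    )
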