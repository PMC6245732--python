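"""Delay-corrected least-squares fitting and model comparison.

Fluorescent reporters take time to accumulate to detectability, so the
measured fraction of each expressing class lags the underlying state
switching by a class-specific detection delay tau_i.  Fitting therefore
proceeds in two stages: delays are estimated from the data as the first time
each class rises significantly above zero (:func:`estimate_delays`), then the
model's class-i prediction is evaluated at t - tau_i and the switching rates
(and free initial-state weights) are fitted by weighted least squares.

Fit quality is scored by the reduced chi-squared (sum of squared
standardized residuals over degrees of freedom); competing models are
compared by the ratio of their reduced chi-squared values under the
F distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .mixture_quantify import FractionSeries
from .state_models import (
    CLASS_LABELS,
    HiddenState,
    InitialStateDistribution,
    ModelKind,
    ObservedClass,
    RateParams,
    naive_init,
    population_fractions,
)

EXPRESSING = (ObservedClass.MONO_Y, ObservedClass.MONO_R, ObservedClass.BI)


@dataclass(frozen=True)
class DelayVector:
    """Per-class detection delays in hours (the none class has none)."""

    tau: np.ndarray  # length 4, tau[0] == 0
    flagged: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        if tau.shape != (4,) or tau[0] != 0 or np.any(tau < 0):
            raise ValueError("tau must be 4 non-negative values with tau[none] = 0")
        object.__setattr__(self, "tau", tau)

    @classmethod
    def zero(cls) -> "DelayVector":
        return cls(np.zeros(4))


def estimate_delays(series: FractionSeries, z_threshold: float = 2.0) -> DelayVector:
    """First bin at which each expressing class is significantly nonzero.

    A class's delay is the earliest bin center where f > z * df both there
    and in the following bin (persistence guard against single-bin noise; the
    final bin needs no successor).  Classes that never cross are assigned the
    last bin center and flagged.
    """
    if len(series.bin_centers) < 3:
        raise ValueError("delay estimation needs at least 3 time bins")
    tau = np.zeros(4)
    flagged = []
    n = len(series.bin_centers)
    for cls in EXPRESSING:
        i = int(cls)
        above = series.f_obs[:, i] > z_threshold * series.df_obs[:, i]
        hit = None
        for j in range(n):
            if above[j] and (j == n - 1 or above[j + 1]):
                hit = j
                break
        if hit is None:
            hit = n - 1
            flagged.append(CLASS_LABELS[i])
        tau[i] = series.bin_centers[hit]
    return DelayVector(tau, tuple(flagged))


def delayed_model_series(
    model_kind: ModelKind | str,
    rates: RateParams,
    init: InitialStateDistribution,
    delays: DelayVector,
    times: np.ndarray,
) -> np.ndarray:
    """Predicted class fractions with per-class detection delays.

    Class i's prediction at t is the undelayed model at t - tau_i (clamped to
    the initial condition for t < tau_i); the non-expressing fraction is
    rebuilt as 1 minus the expressing classes so each row still sums to 1.
    """
    times = np.asarray(times, dtype=float)
    out = np.zeros((len(times), 4))
    for cls in EXPRESSING:
        i = int(cls)
        shifted = np.clip(times - delays.tau[i], 0.0, None)
        traj = population_fractions(model_kind, rates, init, shifted)
        out[:, i] = traj.fractions[:, i]
    out[:, 0] = 1.0 - out[:, 1:].sum(axis=1)
    return out


@dataclass(frozen=True)
class FitResult:
    model_kind: ModelKind
    rates: RateParams
    init: InitialStateDistribution
    delays: DelayVector
    chi2_red: float
    dof: int
    n_points: int
    n_free: int
    sse: float
    param_names: tuple[str, ...]
    param_values: np.ndarray
    param_cov: np.ndarray | None
    seed: int

    def to_dict(self) -> dict:
        return {
            "model": self.model_kind.value,
            "kC": self.rates.kC,
            "kT": self.rates.kT,
            "init": {s.label(): w for s, w in self.init.weights.items()},
            "delays_h": {
                CLASS_LABELS[i]: float(self.delays.tau[i]) for i in range(1, 4)
            },
            "chi2_red": self.chi2_red,
            "dof": self.dof,
            "n_points": self.n_points,
            "n_free": self.n_free,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _free_parametrization(kind: ModelKind):
    """Free-parameter names and (init-distribution builder, rate builder).

    cis_only: kC only.  sequential: kC, kT and the weight of the trans-done
    non-expressing state.  parallel: kC, kT and four non-negative weights u
    for the non-naive non-expressing states, mapped to the simplex by
    w_i = u_i / (1 + sum u) with the naive state taking 1 / (1 + sum u).
    """
    if kind is ModelKind.CIS_ONLY:
        names = ("kC",)

        def build(p):
            return RateParams(kC=p[0]), naive_init(kind)

        lo, hi = [1e-6], [1.0]
    elif kind is ModelKind.SEQUENTIAL:
        names = ("kC", "kT", "w_trans_on")

        def build(p):
            w = p[2]
            init = InitialStateDistribution(
                kind,
                {
                    HiddenState(False, False, False): 1.0 - w,
                    HiddenState(True, False, False): w,
                },
            )
            return RateParams(kC=p[0], kT=p[1]), init

        lo, hi = [1e-6, 1e-6, 0.0], [1.0, 5.0, 1.0]
    else:
        nonnaive = [
            HiddenState(False, True, False),
            HiddenState(False, False, True),
            HiddenState(False, True, True),
            HiddenState(True, False, False),
        ]
        names = ("kC", "kT", "u_cisY", "u_cisR", "u_cisYR", "u_trans")

        def build(p):
            u = np.asarray(p[2:6])
            denom = 1.0 + u.sum()
            weights = {HiddenState(False, False, False): 1.0 / denom}
            for s, ui in zip(nonnaive, u):
                weights[s] = ui / denom
            return RateParams(kC=p[0], kT=p[1]), InitialStateDistribution(kind, weights)

        lo, hi = [1e-6, 1e-6, 0.0, 0.0, 0.0, 0.0], [1.0, 5.0, 20.0, 20.0, 20.0, 20.0]
    return names, build, np.array(lo), np.array(hi)


def _residual_mask(series: FractionSeries, delays: DelayVector, include_none: bool):
    """(class index, time index) pairs entering the chi-squared sum."""
    classes = [int(c) for c in EXPRESSING] + ([0] if include_none else [])
    pairs = []
    for i in classes:
        for j, t in enumerate(series.bin_centers):
            if series.df_obs[j, i] <= 0:
                continue
            if i != 0 and t < delays.tau[i]:
                continue
            pairs.append((i, j))
    return pairs


def fit_model(
    model_kind: ModelKind | str,
    series: FractionSeries,
    delays: DelayVector | None = None,
    start_params: np.ndarray | None = None,
    n_restarts: int = 20,
    seed: int = 0,
    include_none: bool = False,
) -> FitResult:
    """Weighted least-squares fit of one model to a fraction series.

    Residuals are (prediction - observation) / uncertainty over the
    expressing classes (optionally also the non-expressing class), excluding
    each class's points before its detection delay.  The optimizer is bounded
    trust-region least squares restarted from ``n_restarts`` Latin-hypercube
    points (the rate likelihood has plateaus at extreme trans rates).
    """
    kind = ModelKind(model_kind)
    if delays is None:
        delays = estimate_delays(series)
    names, build, lo, hi = _free_parametrization(kind)
    pairs = _residual_mask(series, delays, include_none)
    n_points = len(pairs)
    n_free = len(names)
    dof = n_points - n_free
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom ({n_points} points, {n_free} params)")
    cls_idx = np.array([p[0] for p in pairs])
    t_idx = np.array([p[1] for p in pairs])
    obs = series.f_obs[t_idx, cls_idx]
    err = series.df_obs[t_idx, cls_idx]

    def resid(p):
        rates, init = build(p)
        pred = delayed_model_series(kind, rates, init, delays, series.bin_centers)
        return (pred[t_idx, cls_idx] - obs) / err

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=n_free, seed=rng)
    # log-uniform starts for the rates, uniform for weight parameters
    unit = sampler.random(n_restarts)
    starts = []
    if start_params is not None:
        starts.append(np.asarray(start_params, dtype=float))
    for row in unit:
        p = np.empty(n_free)
        for k, name in enumerate(names):
            if name in ("kC", "kT"):
                p[k] = 10.0 ** (-4 + 3.5 * row[k])  # 1e-4 .. ~0.3 per hour
            else:
                p[k] = lo[k] + row[k] * (min(hi[k], 3.0) - lo[k])
            p[k] = min(max(p[k], lo[k]), hi[k])
        starts.append(p)

    best = None
    failures = []
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", x_scale="jac")
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(str(exc))
            continue
        if sol.status <= 0:
            failures.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"all {len(starts)} fit restarts failed: {failures[:3]}")

    sse = float(2.0 * best.cost)
    J = best.jac
    try:
        cov = (sse / dof) * np.linalg.pinv(J.T @ J)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = None
    rates, init = build(best.x)
    return FitResult(
        model_kind=kind,
        rates=rates,
        init=init,
        delays=delays,
        chi2_red=sse / dof,
        dof=dof,
        n_points=n_points,
        n_free=n_free,
        sse=sse,
        param_names=names,
        param_values=best.x.copy(),
        param_cov=cov,
        seed=seed,
    )


@dataclass(frozen=True)
class ModelComparison:
    """F-ratio of two fits' reduced chi-squared values (worse / better)."""

    worse: ModelKind
    better: ModelKind
    F_value: float
    p_value: float
    dof_worse: int
    dof_better: int

    def to_dict(self) -> dict:
        return {
            "worse_model": self.worse.value,
            "better_model": self.better.value,
            "F": self.F_value,
            "p": self.p_value,
            "dof": [self.dof_worse, self.dof_better],
        }


def compare_models(fit_a: FitResult, fit_b: FitResult) -> ModelComparison:
    """F-test on the ratio of reduced chi-squared values.

    The fit with larger chi2_red is the numerator, so F >= 1; the p-value is
    the F-distribution tail with the two fits' degrees of freedom.  A perfect
    reference fit yields an infinite F (reported as such).
    """
    worse, better = (fit_a, fit_b) if fit_a.chi2_red >= fit_b.chi2_red else (fit_b, fit_a)
    if better.chi2_red == 0.0:
        if worse.chi2_red == 0.0:
            return ModelComparison(worse.model_kind, better.model_kind, 1.0, 1.0,
                                   worse.dof, better.dof)
        return ModelComparison(worse.model_kind, better.model_kind, float("inf"), 0.0,
                               worse.dof, better.dof)
    F = worse.chi2_red / better.chi2_red
    p = float(stats.f.sf(F, worse.dof, better.dof))
    return ModelComparison(worse.model_kind, better.model_kind, float(F), p,
                           worse.dof, better.dof)


def read_fraction_table_ci(path, sep: str | None = None) -> FractionSeries:
    """Read a fractions-with-95%-CI table into a :class:`FractionSeries`.

    Expected layout: a time column (``time_h`` or ``bin_center_h``) and, per
    class, columns ``f_<class>`` and ``ci_<class>`` holding the fraction and
    its 95% confidence half-width; uncertainties are recovered as CI / 1.96.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    tcol = "time_h" if "time_h" in df.columns else "bin_center_h"
    if tcol not in df.columns:
        raise ValueError("fraction table needs a 'time_h' or 'bin_center_h' column")
    f = np.zeros((len(df), 4))
    dfv = np.zeros((len(df), 4))
    for i, c in enumerate(CLASS_LABELS):
        if f"f_{c}" not in df.columns:
            raise ValueError(f"fraction table missing column 'f_{c}'")
        f[:, i] = df[f"f_{c}"].to_numpy(float)
        ci_col = f"ci_{c}"
        if ci_col in df.columns:
            dfv[:, i] = df[ci_col].to_numpy(float) / 1.96
    n = df["n_cells"].to_numpy(int) if "n_cells" in df.columns else np.zeros(len(df), int)
    return FractionSeries(
        bin_centers=df[tcol].to_numpy(float), f_obs=f, df_obs=dfv, n_cells=n
    )
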