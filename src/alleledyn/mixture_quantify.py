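"""Population-fraction quantification from two-channel intensity tables.

Single cells carry a (mCherry, YFP) intensity pair.  The population at any
time is modeled as a four-component bivariate Gaussian mixture, one
component per allelic expression class (non-expressing, mono-YFP,
mono-mCherry, bi-allelic).  Quantification is a constrained two-step
histogram fit:

1. :func:`fit_negative_anchor` fits the non-expressing component's shape
   (means, SDs, correlation) to cells from an early time window known to be
   non-expressing; this shape is then frozen.
2. :func:`fit_timebin` fits the full four-component mixture to the 2-D
   intensity histogram of each time bin by nonlinear least squares, with the
   anchor's shape fixed (only its weight free) and the other components'
   parameters bounded to their expected intensity quadrants.

Class fractions are the normalized component weights f_i = N_i / sum_j N_j,
with uncertainties propagated from the least-squares weight covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .state_models import CLASS_LABELS

REQUIRED_COLUMNS = ("time_h", "yfp", "mch")


class DegenerateDataError(ValueError):
    """Raised when intensity data cannot support a Gaussian fit."""


class FitConvergenceError(RuntimeError):
    """Raised when the mixture optimizer fails to converge."""


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component over (mCherry, YFP) intensity.

    ``N`` is the volume under the component (a cell count when fitted to a
    count histogram); ``rho`` the channel correlation.
    """

    N: float
    mu_r: float
    mu_y: float
    sigma_r: float
    sigma_y: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.sigma_r <= 0 or self.sigma_y <= 0:
            raise ValueError("sigmas must be > 0")
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")


def bivariate_gaussian(r, y, component: GaussianComponent) -> np.ndarray:
    """N-scaled bivariate normal density at (r, y); integrates to N."""
    c = component
    zr = (np.asarray(r, dtype=float) - c.mu_r) / c.sigma_r
    zy = (np.asarray(y, dtype=float) - c.mu_y) / c.sigma_y
    q = 1.0 - c.rho**2
    norm = c.N / (2.0 * np.pi * c.sigma_r * c.sigma_y * np.sqrt(q))
    return norm * np.exp(-(zr**2 - 2.0 * c.rho * zr * zy + zy**2) / (2.0 * q))


@dataclass(frozen=True)
class MixtureFitResult:
    """Four fitted components in (none, monoY, monoR, bi) order."""

    components: tuple[GaussianComponent, ...]
    dN: np.ndarray
    fit_residual: float
    n_cells: int
    flags: tuple[str, ...] = ()

    @property
    def N(self) -> np.ndarray:
        return np.array([c.N for c in self.components])

    @property
    def fractions(self) -> np.ndarray:
        N = self.N
        return N / N.sum()


@dataclass
class FractionSeries:
    """Time-binned class fractions with uncertainties."""

    bin_centers: np.ndarray
    f_obs: np.ndarray  # (n_bins, 4)
    df_obs: np.ndarray  # (n_bins, 4)
    n_cells: np.ndarray
    flags: list[str] = field(default_factory=list)

    _COLUMNS = (
        ["bin_center_h", "n_cells"]
        + [f"f_{c}" for c in CLASS_LABELS]
        + [f"df_{c}" for c in CLASS_LABELS]
    )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin_center_h": self.bin_centers, "n_cells": self.n_cells})
        for i, c in enumerate(CLASS_LABELS):
            df[f"f_{c}"] = self.f_obs[:, i]
        for i, c in enumerate(CLASS_LABELS):
            df[f"df_{c}"] = self.df_obs[:, i]
        return df[list(self._COLUMNS)]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FractionSeries":
        missing = [c for c in cls._COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fraction table missing columns: {missing}")
        return cls(
            bin_centers=df["bin_center_h"].to_numpy(float),
            f_obs=df[[f"f_{c}" for c in CLASS_LABELS]].to_numpy(float),
            df_obs=df[[f"df_{c}" for c in CLASS_LABELS]].to_numpy(float),
            n_cells=df["n_cells"].to_numpy(int),
        )

    @classmethod
    def from_tsv(cls, path) -> "FractionSeries":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def read_tracks(path, sep: str | None = None) -> pd.DataFrame:
    """Read a cell-intensity table (CSV/TSV) and validate its schema."""
    df = pd.read_csv(path, sep=sep, engine="python")
    return validate_tracks(df)


def validate_tracks(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"tracks table missing required column '{col}'")
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            raise ValueError(
                f"non-numeric values in column '{col}' at rows {list(bad[:5])}"
            )
    return df


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    if transform == "linear":
        return values
    if transform == "arcsinh":
        return np.arcsinh(values)
    raise ValueError(f"unknown intensity transform: {transform!r}")


def _histogram(r, y, n_bins, ranges=None):
    """2-D count histogram plus bin-center grids and the bin area."""
    if ranges is None:
        pad_r = 0.05 * (r.max() - r.min() + 1e-12)
        pad_y = 0.05 * (y.max() - y.min() + 1e-12)
        ranges = ((r.min() - pad_r, r.max() + pad_r), (y.min() - pad_y, y.max() + pad_y))
    H, r_edges, y_edges = np.histogram2d(r, y, bins=n_bins, range=ranges)
    rc = 0.5 * (r_edges[:-1] + r_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    rg, yg = np.meshgrid(rc, yc, indexing="ij")
    area = (r_edges[1] - r_edges[0]) * (y_edges[1] - y_edges[0])
    return H, rg, yg, area


def _moments(r: np.ndarray, y: np.ndarray) -> GaussianComponent:
    sr, sy = r.std(ddof=1), y.std(ddof=1)
    if sr <= 0 or sy <= 0:
        raise DegenerateDataError("zero variance in an intensity channel")
    rho = float(np.corrcoef(r, y)[0, 1])
    rho = float(np.clip(rho, -0.95, 0.95))
    return GaussianComponent(float(len(r)), r.mean(), y.mean(), sr, sy, rho)


def fit_negative_anchor(
    cells: pd.DataFrame,
    min_cells: int = 100,
    n_bins: int = 64,
    transform: str = "linear",
) -> GaussianComponent:
    """Fit the non-expressing component's shape to early-window cells.

    A single bivariate Gaussian is fitted to the 2-D intensity histogram,
    initialized at the sample moments.  The returned shape (means, SDs,
    correlation) is frozen for all subsequent time-bin fits.
    """
    cells = validate_tracks(cells) if isinstance(cells, pd.DataFrame) else cells
    r = _transform(cells["mch"].to_numpy(float), transform)
    y = _transform(cells["yfp"].to_numpy(float), transform)
    if len(r) < min_cells:
        raise DegenerateDataError(f"anchor fit needs >= {min_cells} cells, got {len(r)}")
    start = _moments(r, y)
    H, rg, yg, area = _histogram(r, y, n_bins)

    def resid(p):
        comp = GaussianComponent(p[0], p[1], p[2], p[3], p[4], p[5])
        model = bivariate_gaussian(rg, yg, comp) * area
        return (model - H).ravel()

    lo = [0.0, rg.min(), yg.min(), 0.2 * start.sigma_r, 0.2 * start.sigma_y, -0.95]
    hi = [10.0 * start.N, rg.max(), yg.max(), 5.0 * start.sigma_r, 5.0 * start.sigma_y, 0.95]
    p0 = [start.N, start.mu_r, start.mu_y, start.sigma_r, start.sigma_y, start.rho]
    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf")
    if sol.status <= 0:
        warnings.warn("anchor histogram fit did not converge; using moment estimates")
        return start
    p = sol.x
    return GaussianComponent(p[0], p[1], p[2], p[3], p[4], p[5])


@dataclass(frozen=True)
class ComponentBounds:
    """Per-component parameter boxes for the constrained mixture fit."""

    mu_r: tuple[float, float]
    mu_y: tuple[float, float]
    sigma_r: tuple[float, float]
    sigma_y: tuple[float, float]
    rho: tuple[float, float] = (-0.95, 0.95)


def _active_location(values: np.ndarray, thr: float, anchor_sd: float):
    """Center/scale of the matured expressing population in one channel.

    Above-threshold intensities are a matured mode contaminated from below
    by still-maturing cells, so the center is taken as the histogram mode
    and the scale from the upper tail (97.5th percentile), both insensitive
    to the one-sided smear.
    """
    active = values[values > thr]
    if len(active) < 50:
        return None
    counts, edges = np.histogram(active, bins=32)
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    k = int(np.argmax(smooth))
    m = float(0.5 * (edges[k] + edges[k + 1]))
    s = float((np.quantile(active, 0.975) - m) / 1.96)
    return m, max(s, 0.5 * anchor_sd)


def default_bounds(
    anchor: GaussianComponent, r: np.ndarray, y: np.ndarray
) -> dict[str, ComponentBounds]:
    """Component boxes from the observed fluorescence distributions.

    Channel thresholds sit at the anchor mean + 3 SD.  Each expressing
    component's active-channel mean is bounded around the robust center of
    the above-threshold intensities in that channel (so a sparsely populated
    time bin cannot park an expressing component on top of the non-expressing
    blob), and its SD to at most twice their robust scale; off channels use
    the anchor's geometry with SDs in [0.3, 3] x the anchor's.  Pass the
    whole experiment's intensities here, not a single bin's.
    """
    thr_r = anchor.mu_r + 3.0 * anchor.sigma_r
    thr_y = anchor.mu_y + 3.0 * anchor.sigma_y
    r_lo, r_hi = min(r.min(), anchor.mu_r - anchor.sigma_r), r.max() + anchor.sigma_r
    y_lo, y_hi = min(y.min(), anchor.mu_y - anchor.sigma_y), y.max() + anchor.sigma_y
    s_r_off = (0.3 * anchor.sigma_r, 3.0 * anchor.sigma_r)
    s_y_off = (0.3 * anchor.sigma_y, 3.0 * anchor.sigma_y)

    act_r = _active_location(r, thr_r, anchor.sigma_r)
    act_y = _active_location(y, thr_y, anchor.sigma_y)
    # an expressing component's center must sit clearly off the blob
    floor_r = anchor.mu_r + 4.0 * anchor.sigma_r
    floor_y = anchor.mu_y + 4.0 * anchor.sigma_y
    if act_r is None:
        r_on, sr_on = (floor_r, r_hi), (0.3 * anchor.sigma_r, 2.0 * anchor.sigma_r)
    else:
        m, s = act_r
        r_on = (max(floor_r, m - 2 * s), max(r_hi, m + 2 * s))
        sr_on = (0.3 * anchor.sigma_r, 1.5 * s)
    if act_y is None:
        y_on, sy_on = (floor_y, y_hi), (0.3 * anchor.sigma_y, 2.0 * anchor.sigma_y)
    else:
        m, s = act_y
        y_on = (max(floor_y, m - 2 * s), max(y_hi, m + 2 * s))
        sy_on = (0.3 * anchor.sigma_y, 1.5 * s)

    return {
        "monoY": ComponentBounds((r_lo, thr_r), y_on, s_r_off, sy_on),
        "monoR": ComponentBounds(r_on, (y_lo, thr_y), sr_on, s_y_off),
        "bi": ComponentBounds(r_on, y_on, sr_on, sy_on),
    }


def _initial_components(r, y, anchor, bounds) -> list[GaussianComponent]:
    """Quadrant-moment starting point for the three expressing components."""
    thr_r = bounds["monoY"].mu_r[1]
    thr_y = bounds["monoR"].mu_y[1]
    masks = {
        "none": (r < thr_r) & (y < thr_y),
        "monoY": (r < thr_r) & (y >= thr_y),
        "monoR": (r >= thr_r) & (y < thr_y),
        "bi": (r >= thr_r) & (y >= thr_y),
    }
    comps = [replace(anchor, N=float(max(masks["none"].sum(), 1.0)))]
    for name in ("monoY", "monoR", "bi"):
        b = bounds[name]
        m = masks[name]
        mid = lambda lo_hi: 0.5 * (lo_hi[0] + lo_hi[1])
        if m.sum() >= 10:
            mu_r = float(np.clip(r[m].mean(), *b.mu_r))
            mu_y = float(np.clip(y[m].mean(), *b.mu_y))
            s_r = float(np.clip(r[m].std(ddof=1) or anchor.sigma_r, *b.sigma_r))
            s_y = float(np.clip(y[m].std(ddof=1) or anchor.sigma_y, *b.sigma_y))
        else:
            mu_r, mu_y = mid(b.mu_r), mid(b.mu_y)
            s_r, s_y = anchor.sigma_r, anchor.sigma_y
            s_r = float(np.clip(s_r, *b.sigma_r))
            s_y = float(np.clip(s_y, *b.sigma_y))
        comps.append(GaussianComponent(float(max(m.sum(), 0.5)), mu_r, mu_y, s_r, s_y, 0.0))
    return comps


def fit_timebin(
    cells: pd.DataFrame,
    anchor: GaussianComponent,
    bounds: dict[str, ComponentBounds] | None = None,
    n_bins: int = 64,
    transform: str = "linear",
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> MixtureFitResult:
    """Constrained four-component mixture fit to one time bin's histogram.

    The anchor component's shape is fixed (weight free); the expressing
    components vary inside their quadrant boxes.  Weight uncertainties dN
    come from the least-squares covariance (J'J)^-1 scaled by the residual
    variance.
    """
    if len(cells) == 0:
        raise ValueError("empty time bin")
    r = _transform(np.asarray(cells["mch"], dtype=float), transform)
    y = _transform(np.asarray(cells["yfp"], dtype=float), transform)
    if bounds is None:
        bounds = default_bounds(anchor, r, y)
    H, rg, yg, area = _histogram(r, y, n_bins, ranges=ranges)
    start = _initial_components(r, y, anchor, bounds)
    names = ("monoY", "monoR", "bi")

    def unpack(p):
        comps = [replace(anchor, N=p[0])]
        for k in range(3):
            base = 4 + 5 * k
            comps.append(
                GaussianComponent(p[1 + k], p[base], p[base + 1], p[base + 2], p[base + 3], p[base + 4])
            )
        return comps

    def resid(p):
        model = np.zeros_like(H)
        for comp in unpack(p):
            model += bivariate_gaussian(rg, yg, comp) * area
        return (model - H).ravel()

    n = float(len(r))
    p0, lo, hi = [], [], []
    for comp in start:  # weights first
        p0.append(comp.N)
        lo.append(0.0)
        hi.append(2.0 * n)
    for name, comp in zip(names, start[1:]):
        b = bounds[name]
        p0 += [comp.mu_r, comp.mu_y, comp.sigma_r, comp.sigma_y, comp.rho]
        lo += [b.mu_r[0], b.mu_y[0], b.sigma_r[0], b.sigma_y[0], b.rho[0]]
        hi += [b.mu_r[1], b.mu_y[1], b.sigma_r[1], b.sigma_y[1], b.rho[1]]
    p0 = np.clip(p0, lo, hi)
    sol = least_squares(resid, p0, bounds=(lo, hi), method="trf", x_scale="jac")
    if sol.status <= 0:
        raise FitConvergenceError(f"mixture fit failed: {sol.message}")
    comps = unpack(sol.x)

    # covariance of the weight parameters from the Gauss-Newton Hessian
    J = sol.jac
    m, npar = J.shape
    dof = max(m - npar, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = J.T @ J
    cov = s2 * np.linalg.pinv(JTJ)
    dN = np.sqrt(np.clip(np.diag(cov)[:4], 0.0, None))

    flags = []
    total = sum(c.N for c in comps)
    active = [c for c in comps if c.N > 0.01 * total]
    for a_i in range(len(active)):
        for b_i in range(a_i + 1, len(active)):
            ca, cb = active[a_i], active[b_i]
            pooled = 0.5 * (ca.sigma_r + cb.sigma_r + ca.sigma_y + cb.sigma_y) / 2.0
            dist = np.hypot(ca.mu_r - cb.mu_r, ca.mu_y - cb.mu_y)
            if dist < 0.5 * pooled:
                flags.append("component_overlap")
    return MixtureFitResult(
        components=tuple(comps),
        dN=dN,
        fit_residual=float(2.0 * sol.cost),
        n_cells=len(r),
        flags=tuple(sorted(set(flags))),
    )


def propagate_fraction_error(N: np.ndarray, dN: np.ndarray) -> np.ndarray:
    """Quadrature propagation of weight errors onto fractions.

    df_i = f_i * sqrt((dN_i/N_i)^2 + sum_j dN_j^2 / (sum_j N_j)^2).
    Components with N_i = 0 use only the additive (denominator) term.
    """
    N = np.asarray(N, dtype=float)
    dN = np.asarray(dN, dtype=float)
    total = N.sum()
    if total <= 0:
        raise ValueError("total weight must be positive")
    f = N / total
    common = (dN**2).sum() / total**2
    rel = np.zeros_like(N)
    nz = N > 0
    rel[nz] = (dN[nz] / N[nz]) ** 2
    df = f * np.sqrt(rel + common)
    # zero-weight components: additive term only (their own dN still matters)
    df[~nz] = dN[~nz] / total
    return df


def fractions_over_time(
    tracks: pd.DataFrame,
    bin_width_h: float,
    anchor: GaussianComponent,
    bounds: dict[str, ComponentBounds] | None = None,
    min_cells: int = 50,
    n_bins: int = 64,
    transform: str = "linear",
) -> FractionSeries:
    """Mixture-fit class fractions across successive time bins."""
    tracks = validate_tracks(tracks)
    if bin_width_h <= 0:
        raise ValueError("bin_width_h must be > 0")
    if len(tracks) == 0:
        raise ValueError("empty tracks table")
    r_all = _transform(tracks["mch"].to_numpy(float), transform)
    y_all = _transform(tracks["yfp"].to_numpy(float), transform)
    if bounds is None:
        # one set of component boxes for the whole run, from the full
        # experiment's intensity distributions
        bounds = default_bounds(anchor, r_all, y_all)
    # one histogram window for the whole run, so components far from a
    # sparse bin's data cannot hide their mass outside the fitted window
    pad_r = 0.05 * (r_all.max() - r_all.min() + 1e-12)
    pad_y = 0.05 * (y_all.max() - y_all.min() + 1e-12)
    ranges = (
        (r_all.min() - pad_r, r_all.max() + pad_r),
        (y_all.min() - pad_y, y_all.max() + pad_y),
    )
    t = tracks["time_h"].to_numpy(float)
    t0 = np.floor(t.min() / bin_width_h) * bin_width_h
    idx = np.floor((t - t0) / bin_width_h).astype(int)
    has_ids = {"clone_id", "cell_id"}.issubset(tracks.columns)
    centers, fs, dfs, ns, flags = [], [], [], [], []
    for b in range(idx.max() + 1):
        sel = tracks[idx == b]
        center = t0 + (b + 0.5) * bin_width_h
        if len(sel) == 0:
            continue
        # successive frames of one cell are nearly identical measurements:
        # weight uncertainties are scaled to the number of distinct cells
        n_distinct = (
            len(sel.groupby(["clone_id", "cell_id"]).size()) if has_ids else len(sel)
        )
        if n_distinct < min_cells:
            flags.append(f"bin {center:.1f} h: only {n_distinct} cells")
        fit = fit_timebin(
            sel, anchor, bounds=bounds, n_bins=n_bins, transform=transform, ranges=ranges
        )
        for fl in fit.flags:
            flags.append(f"bin {center:.1f} h: {fl}")
        dN = fit.dN * np.sqrt(len(sel) / max(n_distinct, 1))
        centers.append(center)
        fs.append(fit.fractions)
        dfs.append(propagate_fraction_error(fit.N, dN))
        ns.append(n_distinct)
    return FractionSeries(
        bin_centers=np.array(centers),
        f_obs=np.vstack(fs),
        df_obs=np.vstack(dfs),
        n_cells=np.array(ns),
        flags=flags,
    )
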