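"""The apex-density observable and its growth-phase minimum.

The spatial spread of the apex (V1 + V1l) point cloud is summarized by
the inertia tensor of the centered coordinates, normalized by the number
of points so its eigenvalues λ1 ≥ λ2 are per-point dispersions with
units of µm².  Their roots r_i = sqrt(λ_i) are characteristic lengths,
r1·r2 a surface proxy, and the density

    ρ_o(t) = N1(t) / (r1(t) · r2(t))

combines the amount of matter with its spatial distribution.  When the
apex count grows exponentially (N1 = C·2^(ωt)) and the r_i grow
linearly, ρ(t) = D·2^(ωt)/t² with D = C/(B1·B2), which diverges at both
ends and has its minimum at t_min = n/(ω·ln 2) with n = 2 — the
boundary between the early exploration phase and the late densification
phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "InertiaSummary",
    "DensitySeries",
    "DensityMinimum",
    "DegenerateCloudError",
    "inertia_summary",
    "density_series",
    "detect_density_minimum",
]


class DegenerateCloudError(ValueError):
    """Point cloud too small or with zero spatial variance."""


@dataclass(frozen=True)
class InertiaSummary:
    """Inertia-tensor summary of a 2-D point cloud."""

    centroid: tuple[float, float]
    lambda1: float      # µm², larger eigenvalue
    lambda2: float      # µm²
    n_points: int

    @property
    def r1(self) -> float:
        return float(np.sqrt(self.lambda1))

    @property
    def r2(self) -> float:
        return float(np.sqrt(self.lambda2))

    @property
    def sphericity(self) -> float:
        """2λ2/(λ1+λ2) in [0, 1]; 1 iff the cloud is isotropic."""
        return 2.0 * self.lambda2 / (self.lambda1 + self.lambda2)

    @property
    def surface_proxy(self) -> float:
        """r1·r2 = sqrt(λ1 λ2), the characteristic surface (µm²)."""
        return float(np.sqrt(self.lambda1 * self.lambda2))


def _eig2(cxx: np.ndarray, cyy: np.ndarray, cxy: np.ndarray):
    """Eigenvalues of symmetric 2x2 tensors, closed form, λ1 >= λ2."""
    tr = cxx + cyy
    disc = np.sqrt(np.maximum((cxx - cyy) ** 2 + 4.0 * cxy ** 2, 0.0))
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    return l1, np.maximum(l2, 0.0)


def inertia_summary(points) -> InertiaSummary:
    """Inertia tensor of a point cloud, normalized by the point count.

    The tensor is the matrix of second moments of the centered
    coordinates divided by ``n_points``, so the eigenvalues are mean
    squared extents (µm²) independent of how many points sample the
    cloud, and r_i = sqrt(λ_i) are lengths.  Eigenvalues are invariant
    under rigid motions of the cloud.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 2:
        raise DegenerateCloudError("need at least two points")
    c = pts.mean(axis=0)
    d = pts - c
    cxx = float(np.mean(d[:, 0] ** 2))
    cyy = float(np.mean(d[:, 1] ** 2))
    cxy = float(np.mean(d[:, 0] * d[:, 1]))
    if cxx + cyy <= 0.0:
        raise DegenerateCloudError("zero-variance cloud (all points identical)")
    l1, l2 = _eig2(cxx, cyy, cxy)
    return InertiaSummary(centroid=(float(c[0]), float(c[1])),
                          lambda1=float(l1), lambda2=float(l2),
                          n_points=pts.shape[0])


@dataclass
class DensitySeries:
    """Per-snapshot apex-cloud summary and density with bootstrap CIs."""

    t_h: np.ndarray
    n1: np.ndarray
    r1_um: np.ndarray
    r2_um: np.ndarray
    sphericity: np.ndarray
    rho: np.ndarray            # µm⁻², N1/(r1 r2)
    rho_lo: np.ndarray
    rho_hi: np.ndarray
    n_dropped: int = 0
    rho_replicates: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.t_h)


def _bootstrap_rho(pts: np.ndarray, n1: int, b: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Bootstrap ρ by resampling apex locations and a Poisson count."""
    n = pts.shape[0]
    idx = rng.integers(0, n, size=(b, n))
    x = pts[idx, 0]
    y = pts[idx, 1]
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    cxx = np.mean(x * x, axis=1)
    cyy = np.mean(y * y, axis=1)
    cxy = np.mean(x * y, axis=1)
    l1, l2 = _eig2(cxx, cyy, cxy)
    surf = np.sqrt(np.maximum(l1 * l2, 0.0))
    counts = rng.poisson(n1, size=b).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = counts / surf
    return rho[np.isfinite(rho) & (surf > 0)]


def density_series(trajectory, bootstrap: int = 500,
                   rng: np.random.Generator | None = None,
                   keep_replicates: bool = False) -> DensitySeries:
    """Measure ρ_o(t) = N1/(r1 r2) over the snapshots of a trajectory.

    Snapshots whose apex cloud is degenerate (fewer than two distinct
    locations, or a collinear cloud with λ2 = 0 — e.g. the two
    germination tips before any branching) are dropped with a warning.
    Uncertainties come from ``bootstrap`` resamplings of the apex
    locations combined with a Poisson-distributed apex count; set
    ``bootstrap=0`` to skip them.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    reps = []
    dropped = 0
    for t, pts in trajectory.snapshots():
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        n1 = pts.shape[0]
        try:
            summ = inertia_summary(pts)
        except DegenerateCloudError:
            dropped += 1
            continue
        if summ.lambda2 <= 1e-9 * summ.lambda1 or summ.surface_proxy <= 0.0:
            dropped += 1
            continue
        rho = n1 / summ.surface_proxy
        if bootstrap > 0:
            samples = _bootstrap_rho(pts, n1, bootstrap, rng)
            lo, hi = (np.percentile(samples, [2.5, 97.5])
                      if samples.size else (np.nan, np.nan))
        else:
            samples = np.empty(0)
            lo = hi = np.nan
        rows.append((t, n1, summ.r1, summ.r2, summ.sphericity, rho, lo, hi))
        if keep_replicates:
            pad = np.full(bootstrap, np.nan)
            pad[: samples.size] = samples[:bootstrap]
            reps.append(pad)
    if dropped:
        warnings.warn(
            f"dropped {dropped} degenerate snapshot(s) from the density series",
            stacklevel=2,
        )
    if not rows:
        raise DegenerateCloudError("no non-degenerate snapshots in trajectory")
    arr = np.array(rows, dtype=float)
    return DensitySeries(
        t_h=arr[:, 0], n1=arr[:, 1].astype(np.int64), r1_um=arr[:, 2],
        r2_um=arr[:, 3], sphericity=arr[:, 4], rho=arr[:, 5],
        rho_lo=arr[:, 6], rho_hi=arr[:, 7], n_dropped=dropped,
        rho_replicates=np.array(reps).T if reps else None,
    )


@dataclass
class DensityMinimum:
    """Location of the density minimum separating the growth phases."""

    found: bool
    t_min_h: float = float("nan")
    ci: tuple[float, float] = (float("nan"), float("nan"))


def _argmin_smoothed(t: np.ndarray, log_rho: np.ndarray,
                     window: int) -> float | None:
    n = len(t)
    w = min(window, n if n % 2 == 1 else n - 1)
    smooth = savgol_filter(log_rho, w, 2) if w >= 5 else log_rho
    # monotone (within smoothing) series: no interior minimum
    i = int(np.argmin(smooth))
    if i == 0 or i == n - 1:
        return None
    # quadratic refinement through the three points around the argmin
    y0, y1, y2 = smooth[i - 1], smooth[i], smooth[i + 1]
    x0, x1, x2 = t[i - 1], t[i], t[i + 1]
    coef = np.polyfit([x0, x1, x2], [y0, y1, y2], 2)
    if coef[0] <= 0:
        return float(x1)
    vertex = -coef[1] / (2.0 * coef[0])
    if not (x0 <= vertex <= x2):
        return float(x1)
    return float(vertex)


def detect_density_minimum(series, t=None, window: int = 5,
                           n_boot: int = 200,
                           rng: np.random.Generator | None = None) -> DensityMinimum:
    """Locate the interior minimum of ρ(t).

    The argmin is taken on a local-quadratic (Savitzky-Golay, 5-point
    window) smooth of log ρ — the noise on a counting-driven density is
    multiplicative — and refined by the vertex of a parabola through the
    three surrounding points.  A monotone series yields
    ``DensityMinimum(found=False)``.  When the series carries bootstrap
    replicates a percentile CI over re-detected minima is attached.

    Accepts a :class:`DensitySeries` or a plain ``(t, rho)`` pair.
    """
    if t is not None:
        t_arr = np.asarray(series, dtype=float)
        rho = np.asarray(t, dtype=float)
    else:
        t_arr = np.asarray(series.t_h, dtype=float)
        rho = np.asarray(series.rho, dtype=float)
    if len(t_arr) < 5:
        raise ValueError("need at least five time points")
    mask = np.isfinite(rho) & (rho > 0)
    t_arr, rho = t_arr[mask], rho[mask]
    log_rho = np.log(rho)
    tmin = _argmin_smoothed(t_arr, log_rho, window)
    if tmin is None:
        return DensityMinimum(found=False)
    ci = (float("nan"), float("nan"))
    reps = getattr(series, "rho_replicates", None) if t is None else None
    if reps is not None and n_boot > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        reps = reps[:, mask]
        picks = rng.integers(0, reps.shape[0], size=min(n_boot, reps.shape[0]))
        boots = []
        for k in picks:
            r = reps[k]
            ok = np.isfinite(r) & (r > 0)
            if ok.sum() >= 5:
                tm = _argmin_smoothed(t_arr[ok], np.log(r[ok]), window)
                if tm is not None:
                    boots.append(tm)
        if len(boots) >= 10:
            ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return DensityMinimum(found=True, t_min_h=tmin, ci=(float(ci[0]), float(ci[1])))
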