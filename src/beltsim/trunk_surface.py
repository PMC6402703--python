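"""Torso surfaces on a regular cylindrical grid, and their curvature.

A trunk is stored as a radius map r(theta, z) on a regular grid: theta
uniform and half-open on [0, 2*pi), z uniform and ascending. The angular
convention follows clinical belt use: the belt closure sits on the abdomen
at theta = 90 deg and the back midline is centred at theta = 270 deg; theta
is counter-clockwise seen from above, so +y is anterior and +x is the
patient's left-right axis.

The module ingests raw scanner point clouds (resampling them onto the
grid, despiking and smoothing), generates fully synthetic torsos with
controllable abdominal protrusion (a BMI proxy), lumbar lordosis and
spinal furrow, and estimates the signed curvature field along the belt
(angular) direction from local second-order polynomial fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "TrunkSurface",
    "CurvatureField",
    "TorsoParams",
    "LumbarCenter",
    "cylindrical_resample",
    "despike_and_smooth",
    "angular_curvature",
    "synthetic_trunk",
    "lumbar_center",
    "ANTERIOR_ANGLE",
    "POSTERIOR_ANGLE",
]

ANTERIOR_ANGLE = np.pi / 2  # belt closure, abdomen
POSTERIOR_ANGLE = 3 * np.pi / 2  # back midline


def _wrapped_diff(theta: np.ndarray, center: float) -> np.ndarray:
    """Angular difference theta - center wrapped to (-pi, pi]."""
    d = (np.asarray(theta) - center + np.pi) % (2 * np.pi) - np.pi
    return d


@dataclass
class TrunkSurface:
    """Regular cylindrical radius map of a torso.

    Attributes
    ----------
    theta:
        Angles (rad), uniform step, half-open [0, 2*pi).
    z:
        Heights (m), uniform ascending step.
    r:
        Radii (m), shape (n_theta, n_z), all positive and finite; the map is
        periodic across the theta seam.
    metadata:
        Free-form subject metadata (id, sex, age, height, weight, BMI, ...).
    """

    theta: np.ndarray
    z: np.ndarray
    r: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        nt, nz = self.theta.size, self.z.size
        if self.r.shape != (nt, nz):
            raise ValueError(f"r must have shape ({nt}, {nz}), got {self.r.shape}")
        if nt < 8 or nz < 2:
            raise ValueError("grid too small")
        dth = np.diff(self.theta)
        if not np.allclose(dth, dth[0], rtol=0, atol=1e-9):
            raise ValueError("theta grid must be uniform")
        if not np.isclose(self.theta[0], 0.0) or self.theta[-1] >= 2 * np.pi:
            raise ValueError("theta must be half-open [0, 2*pi) starting at 0")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) and np.allclose(dz, dz[0], rtol=1e-9)):
            raise ValueError("z grid must be uniform ascending")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("radii must be finite")
        if np.any(self.r <= 0):
            raise ValueError("radii must be positive")

    # -- grid helpers -----------------------------------------------------
    @property
    def n_theta(self) -> int:
        return self.theta.size

    @property
    def n_z(self) -> int:
        return self.z.size

    @property
    def dtheta(self) -> float:
        return float(2 * np.pi / self.n_theta)

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    def cartesian(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, z) arrays of shape (n_theta, n_z), in the scanner frame."""
        x = self.r * np.cos(self.theta)[:, None] + self.origin[0]
        y = self.r * np.sin(self.theta)[:, None] + self.origin[1]
        z = np.broadcast_to(self.z[None, :], self.r.shape) + self.origin[2]
        return x, y, z

    def circumference(self) -> np.ndarray:
        """Perimeter of each cross-section polygon (m), shape (n_z,)."""
        x = self.r * np.cos(self.theta)[:, None]
        y = self.r * np.sin(self.theta)[:, None]
        dx = np.diff(np.vstack([x, x[:1]]), axis=0)
        dy = np.diff(np.vstack([y, y[:1]]), axis=0)
        return np.hypot(dx, dy).sum(axis=0)

    def arc_lengths(self) -> np.ndarray:
        """Chord length from node i to node i+1 per row, shape (n_theta, n_z)."""
        x = self.r * np.cos(self.theta)[:, None]
        y = self.r * np.sin(self.theta)[:, None]
        dx = np.roll(x, -1, axis=0) - x
        dy = np.roll(y, -1, axis=0) - y
        return np.hypot(dx, dy)

    def with_radii(self, r: np.ndarray) -> "TrunkSurface":
        return TrunkSurface(self.theta.copy(), self.z.copy(), np.asarray(r, dtype=float),
                            self.origin.copy(), dict(self.metadata))

    def scaled(self, lam: float) -> "TrunkSurface":
        """Uniformly rescale all lengths by ``lam``."""
        return TrunkSurface(self.theta.copy(), self.z * lam, self.r * lam,
                            self.origin * lam, dict(self.metadata))

    def theta_index(self, angle: float) -> int:
        return int(np.round((angle % (2 * np.pi)) / self.dtheta)) % self.n_theta


@dataclass
class CurvatureField:
    """Signed curvature of the surface, positive where convex outward.

    ``gamma1`` is the curvature along the belt (angular) direction;
    ``gamma2`` (optional) along the axial direction. Units 1/m.
    """

    gamma1: np.ndarray
    gamma2: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gamma1 = np.asarray(self.gamma1, dtype=float)
        if not np.all(np.isfinite(self.gamma1)):
            raise ValueError("gamma1 must be finite")
        if self.gamma2 is not None:
            self.gamma2 = np.asarray(self.gamma2, dtype=float)
            if self.gamma2.shape != self.gamma1.shape:
                raise ValueError("gamma2 shape mismatch")
            if not np.all(np.isfinite(self.gamma2)):
                raise ValueError("gamma2 must be finite")


@dataclass(frozen=True)
class TorsoParams:
    """Parameters of the synthetic torso generator (lengths in m).

    The generator emulates the lumbar band of a standing adult trunk:
    a mostly convex superellipse-like cross-section, an anterior abdominal
    bulge whose amplitude acts as a BMI proxy (larger bellies also sag
    lower), a broad posterior lordosis hollow that defines the lumbar
    centre, a narrow concave spinal furrow along the back midline, and
    optional gluteal/chest flares, left-right asymmetry and smooth seeded
    surface noise.
    """

    n_theta: int = 360
    n_z: int = 80
    length: float = 0.40
    lateral_radius: float = 0.16
    ap_radius: float = 0.125
    superellipse_exponent: float = 2.4
    protrusion: float = 0.03          # abdominal bulge amplitude (BMI proxy)
    protrusion_sag: float = 0.5       # how far the bulge centre drops per m of amplitude
    lordosis_depth: float = 0.025     # posterior hollow depth at the lumbar centre
    lordosis_center: float = 0.18     # z of the lumbar lordosis (and belt) centre
    furrow_depth: float = 0.008       # concave spinal furrow depth
    furrow_sigma_deg: float = 7.0
    gluteal_flare: float = 0.02
    chest_flare: float = 0.015
    asymmetry: float = 0.0            # left-right multiplicative asymmetry
    noise: float = 0.0                # smooth random perturbation amplitude
    seed: int = 0


def synthetic_trunk(params: TorsoParams) -> TrunkSurface:
    """Generate a smooth closed synthetic torso band.

    Deterministic given ``params.seed``. Raises if the parameters would
    produce a non-positive radius anywhere.
    """
    p = params
    theta = np.arange(p.n_theta) * (2 * np.pi / p.n_theta)
    z = np.linspace(0.0, p.length, p.n_z)
    th = theta[:, None]
    zz = z[None, :]

    # superellipse-like base cross-section (exactly elliptic for exponent 2)
    n = p.superellipse_exponent
    base = (
        np.abs(np.cos(th) / p.lateral_radius) ** n
        + np.abs(np.sin(th) / p.ap_radius) ** n
    ) ** (-1.0 / n)
    base = base * (1.0 + p.asymmetry * np.cos(th))

    ant = _wrapped_diff(th, ANTERIOR_ANGLE)
    post = _wrapped_diff(th, POSTERIOR_ANGLE)

    def gauss(u, s):
        return np.exp(-0.5 * (u / s) ** 2)

    r = base
    if p.protrusion != 0.0:
        z_belly = p.lordosis_center - 0.02 - p.protrusion_sag * p.protrusion
        r = r + p.protrusion * gauss(zz - z_belly, 0.10) * gauss(ant, np.deg2rad(40))
    if p.lordosis_depth != 0.0:
        r = r - p.lordosis_depth * gauss(zz - p.lordosis_center, 0.08) * gauss(
            post, np.deg2rad(46)
        )
    if p.furrow_depth != 0.0:
        r = r - p.furrow_depth * gauss(post, np.deg2rad(p.furrow_sigma_deg))
    if p.gluteal_flare != 0.0:
        r = r + p.gluteal_flare * gauss(zz - 0.0, 0.06) * gauss(post, np.deg2rad(52))
    if p.chest_flare != 0.0:
        r = r + p.chest_flare * gauss(zz - p.length, 0.06) * gauss(ant, np.deg2rad(57))
    if p.noise != 0.0:
        rng = np.random.default_rng(p.seed)
        for k in range(2, 6):
            amp = p.noise * rng.normal() / k
            phase = rng.uniform(0, 2 * np.pi)
            axial = np.cos(np.pi * zz / p.length * rng.integers(1, 4) + rng.uniform(0, 2 * np.pi))
            r = r + amp * np.cos(k * th + phase) * axial

    r = r + np.zeros((1, p.n_z))  # broadcast z-independent shapes to the grid
    if np.any(r <= 0):
        raise ValueError("torso parameters produce non-positive radii")
    meta = {"params": p}
    return TrunkSurface(theta, z, r, metadata=meta)


def cylindrical_resample(
    points: np.ndarray,
    n_theta: int = 360,
    n_z: int = 80,
    z_range: tuple[float, float] | None = None,
) -> TrunkSurface:
    """Resample a raw (x, y, z) point cloud onto the regular cylindrical grid.

    The vertical axis passes through the x-y centroid of the cloud. Each
    grid cell's radius is the median of its member points; empty cells are
    filled by periodic angular interpolation within their row. The achieved
    fill fraction is stored in ``metadata["fill_fraction"]``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point cloud")
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (N, 3) array")
    z_span = pts[:, 2].max() - pts[:, 2].min()
    if z_span < 1e-9:
        raise ValueError("degenerate axis: all points coplanar in z")

    cx, cy = pts[:, 0].mean(), pts[:, 1].mean()
    x, y = pts[:, 0] - cx, pts[:, 1] - cy
    rad = np.hypot(x, y)
    ang = np.arctan2(y, x) % (2 * np.pi)

    if z_range is None:
        z_range = (pts[:, 2].min(), pts[:, 2].max())
    z_grid = np.linspace(z_range[0], z_range[1], n_z)
    dz = z_grid[1] - z_grid[0]
    dth = 2 * np.pi / n_theta

    it = np.round(ang / dth).astype(int) % n_theta
    iz = np.round((pts[:, 2] - z_range[0]) / dz).astype(int)
    ok = (iz >= 0) & (iz < n_z)
    it, iz, rad_ok = it[ok], iz[ok], rad[ok]

    # median radius per cell
    cell = it * n_z + iz
    order = np.argsort(cell, kind="stable")
    cell_s, rad_s = cell[order], rad_ok[order]
    uniq, starts = np.unique(cell_s, return_index=True)
    r_grid = np.full(n_theta * n_z, np.nan)
    med = [np.median(rad_s[s:e]) for s, e in zip(starts, np.append(starts[1:], rad_s.size))]
    r_grid[uniq] = med
    r_grid = r_grid.reshape(n_theta, n_z)

    fill = float(np.mean(np.isfinite(r_grid)))
    theta = np.arange(n_theta) * dth
    # fill empty cells: periodic interpolation over theta within each row
    for j in range(n_z):
        col = r_grid[:, j]
        good = np.isfinite(col)
        if not good.any():
            continue  # fully empty row, filled axially below
        if not good.all():
            r_grid[:, j] = np.interp(
                theta, theta[good], col[good], period=2 * np.pi
            )
    # any fully-empty rows: interpolate along z per angle
    row_ok = np.isfinite(r_grid).all(axis=0)
    if not row_ok.all():
        if not row_ok.any():
            raise ValueError("no points fell inside the grid")
        for i in range(n_theta):
            r_grid[i, :] = np.interp(z_grid, z_grid[row_ok], r_grid[i, row_ok])

    meta = {"fill_fraction": fill, "n_points": int(pts.shape[0])}
    return TrunkSurface(theta, z_grid, r_grid, origin=np.array([cx, cy, 0.0]), metadata=meta)


def despike_and_smooth(
    surface: TrunkSurface,
    outlier_k: float = 3.0,
    sigma_theta: float = 2.0,
    sigma_z: float = 2.0,
    median_size: int = 5,
) -> TrunkSurface:
    """Remove radial spikes and apply a periodic Gaussian low-pass.

    Radii deviating more than ``outlier_k`` robust standard deviations
    (1.4826 * MAD) from their local median are replaced by that median;
    the map is then smoothed with a separable Gaussian (sigmas in grid
    cells), periodic across the theta seam.
    """
    if sigma_theta <= 0 or sigma_z <= 0:
        raise ValueError("Gaussian sigmas must be > 0")
    r = surface.r
    # rank filters do not accept per-axis modes: pad periodically in theta
    pad = median_size
    r_pad = np.pad(r, ((pad, pad), (0, 0)), mode="wrap")
    med = ndimage.median_filter(
        r_pad, size=(median_size, median_size), mode="nearest"
    )[pad:-pad, :]
    dev = r - med
    rsd = 1.4826 * np.median(np.abs(dev))
    # rsd degenerates to 0 when most cells equal their local median exactly;
    # then any nonzero deviation is an outlier
    thresh = outlier_k * rsd if rsd > 0 else 0.0
    r = np.where(np.abs(dev) > thresh, med, r)
    r = ndimage.gaussian_filter(
        r, sigma=(sigma_theta, sigma_z), mode=("wrap", "nearest"), truncate=6.0
    )
    return surface.with_radii(r)


def angular_curvature(
    surface: TrunkSurface,
    window_halfwidth: float = np.deg2rad(8.0),
    axial: bool = True,
    axial_halfcells: int = 3,
) -> CurvatureField:
    """Signed curvature along the belt direction (and optionally axial).

    For each grid node, the cross-section polyline in a +/- window around
    the node is expressed in the local tangent frame (arc position x,
    radial offset y), a second-order polynomial y(x) is least-squares
    fitted, and the planar curvature gamma = y''/(1 + y'^2)^(3/2) is
    evaluated at the centre, signed positive where the surface is convex
    outward. A circular cylinder of radius R yields 1/R everywhere.
    """
    if window_halfwidth > np.pi:
        raise ValueError("curvature window larger than pi")
    dth = surface.dtheta
    m = int(round(window_halfwidth / dth))
    if 2 * m + 1 < 5:
        raise ValueError("curvature window must contain at least 5 samples")

    offsets = np.arange(-m, m + 1)
    ang = offsets * dth
    r = surface.r
    # neighbour stacks: rj[k] = r[(i + offsets[k]) mod n_theta, :]
    rj = np.stack([np.roll(r, -int(j), axis=0) for j in offsets])  # (2m+1, nt, nz)
    x = rj * np.sin(ang)[:, None, None]
    y = rj * np.cos(ang)[:, None, None] - r[None, :, :]

    # per-node quadratic fit via 3x3 normal equations
    pows = [np.sum(x ** k, axis=0) for k in range(5)]  # S0..S4
    b = [np.sum(y * x ** k, axis=0) for k in range(3)]
    A = np.stack(
        [
            np.stack([pows[0], pows[1], pows[2]], axis=-1),
            np.stack([pows[1], pows[2], pows[3]], axis=-1),
            np.stack([pows[2], pows[3], pows[4]], axis=-1),
        ],
        axis=-2,
    )  # (nt, nz, 3, 3)
    rhs = np.stack(b, axis=-1)[..., None]  # (nt, nz, 3, 1)
    coef = np.linalg.solve(A, rhs)[..., 0]  # (nt, nz, 3)
    c1, c2 = coef[..., 1], coef[..., 2]
    gamma1 = -2.0 * c2 / (1.0 + c1 ** 2) ** 1.5

    gamma2 = None
    if axial:
        h = min(axial_halfcells, surface.n_z // 2 - 1)
        h = max(h, 2)
        offs = np.arange(-h, h + 1)
        xz = offs * surface.dz
        # fixed-abscissa quadratic fit -> linear filters for r' and r''
        V = np.vander(xz, 3, increasing=True)  # columns 1, x, x^2
        pinv = np.linalg.pinv(V)  # (3, 2h+1)
        rp = np.pad(r, ((0, 0), (h, h)), mode="edge")
        cols = np.stack([rp[:, k : k + surface.n_z] for k in range(2 * h + 1)])
        c1z = np.tensordot(pinv[1], cols, axes=(0, 0))
        c2z = np.tensordot(pinv[2], cols, axes=(0, 0))
        gamma2 = -2.0 * c2z / (1.0 + c1z ** 2) ** 1.5
    return CurvatureField(gamma1=gamma1, gamma2=gamma2)


@dataclass(frozen=True)
class LumbarCenter:
    """Torque reduction point: deepest point of the posterior midline profile."""

    theta: float
    z: float
    point: np.ndarray  # 3-D location on the surface, scanner frame
    fallback: bool = False


def lumbar_center(surface: TrunkSurface) -> LumbarCenter:
    """Locate the lumbar lordosis centre on the posterior midline.

    Returns the most anterior point (minimum radius, i.e. deepest lordosis
    hollow) of the sagittal back-midline profile. If the profile has no
    interior minimum (no lordosis), falls back to mid-height with a warning.
    """
    it = surface.theta_index(POSTERIOR_ANGLE)
    prof = surface.r[it, :]
    i_min = int(np.argmin(prof))
    interior = 0 < i_min < surface.n_z - 1
    depth = min(prof[0], prof[-1]) - prof[i_min]
    if not interior or depth <= 1e-9:
        warnings.warn(
            "posterior midline profile has no interior lordosis minimum; "
            "falling back to mid-height",
            stacklevel=2,
        )
        i_min = surface.n_z // 2
        fallback = True
    else:
        fallback = False
    z_c = float(surface.z[i_min])
    th = float(surface.theta[it])
    rr = float(surface.r[it, i_min])
    point = np.array(
        [rr * np.cos(th) + surface.origin[0], rr * np.sin(th) + surface.origin[1],
         z_c + surface.origin[2]]
    )
    return LumbarCenter(theta=th, z=z_c, point=point, fallback=fallback)
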