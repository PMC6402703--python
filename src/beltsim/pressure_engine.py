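"""Interface pressure and elastic trunk remodeling.

Pressure follows the extended Law of Laplace, p = T1/R1 + T2/R2, on convex
regions; where the surface is concave along the belt direction the belt
lifts off and the pressure is zero. The trunk responds as a homogeneous,
linear elastic, semi-infinite body: the surface deflection under each
loaded grid cell is Love's closed-form solution for a uniform rectangular
pressure patch, and the total deflection is the superposition over all
cells. Because deflection changes the curvature (and slackens the belt),
pressure and geometry are coupled; ``equilibrate`` ramps the belt tension
in increments and then fixed-point iterates until the Laplace pressure of
the deformed shape matches the pressure that produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import fft as sfft

from .belt_placement import ContactModel, Placement, TensionField, place_belt, tension_with_adhesion
from .fabric_mechanics import BeltDesign
from .trunk_surface import CurvatureField, TrunkSurface, angular_curvature

__all__ = [
    "MMHG_PER_PA",
    "PA_PER_MMHG",
    "BodyElasticity",
    "PressureField",
    "DeflectionField",
    "EquilibriumState",
    "laplace_pressure",
    "love_kernel",
    "love_patch_deflection",
    "love_deflection",
    "equilibrate",
]

PA_PER_MMHG = 133.322
MMHG_PER_PA = 1.0 / PA_PER_MMHG


@dataclass(frozen=True)
class BodyElasticity:
    """Homogeneous linear-elastic trunk: Young's modulus (Pa) and Poisson ratio."""

    youngs_modulus: float = 15e3
    poisson: float = 0.48

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not 0.0 <= self.poisson < 0.5:
            raise ValueError("body Poisson ratio must lie in [0, 0.5)")

    @property
    def compliance(self) -> float:
        """(1 - nu^2) / (pi * E), the Love kernel prefactor (1/Pa)."""
        return (1.0 - self.poisson**2) / (np.pi * self.youngs_modulus)


@dataclass
class PressureField:
    """Interface pressure on the grid (Pa, >= 0). Report unit: mmHg."""

    p: np.ndarray
    cell_area: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if np.any(self.p < 0):
            raise ValueError("pressure must be non-negative")

    @property
    def mmhg(self) -> np.ndarray:
        return self.p * MMHG_PER_PA


@dataclass
class DeflectionField:
    """Inward normal surface displacement (m); linear in the applied pressure."""

    u_z: np.ndarray


@dataclass
class EquilibriumState:
    """Converged (or last) state of the pressure/geometry fixed point."""

    surface: TrunkSurface
    pressure: PressureField
    tension: TensionField
    curvature: CurvatureField
    deflection: DeflectionField
    placement: Placement
    residuals: list = field(default_factory=list)
    converged: bool = False


def laplace_pressure(
    tension: TensionField,
    curvature: CurvatureField,
    mask: Optional[np.ndarray] = None,
) -> PressureField:
    """Extended Law of Laplace, p = T1*gamma1 + T2*gamma2 on convex cells.

    Cells with gamma1 <= 0 (concave along the belt) carry zero pressure:
    the belt is not in contact there. A concave axial curvature simply
    contributes nothing.
    """
    g1 = curvature.gamma1
    if tension.T1.shape != g1.shape:
        raise ValueError("tension and curvature grids do not match")
    p = tension.T1 * np.clip(g1, 0.0, None)
    if curvature.gamma2 is not None:
        p = p + tension.T2 * np.clip(curvature.gamma2, 0.0, None)
    p = np.where(g1 > 0.0, p, 0.0)
    if mask is not None:
        p = np.where(mask, p, 0.0)
    return PressureField(p=np.clip(p, 0.0, None))


def love_kernel(x, y, a, b):
    """Love's rectangular-punch influence function (units of length).

    Surface deflection at in-plane offset (x, y) from the centre of a
    uniform pressure p over the rectangle |x| < a, |y| < b on a semi-infinite
    body is ``u_z = p * (1 - nu^2) / (pi * E) * love_kernel(x, y, a, b)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xp, xm = x + a, x - a
    yp, ym = y + b, y - b

    def rad(u, v):
        return np.sqrt(u * u + v * v)

    t1 = xp * np.log((yp + rad(yp, xp)) / (ym + rad(ym, xp)))
    t2 = yp * np.log((xp + rad(yp, xp)) / (xm + rad(yp, xm)))
    t3 = xm * np.log((ym + rad(ym, xm)) / (yp + rad(yp, xm)))
    t4 = ym * np.log((xm + rad(ym, xm)) / (xp + rad(ym, xp)))
    return t1 + t2 + t3 + t4


def love_patch_deflection(pressure, elasticity: BodyElasticity, a, b, x, y):
    """Deflection under a single uniform rectangular patch (m)."""
    if elasticity.youngs_modulus <= 0:
        raise ValueError("Young's modulus must be > 0")
    return pressure * elasticity.compliance * love_kernel(x, y, a, b)


def love_deflection(
    pressure: np.ndarray,
    elasticity: BodyElasticity,
    arc_spacing: float,
    dz: float,
) -> np.ndarray:
    """Superpose the Love kernel over all loaded cells of a gridded field.

    Distances are measured in the unrolled tangent plane (arc length x
    axial offset), with the arc step taken uniform at ``arc_spacing`` and
    the angular direction periodic (shorter-way distance across the seam).
    The superposition is a convolution, evaluated with FFTs: circular along
    theta, zero-padded (linear) along z.
    """
    p = np.asarray(pressure, dtype=float)
    nt, nz = p.shape
    nzp = 2 * nz - 1
    it = np.arange(nt)
    di = np.minimum(it, nt - it)  # shorter-way step count across the seam
    lz = np.arange(nzp)
    djz = np.where(lz <= nz - 1, lz, lz - nzp)
    K = love_kernel(
        (di * arc_spacing)[:, None], (djz * dz)[None, :], arc_spacing / 2, dz / 2
    )
    p_pad = np.zeros((nt, nzp))
    p_pad[:, :nz] = p
    u = sfft.irfft2(sfft.rfft2(p_pad) * sfft.rfft2(K), s=(nt, nzp))
    return elasticity.compliance * u[:, :nz]


def equilibrate(
    surface: TrunkSurface,
    belt: BeltDesign,
    contact: ContactModel,
    elasticity: BodyElasticity,
    nominal_stretch: float = 0.20,
    n_steps: int = 10,
    tol: float = 1e-3,
    max_iter: int = 50,
    curvature_window: float = np.deg2rad(8.0),
    center_z: Optional[float] = None,
    step_deflection_cap: float = 5e-3,
) -> EquilibriumState:
    """Ramp the belt load and iterate pressure/geometry to equilibrium.

    The tension is applied in ``n_steps`` increments. At each step the
    Laplace pressure on the current geometry is computed, the pressure
    change is turned into a Love deflection, the radii shrink, and the
    circumference (hence the belt stretch) and curvature are refreshed.
    After the ramp, fixed-point iterations continue at full load until the
    maximum relative pressure residual drops below ``tol`` or ``max_iter``
    is reached (the state is then returned with ``converged=False``).

    The belt-slack feedback (compression slackens the belt, which lowers
    the pressure) can have a loop gain well above one for soft bodies, so
    the explicit update is under-relaxed: the initial relaxation factor is
    set from an a-priori gain estimate and then adapted by Aitken's Delta^2
    rule, and any single step is capped to ``step_deflection_cap`` metres
    of radial motion. Three consecutive residual increases abort with a
    diagnostic.
    """
    placement = place_belt(surface, belt, nominal_stretch, center_z=center_z)
    dz = surface.dz
    arc = float(
        np.mean(surface.circumference()[placement.rows]) / surface.n_theta
    )

    surf = surface.with_radii(surface.r.copy())
    p_applied = np.zeros((surface.n_theta, surface.n_z))
    residuals: list[float] = []

    def evaluate(s: TrunkSurface, frac: float):
        curv = angular_curvature(s, window_halfwidth=curvature_window)
        tens = tension_with_adhesion(placement, s, contact, curvature=curv,
                                     tension_scale=frac)
        pres = laplace_pressure(tens, curv, mask=placement.mask)
        return pres, tens, curv

    def deflect(s: TrunkSurface, dp: np.ndarray):
        """Apply the (possibly capped) deflection of dp; return surface and scale."""
        u = love_deflection(dp, elasticity, arc, dz)
        umax = float(np.abs(u).max())
        scale = 1.0 if umax <= step_deflection_cap else step_deflection_cap / umax
        r_new = s.r - scale * u
        if np.any(r_new <= 0):
            raise RuntimeError("deflection collapsed the surface (r <= 0)")
        return s.with_radii(r_new), scale

    # a-priori loop-gain estimate for the initial under-relaxation factor:
    # compliance of a uniform unit band load times the tension-slack slope
    curv0 = angular_curvature(surf, window_halfwidth=curvature_window)
    g_band = curv0.gamma1[placement.mask]
    gbar = float(np.clip(g_band, 0.0, None).mean())
    rest = float(placement.rest_length.mean())
    g_char = float(
        love_deflection(placement.mask.astype(float), elasticity, arc, dz).max()
    )
    slope = belt.k_eq * gbar * (2 * np.pi / rest) + belt.k_eq * nominal_stretch * gbar**2
    lam = float(np.clip(1.0 / (1.0 + g_char * slope), 0.02, 1.0))

    converged = False
    prev_resid = None
    prev_R = None
    growth = 0
    for it in range(n_steps + max_iter):
        frac = min(1.0, (it + 1) / n_steps)
        pres, tens, curv = evaluate(surf, frac)
        R = pres.p - p_applied
        if frac >= 1.0:
            scale = max(float(pres.p.max()), 1e-12)
            resid = float(np.abs(R).max() / scale)
            residuals.append(resid)
            if resid < tol:
                converged = True
                p_applied = pres.p
                break
            grew = prev_resid is not None and resid > prev_resid
            if grew:
                # damp the relaxation to break limit cycles; abort only on
                # repeated significant growth (true divergence)
                lam = float(max(0.5 * lam, 0.02))
                if resid > 1.2 * prev_resid:
                    growth += 1
                    if growth >= 4:
                        raise RuntimeError(
                            "pressure/geometry iteration diverging: residuals "
                            f"{residuals[-5:]}"
                        )
            else:
                growth = 0
            if prev_R is not None and not grew:
                dR = R - prev_R
                denom = float((dR * dR).sum())
                if denom > 0:
                    lam = -lam * float((prev_R * dR).sum()) / denom
                    lam = float(np.clip(lam, 0.02, 1.0))
            prev_R = R
            prev_resid = resid
        dp = lam * R
        surf, applied = deflect(surf, dp)
        p_applied = p_applied + applied * dp

    deflection = surface.r - surf.r
    local_ratio = np.max(deflection / surface.r)
    if local_ratio > 0.10:
        warnings.warn(
            f"maximum deflection is {100 * local_ratio:.1f}% of the local radius; "
            "the semi-infinite body assumption is strained",
            stacklevel=2,
        )

    area = surf.r * surf.dtheta * dz
    return EquilibriumState(
        surface=surf,
        pressure=PressureField(p=p_applied, cell_area=area),
        tension=tens,
        curvature=curv,
        deflection=DeflectionField(u_z=deflection),
        placement=placement,
        residuals=residuals,
        converged=converged,
    )
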