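"""Screw (wrench) reduction of the interface pressure field.

The pressure field is integrated slice by slice into resultant forces and
centres of force, then reduced to a single force/torque pair (a wrench) at
the lumbar reduction point on the body surface. The transversal moment
``M_t`` -- the component about the patient's left-right (frontal) axis, the
x axis in this package's frame -- is the delordosing indicator: positive
values tend to reduce the lumbar lordosis angle, negative values to
increase it.

Forces use the inward radial direction as the surface normal and
``r * dtheta * dz`` as the cell area, consistent with the cylindrical data
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pressure_engine import PressureField
from .trunk_surface import TrunkSurface, lumbar_center

__all__ = ["SliceResultants", "ForceScrew", "slice_resultants", "reduce_wrench", "transport_wrench"]


def _cell_forces(pressure: np.ndarray, surface: TrunkSurface):
    """Per-cell force vectors and application points, shapes (nt, nz, 3)."""
    if pressure.shape != surface.r.shape:
        raise ValueError("pressure and surface grids do not match")
    ct = np.cos(surface.theta)[:, None]
    st = np.sin(surface.theta)[:, None]
    area = surface.r * surface.dtheta * surface.dz
    w = pressure * area
    forces = np.stack([-w * ct, -w * st, np.zeros_like(w)], axis=-1)
    x, y, z = surface.cartesian()
    points = np.stack([x, y, z], axis=-1)
    return forces, points, w


@dataclass
class SliceResultants:
    """Per-z-slice resultant forces and centres of force."""

    z: np.ndarray
    force: np.ndarray      # (n_z, 3) N
    center: np.ndarray     # (n_z, 3) m; NaN where the slice is unloaded
    loaded: np.ndarray     # (n_z,) bool

    def loaded_centers(self) -> np.ndarray:
        """Centres of force of the loaded slices only."""
        return self.center[self.loaded]


@dataclass
class ForceScrew:
    """Global wrench at the reduction point, plus the per-slice breakdown.

    ``moment`` obeys the transport law M_P = M_Q + (Q - P) x F. ``M_t`` is
    the moment component about the left-right axis (x), positive when the
    pressure pattern acts to reduce the lumbar lordosis.
    """

    force: np.ndarray
    moment: np.ndarray
    point: np.ndarray
    slices: SliceResultants

    @property
    def M_t(self) -> float:
        return float(self.moment[0])


def slice_resultants(pressure: PressureField, surface: TrunkSurface) -> SliceResultants:
    """Integrate pressure into per-slice resultants and centres of force."""
    forces, points, w = _cell_forces(pressure.p, surface)
    f_slice = forces.sum(axis=0)
    w_sum = w.sum(axis=0)
    loaded = w_sum > 0
    center = np.full((surface.n_z, 3), np.nan)
    if loaded.any():
        weighted = (points * w[..., None]).sum(axis=0)
        center[loaded] = weighted[loaded] / w_sum[loaded, None]
    return SliceResultants(z=surface.z.copy(), force=f_slice, center=center, loaded=loaded)


def reduce_wrench(
    pressure: PressureField,
    surface: TrunkSurface,
    point: Optional[np.ndarray] = None,
) -> ForceScrew:
    """Reduce the pressure field to a wrench at ``point``.

    ``point`` defaults to the lumbar centre on the body surface (the
    deepest point of the posterior midline profile).
    """
    if point is None:
        point = lumbar_center(surface).point
    point = np.asarray(point, dtype=float)
    forces, points, _ = _cell_forces(pressure.p, surface)
    total_f = forces.reshape(-1, 3).sum(axis=0)
    lever = points - point
    total_m = np.cross(lever.reshape(-1, 3), forces.reshape(-1, 3)).sum(axis=0)
    return ForceScrew(
        force=total_f,
        moment=total_m,
        point=point,
        slices=slice_resultants(pressure, surface),
    )


def transport_wrench(screw: ForceScrew, new_point: np.ndarray) -> ForceScrew:
    """Transport the wrench to a different reduction point."""
    new_point = np.asarray(new_point, dtype=float)
    moment = screw.moment + np.cross(screw.point - new_point, screw.force)
    return ForceScrew(force=screw.force.copy(), moment=moment, point=new_point,
                      slices=screw.slices)
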