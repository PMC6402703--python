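"""Belt positioning and tension distribution with belt-skin adhesion.

The belt band is centred vertically on the lumbar lordosis centre and
tightened to a nominal stretch (manufacturer recommendation: 20%), which
fixes its rest length per grid row. The tension per unit width along the
belt then obeys a capstan-type equilibrium of an infinitesimal belt
element sticking to the skin:

    dT/ds + xi * a * T / R(s) = 0,

where ``a`` is the coefficient of adhesion of the skin/textile contact,
``xi`` in [0, 1] interpolates between pure sliding (0) and fully mobilised
adhesion (1), and R is the local convex curvature radius. On concave
segments the belt lifts off and T is constant. The locking kinematics set
the boundary layout:

- ``frictionless``: no shear transfer, T uniform at the anchor tension;
- ``symmetric``: both hands pull to the front; tension decays from the
  closure (90 deg) both ways around, meeting at the back midline (270 deg);
- ``asymmetric``: one hand holds and the other pulls the strap all the way
  around; tension decays one way from the closure over the full wrap,
  leaving a left/right asymmetric field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .fabric_mechanics import BeltDesign
from .trunk_surface import CurvatureField, TrunkSurface, angular_curvature, lumbar_center

__all__ = [
    "ContactModel",
    "Placement",
    "StrainField",
    "TensionField",
    "place_belt",
    "tension_with_adhesion",
]

LOCKING_MODES = ("frictionless", "symmetric", "asymmetric")


@dataclass(frozen=True)
class ContactModel:
    """Skin/textile contact: coefficient of adhesion, sticking fraction, locking."""

    adhesion: float = 0.3
    xi: float = 1.0
    locking: str = "frictionless"

    def __post_init__(self) -> None:
        if self.adhesion < 0:
            raise ValueError("coefficient of adhesion must be >= 0")
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("sticking fraction xi must lie in [0, 1]")
        if self.locking not in LOCKING_MODES:
            raise ValueError(f"locking must be one of {LOCKING_MODES}")

    @property
    def effective_adhesion(self) -> float:
        """xi * a, the decay coefficient of the tension equilibrium; 0 if frictionless."""
        if self.locking == "frictionless":
            return 0.0
        return self.xi * self.adhesion


@dataclass
class Placement:
    """Belt position on a trunk: covered rows, rest length, anchor."""

    belt: BeltDesign
    z_center: float
    rows: np.ndarray          # boolean mask over z levels covered by the belt
    mask: np.ndarray          # (n_theta, n_z) contact mask
    circumference0: np.ndarray  # per covered row, at placement time (m)
    rest_length: np.ndarray     # per covered row (m)
    nominal_stretch: float
    anchor_theta: float


@dataclass
class StrainField:
    """Warp-direction strain eps1 and Poisson-coupled transverse strain eps2."""

    eps1: np.ndarray
    eps2: np.ndarray


@dataclass
class TensionField:
    """Belt tension per unit width on the grid (N/m), zero off the belt band.

    ``T1`` acts along the belt (angular) direction, ``T2`` along the axial
    direction via the Poisson coupling; both are non-negative.
    """

    T1: np.ndarray
    T2: np.ndarray
    strain: StrainField
    arc: np.ndarray  # (n_theta, n_z) segment lengths used for the integration

    def __post_init__(self) -> None:
        if np.any(self.T1 < 0) or np.any(self.T2 < 0):
            raise ValueError("tensions must be non-negative")


def place_belt(
    surface: TrunkSurface,
    belt: BeltDesign,
    nominal_stretch: float = 0.20,
    center_z: Optional[float] = None,
) -> Placement:
    """Centre the belt band on the lumbar centre and fix its rest lengths.

    The per-row rest length is circumference / (1 + nominal_stretch), so
    that the freshly closed belt is exactly at the nominal stretch.
    Raises ``ValueError`` if the band does not fit in the scanned z range.
    """
    if center_z is None:
        center_z = lumbar_center(surface).z
    half = belt.height / 2.0
    zlo, zhi = center_z - half, center_z + half
    eps = surface.dz / 2 + 1e-12
    if zlo < surface.z[0] - eps or zhi > surface.z[-1] + eps:
        raise ValueError(
            f"belt band [{zlo:.3f}, {zhi:.3f}] m exceeds scan extent "
            f"[{surface.z[0]:.3f}, {surface.z[-1]:.3f}] m"
        )
    rows = (surface.z >= zlo - 1e-12) & (surface.z <= zhi + 1e-12)
    mask = np.zeros((surface.n_theta, surface.n_z), dtype=bool)
    mask[:, rows] = True
    circ = surface.circumference()[rows]
    rest = circ / (1.0 + nominal_stretch)
    return Placement(
        belt=belt,
        z_center=float(center_z),
        rows=rows,
        mask=mask,
        circumference0=circ,
        rest_length=rest,
        nominal_stretch=float(nominal_stretch),
        anchor_theta=float(belt.closure_angle),
    )


def _integrate_row(
    T0: float,
    gamma: np.ndarray,
    ds: np.ndarray,
    anchor: int,
    coeff: float,
    mode: str,
) -> np.ndarray:
    """Integrate dT/ds = -coeff * max(gamma, 0) * T from the anchor node.

    Uses the exact exponential update per segment (midpoint curvature),
    which reproduces the capstan closed form on circular sections to
    machine precision. ``ds[i]`` is the arc step from node i to node i+1.
    """
    n = gamma.size
    g = np.clip(gamma, 0.0, None)
    gmid = 0.5 * (g + np.roll(g, -1))  # per forward segment i -> i+1
    seg = coeff * gmid * ds  # decay exponent of segment i -> i+1
    if coeff == 0.0:
        return np.full(n, T0)
    if mode == "asymmetric":
        # one-way full wrap in +theta direction from the anchor
        order = (anchor + np.arange(n)) % n
        cum = np.concatenate([[0.0], np.cumsum(seg[order[:-1]])])
        T = np.empty(n)
        T[order] = T0 * np.exp(-cum)
        return T
    # symmetric: decay both ways from the anchor, meet at the opposite node
    fwd = (anchor + np.arange(n // 2 + 1)) % n
    cum_f = np.concatenate([[0.0], np.cumsum(seg[fwd[:-1]])])
    bwd = (anchor - np.arange(n - n // 2 + 1)) % n
    # stepping from node i to i-1 traverses segment i-1
    cum_b = np.concatenate([[0.0], np.cumsum(seg[bwd[1:]])])
    T = np.zeros(n)
    T[fwd] = T0 * np.exp(-cum_f)
    t_b = T0 * np.exp(-cum_b)
    # shared nodes (anchor, meeting point) take the smaller feed
    T[bwd] = np.where(T[bwd] > 0, np.minimum(T[bwd], t_b), t_b)
    return T


def tension_with_adhesion(
    placement: Placement,
    surface: TrunkSurface,
    contact: ContactModel,
    curvature: Optional[CurvatureField] = None,
    tension_scale: float = 1.0,
) -> TensionField:
    """Solve the tension distribution of the placed belt on the surface.

    The anchor tension per row is ``k_eq * stretch * tension_scale`` with the
    stretch recomputed from the row's *current* circumference and the fixed
    rest length (body compression slackens the belt). ``tension_scale``
    supports incremental load ramps.
    """
    if curvature is None:
        curvature = angular_curvature(surface)
    belt = placement.belt
    nt, nz = surface.n_theta, surface.n_z
    T1 = np.zeros((nt, nz))
    ds_all = surface.arc_lengths()
    anchor = surface.theta_index(placement.anchor_theta)
    coeff = contact.effective_adhesion
    mode = contact.locking

    circ_now = surface.circumference()
    row_idx = np.flatnonzero(placement.rows)
    for j, row in enumerate(row_idx):
        stretch = circ_now[row] / placement.rest_length[j] - 1.0
        T0 = belt.k_eq * max(stretch, 0.0) * tension_scale
        if T0 == 0.0:
            continue
        if mode == "frictionless" or coeff == 0.0:
            T1[:, row] = T0
        else:
            T1[:, row] = _integrate_row(
                T0, curvature.gamma1[:, row], ds_all[:, row], anchor, coeff, mode
            )

    eps1 = T1 / belt.k_eq
    eps2 = -belt.poisson * eps1
    if belt.transverse_stiffness is not None:
        T2 = np.clip(belt.transverse_stiffness * eps2, 0.0, None)
    else:
        T2 = np.zeros_like(T1)
    return TensionField(T1=T1, T2=T2, strain=StrainField(eps1=eps1, eps2=eps2), arc=ds_all)
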