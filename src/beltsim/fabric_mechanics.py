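"""Fabric tensile mechanics and belt equivalent stiffness.

Lumbar belts are assemblies of woven/knitted panels. Each panel is modelled
as a linear spring whose stiffness is the tangent slope at the beginning of
the *unloading* branch of its tensile force-per-unit-width vs. strain curve
(belts are stretched, locked on the body, and then relax, so the unloading
tangent is the stiffness that matters in use). Panels combine as a
series/parallel spring network into a single belt equivalent stiffness
``k_eq`` with the same units as the fabric stiffnesses: tension per unit
width per unit strain (N/m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

__all__ = [
    "TensileCurve",
    "FabricSpec",
    "Leaf",
    "Series",
    "Parallel",
    "SpringNetwork",
    "BeltDesign",
    "unloading_stiffness",
    "equivalent_stiffness",
    "tension_from_strain",
    "network_from_list",
]


@dataclass(frozen=True)
class TensileCurve:
    """One tensile-test ramp: loading then unloading of a fabric specimen.

    Parameters
    ----------
    elongation_mm, force_n:
        Sampled crosshead elongation (mm) and force (N), time ordered.
    phase:
        Per-sample label, ``"loading"`` or ``"unloading"``.
    specimen_width_mm, gauge_length_mm:
        Specimen geometry; strain = elongation / gauge length and tension
        per unit width = force / width.
    """

    elongation_mm: np.ndarray
    force_n: np.ndarray
    phase: np.ndarray
    specimen_width_mm: float
    gauge_length_mm: float

    def __post_init__(self) -> None:
        e = np.asarray(self.elongation_mm, dtype=float)
        f = np.asarray(self.force_n, dtype=float)
        ph = np.asarray(self.phase)
        object.__setattr__(self, "elongation_mm", e)
        object.__setattr__(self, "force_n", f)
        object.__setattr__(self, "phase", ph)
        if e.ndim != 1 or e.shape != f.shape or ph.shape != e.shape:
            raise ValueError("elongation, force and phase must be 1-D and equal length")
        if self.specimen_width_mm <= 0 or self.gauge_length_mm <= 0:
            raise ValueError("specimen width and gauge length must be positive")
        if np.any(f < 0):
            raise ValueError("forces must be non-negative")
        for name in ("loading", "unloading"):
            if np.count_nonzero(ph == name) not in (0,) and np.count_nonzero(ph == name) < 2:
                raise ValueError(f"phase '{name}' needs at least 2 points")

    @property
    def strain(self) -> np.ndarray:
        """Engineering strain (dimensionless)."""
        return self.elongation_mm / self.gauge_length_mm

    @property
    def tension(self) -> np.ndarray:
        """Tensile force per unit width (N/m)."""
        return self.force_n / (self.specimen_width_mm * 1e-3)

    @classmethod
    def from_arrays(
        cls,
        elongation_mm: np.ndarray,
        force_n: np.ndarray,
        specimen_width_mm: float,
        gauge_length_mm: float,
    ) -> "TensileCurve":
        """Build a curve splitting phases at the global force maximum."""
        f = np.asarray(force_n, dtype=float)
        imax = int(np.argmax(f))
        phase = np.array(
            ["loading"] * (imax + 1) + ["unloading"] * (len(f) - imax - 1)
        )
        return cls(elongation_mm, force_n, phase, specimen_width_mm, gauge_length_mm)


@dataclass(frozen=True)
class FabricSpec:
    """Per-direction stiffness and Poisson ratio of one fabric.

    Stiffness is tension per unit width per unit strain (N/m). Negative
    Poisson ratios occur for some technical textiles. A fabric tested in a
    single direction (e.g. a narrow ribbon) may omit the second direction
    and is then usable in either orientation (direction ``"any"``).
    """

    name: str
    stiffness_warp: float
    poisson_warp: float = 0.0
    stiffness_weft: float | None = None
    poisson_weft: float | None = None

    def __post_init__(self) -> None:
        if self.stiffness_warp <= 0:
            raise ValueError(f"fabric {self.name}: warp stiffness must be > 0")
        if self.stiffness_weft is not None and self.stiffness_weft <= 0:
            raise ValueError(f"fabric {self.name}: weft stiffness must be > 0")
        for nu in (self.poisson_warp, self.poisson_weft):
            if nu is not None and not (-1.0 < nu < 1.0):
                raise ValueError(f"fabric {self.name}: Poisson ratio {nu} outside (-1, 1)")

    def stiffness(self, direction: str = "warp") -> float:
        if direction == "warp":
            return self.stiffness_warp
        if direction == "weft":
            if self.stiffness_weft is None:
                # single-direction fabric: usable in either orientation
                return self.stiffness_warp
            return self.stiffness_weft
        if direction == "any":
            return self.stiffness_warp
        raise ValueError(f"unknown direction {direction!r}")

    def poisson(self, direction: str = "warp") -> float:
        if direction in ("warp", "any"):
            return self.poisson_warp
        if direction == "weft":
            return self.poisson_weft if self.poisson_weft is not None else self.poisson_warp
        raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class Leaf:
    """A single fabric panel spring (``multiplicity`` identical springs in parallel)."""

    fabric: str
    direction: str = "warp"
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclass(frozen=True)
class Series:
    children: tuple

    def __post_init__(self) -> None:
        if len(self.children) == 0:
            raise ValueError("series node needs at least one child")


@dataclass(frozen=True)
class Parallel:
    children: tuple

    def __post_init__(self) -> None:
        if len(self.children) == 0:
            raise ValueError("parallel node needs at least one child")


SpringNetwork = Union[Leaf, Series, Parallel]


def network_from_list(expr: Sequence) -> SpringNetwork:
    """Parse a nested-list network expression.

    ``["series", child, ...]`` / ``["parallel", child, ...]`` /
    ``["leaf", fabric, direction, multiplicity]`` (direction and
    multiplicity optional).
    """
    if not isinstance(expr, (list, tuple)) or len(expr) == 0:
        raise ValueError("network expression must be a non-empty list")
    head = expr[0]
    if head == "leaf":
        args = list(expr[1:])
        if not 1 <= len(args) <= 3:
            raise ValueError("leaf takes fabric[, direction[, multiplicity]]")
        fabric = str(args[0])
        direction = str(args[1]) if len(args) > 1 else "warp"
        mult = int(args[2]) if len(args) > 2 else 1
        return Leaf(fabric, direction, mult)
    if head in ("series", "parallel"):
        children = tuple(network_from_list(c) for c in expr[1:])
        return Series(children) if head == "series" else Parallel(children)
    raise ValueError(f"unknown network node {head!r}")


def equivalent_stiffness(
    network: SpringNetwork, fabrics: Mapping[str, FabricSpec]
) -> float:
    """Reduce a spring network to one stiffness (N/m).

    Parallel springs add stiffnesses; serial springs add compliances
    (the equivalent is the inverse of the summed compliances). A leaf with
    multiplicity m counts as m identical springs in parallel.
    """
    if isinstance(network, Leaf):
        if network.fabric not in fabrics:
            raise KeyError(f"unknown fabric {network.fabric!r}")
        k = fabrics[network.fabric].stiffness(network.direction)
        if k <= 0:
            raise ValueError(f"non-positive stiffness for fabric {network.fabric!r}")
        return float(network.multiplicity * k)
    if isinstance(network, Parallel):
        return float(sum(equivalent_stiffness(c, fabrics) for c in network.children))
    if isinstance(network, Series):
        compliance = sum(1.0 / equivalent_stiffness(c, fabrics) for c in network.children)
        return float(1.0 / compliance)
    raise TypeError(f"not a spring network node: {network!r}")


def unloading_stiffness(
    curve: TensileCurve,
    window_fraction: float = 0.02,
    min_points: int = 5,
) -> float:
    """Stiffness as the tangent slope at the start of unloading (N/m).

    A straight line is least-squares fitted to tension-per-width vs strain
    over the first ``window_fraction`` of the unloading strain range (at
    least ``min_points`` samples).
    """
    mask = curve.phase == "unloading"
    if not np.any(mask):
        raise ValueError("curve has no unloading phase")
    eps = curve.strain[mask]
    ten = curve.tension[mask]
    if eps.size < min_points:
        raise ValueError(
            f"unloading phase has {eps.size} points; at least {min_points} required"
        )
    eps0 = eps[0]
    span = eps0 - eps.min()
    if span <= 0:
        raise ValueError("unloading strain does not decrease")
    sel = eps >= eps0 - window_fraction * span
    n_sel = max(int(np.count_nonzero(sel)), min_points)
    # unloading samples are time ordered from the load peak downwards
    e_fit, t_fit = eps[:n_sel], ten[:n_sel]
    slope = np.polyfit(e_fit, t_fit, 1)[0]
    if slope <= 0:
        raise ValueError(f"non-positive unloading tangent ({slope:.3g} N/m)")
    return float(slope)


@dataclass(frozen=True)
class BeltDesign:
    """A belt: its spring network, equivalent stiffness and geometry.

    ``k_eq`` is the warp-direction (circumferential) tension stiffness per
    unit width (N/m). ``transverse_stiffness`` drives the axial tension T2
    through the Poisson coupling; set it to ``None`` to disable T2.
    """

    name: str
    k_eq: float
    height: float = 0.26
    poisson: float = 0.3
    transverse_stiffness: float | None = None
    network: SpringNetwork | None = None
    closure_angle: float = float(np.pi / 2)

    def __post_init__(self) -> None:
        if self.k_eq <= 0:
            raise ValueError("k_eq must be > 0")
        if self.height <= 0:
            raise ValueError("height must be > 0")
        if not (-1.0 < self.poisson < 1.0):
            raise ValueError("belt Poisson ratio outside (-1, 1)")
        if self.transverse_stiffness is not None and self.transverse_stiffness < 0:
            raise ValueError("transverse stiffness must be >= 0")

    @classmethod
    def from_network(
        cls,
        name: str,
        network: SpringNetwork,
        fabrics: Mapping[str, FabricSpec],
        **kwargs,
    ) -> "BeltDesign":
        k_eq = equivalent_stiffness(network, fabrics)
        return cls(name=name, k_eq=k_eq, network=network, **kwargs)


def tension_from_strain(belt: BeltDesign, strain: float) -> float:
    """Belt tension per unit width, T = k_eq * strain, clamped at 0 for slack."""
    return float(belt.k_eq * max(float(strain), 0.0))
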