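"""Reference fabric and belt catalog.

Measured unloading-tangent stiffnesses (N/m of tension per unit width, per
unit strain) and Poisson ratios for the five panel fabrics of two
commercial lumbar-support belts, and the spring networks describing how the
panels are assembled. The networks are data, not code: users can define any
belt architecture in a belt definition file (see :mod:`beltsim.io_cli`).

Belt A is assembled from a twill panel (fabric 1) and two coated plain-weave
panels (fabric 3) in series. Belt B chains a double-face plain weave
(fabric 2), a narrow plain-weave ribbon (fabric 4, tested in a single
direction) and a laminated knit (fabric 5); its network reduces
algebraically to the series combination of the three panel stiffnesses.
"""

from __future__ import annotations

from .fabric_mechanics import BeltDesign, FabricSpec, Leaf, Series, equivalent_stiffness

__all__ = ["reference_fabrics", "belt_a", "belt_b", "reference_belts"]


def reference_fabrics() -> dict[str, FabricSpec]:
    """Measured stiffness / Poisson ratio of the five catalog fabrics."""
    return {
        "fabric1": FabricSpec("fabric1", 39_226.0, -0.08, 38_948.0, -0.32),
        "fabric2": FabricSpec("fabric2", 16_611.0, -0.03, 52_772.0, -0.35),
        "fabric3": FabricSpec("fabric3", 41_421.0, 0.52, 32_321.0, 0.45),
        # 35 mm ribbon, tested in a single direction; stored direction-agnostic
        "fabric4": FabricSpec("fabric4", 101_433.0, 0.30),
        "fabric5": FabricSpec("fabric5", 51_429.0, 0.46, 57_470.0, 0.55),
    }


def _transverse_series(fabrics, names) -> float:
    """Series combination of the weft-direction stiffnesses of the panels."""
    return 1.0 / sum(1.0 / fabrics[n].stiffness("weft") for n in names)


def belt_a(height: float = 0.26) -> BeltDesign:
    fabrics = reference_fabrics()
    network = Series(
        (Leaf("fabric1", "warp"), Leaf("fabric3", "warp"), Leaf("fabric3", "warp"))
    )
    return BeltDesign(
        name="Belt A",
        k_eq=equivalent_stiffness(network, fabrics),
        height=height,
        poisson=0.3,
        transverse_stiffness=_transverse_series(fabrics, ["fabric1", "fabric3", "fabric3"]),
        network=network,
    )


def belt_b(height: float = 0.26) -> BeltDesign:
    fabrics = reference_fabrics()
    network = Series(
        (Leaf("fabric2", "warp"), Leaf("fabric4", "any"), Leaf("fabric5", "warp"))
    )
    return BeltDesign(
        name="Belt B",
        k_eq=equivalent_stiffness(network, fabrics),
        height=height,
        poisson=0.3,
        transverse_stiffness=_transverse_series(fabrics, ["fabric2", "fabric4", "fabric5"]),
        network=network,
    )


def reference_belts() -> dict[str, BeltDesign]:
    return {"A": belt_a(), "B": belt_b()}
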