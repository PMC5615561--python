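"""Layered skin slab and its 1D spatial discretization.

The slab is described surface-down as an ordered stack of homogeneous
layers, each with constant thermal conductivity ``k`` (W/m K), density
``rho`` (kg/m^3) and specific heat ``C`` (J/kg K).  The stack is
discretized on a uniform vertex-centred grid; every node carries the
material properties of the layer that contains it, with interface nodes
owned by the deeper layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SkinLayer",
    "LayerStack",
    "Grid1D",
    "thermal_diffusivity",
    "build_grid",
    "check_stability",
    "back_skin_stack",
]


def thermal_diffusivity(conductivity: float, density: float, specific_heat: float) -> float:
    """Thermal diffusivity a = k / (rho * C) in m^2/s.

    All arguments must be strictly positive.
    """
    if conductivity <= 0 or density <= 0 or specific_heat <= 0:
        raise ValueError(
            "conductivity, density and specific_heat must all be positive, got "
            f"k={conductivity}, rho={density}, C={specific_heat}"
        )
    return conductivity / (density * specific_heat)


@dataclass(frozen=True)
class SkinLayer:
    """One homogeneous tissue layer.

    Parameters
    ----------
    name
        Label, e.g. ``"epidermis"``.
    conductivity
        Thermal conductivity k, W/m K.
    density
        rho, kg/m^3.
    specific_heat
        C, J/kg K.
    thickness
        Layer thickness, m.
    """

    name: str
    conductivity: float
    density: float
    specific_heat: float
    thickness: float

    def __post_init__(self) -> None:
        for attr in ("conductivity", "density", "specific_heat", "thickness"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be strictly positive")

    @property
    def diffusivity(self) -> float:
        """k / (rho * C), m^2/s."""
        return thermal_diffusivity(self.conductivity, self.density, self.specific_heat)

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * C, J/m^3 K."""
        return self.density * self.specific_heat


@dataclass(frozen=True)
class LayerStack:
    """Ordered stack of skin layers, surface first."""

    layers: tuple[SkinLayer, ...]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("a LayerStack needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def total_depth(self) -> float:
        """Sum of layer thicknesses, m."""
        return float(sum(layer.thickness for layer in self.layers))

    @property
    def interfaces(self) -> np.ndarray:
        """Cumulative depths of the layer bottoms, m (last = total_depth)."""
        return np.cumsum([layer.thickness for layer in self.layers])

    @property
    def max_diffusivity(self) -> float:
        return max(layer.diffusivity for layer in self.layers)


def back_skin_stack(subcutaneous_thickness: float = 0.01) -> LayerStack:
    """Epidermis / dermis / subcutaneous stack for the human back.

    Trunk epidermis of 43 um, dermis 1.3 mm and a 10 mm subcutaneous layer;
    the subcutaneous thickness is configurable so the domain can be padded
    when a deeper slab is wanted.
    """
    return LayerStack(
        layers=(
            SkinLayer("epidermis", 0.24, 1200.0, 3590.0, 43e-6),
            SkinLayer("dermis", 0.45, 1200.0, 3300.0, 1.3e-3),
            SkinLayer("subcutaneous", 0.19, 1000.0, 2500.0, subcutaneous_thickness),
        )
    )


@dataclass(frozen=True)
class Grid1D:
    """Uniform vertex-centred grid over a layer stack.

    Nodes run from the surface (depth 0) to the bottom of the stack.  The
    per-node property arrays are those of the layer containing each node;
    a node on a layer interface takes the deeper layer's properties.
    Layer interfaces that do not fall on a node are snapped to the nearest
    node; the snapped interface depths are recorded.
    """

    spacing: float
    node_depths: np.ndarray = field(repr=False)
    node_conductivity: np.ndarray = field(repr=False)
    node_density: np.ndarray = field(repr=False)
    node_specific_heat: np.ndarray = field(repr=False)
    snapped_interfaces: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.node_depths)

    @property
    def total_depth(self) -> float:
        return float(self.node_depths[-1])

    @property
    def node_volumetric_heat_capacity(self) -> np.ndarray:
        return self.node_density * self.node_specific_heat

    def node_index(self, depth: float) -> float:
        """Fractional node index of a physical depth."""
        if depth < 0 or depth > self.total_depth + 0.5 * self.spacing:
            raise ValueError(f"depth {depth} m outside domain [0, {self.total_depth}] m")
        return depth / self.spacing


def build_grid(stack: LayerStack, spacing: float) -> Grid1D:
    """Discretize ``stack`` on a uniform grid with node distance ``spacing``.

    ``spacing`` must be positive and no larger than the thinnest layer.
    The grid spans [0, total_depth] with ``round(total_depth/spacing)``
    intervals; interfaces are snapped to the nearest node.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    thinnest = min(layer.thickness for layer in stack.layers)
    if spacing > thinnest:
        raise ValueError(
            f"grid spacing {spacing} m exceeds the thinnest layer ({thinnest} m); "
            "refine the grid or merge layers"
        )

    n_intervals = int(round(stack.total_depth / spacing))
    depths = np.arange(n_intervals + 1) * spacing
    # snap interface depths to the nearest node so the grid stays uniform
    snapped = np.round(stack.interfaces / spacing) * spacing
    # deeper layer owns an interface node: searchsorted right maps a depth
    # equal to an interface onto the next layer
    layer_idx = np.searchsorted(snapped, depths, side="right")
    layer_idx = np.clip(layer_idx, 0, len(stack.layers) - 1)

    k = np.array([layer.conductivity for layer in stack.layers])[layer_idx]
    rho = np.array([layer.density for layer in stack.layers])[layer_idx]
    cp = np.array([layer.specific_heat for layer in stack.layers])[layer_idx]

    return Grid1D(
        spacing=float(spacing),
        node_depths=depths,
        node_conductivity=k,
        node_density=rho,
        node_specific_heat=cp,
        snapped_interfaces=snapped,
    )


def check_stability(max_diffusivity: float, dt: float, dx: float) -> tuple[float, bool]:
    """Fourier number Fo = a dt / dx^2 and the explicit-scheme stability flag.

    The forward-in-time central-in-space scheme is stable iff Fo < 0.5
    (strict).  ``max_diffusivity`` may be zero (Fo = 0, stable); negative
    arguments are rejected.
    """
    if max_diffusivity < 0 or dt <= 0 or dx <= 0:
        raise ValueError("max_diffusivity must be >= 0 and dt, dx > 0")
    fo = max_diffusivity * dt / dx**2
    return fo, fo < 0.5
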