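"""Docking search-space construction.

Three protocols are provided:

* **default** — the Vina-style box built from a bound ligand: the
  axis-aligned bounding box of its heavy atoms, grown by 10 A per
  dimension (5 A per side), then by a further 5 A on one randomly chosen
  side of each dimension, and finally floored at 22.5 A per dimension.
* **optimized** — a cube of edge ``2.857 x Rg`` centered on the pocket,
  equivalently an Rg-to-edge ratio of 0.35; the size adapts to the query
  ligand instead of the crystallographic pose.
* **sweep** — a grid of cubes (default edges 2, 4, ..., 36 A) sharing the
  pocket center, used to map docking accuracy against relative box size.

A Vina-style ``key = value`` configuration writer/parser rounds out the
module so boxes can be handed to a docking engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import PocketSpec

__all__ = [
    "DockingBox",
    "SweepSpec",
    "default_box",
    "optimized_box",
    "sweep_boxes",
    "relative_box_size",
    "box_volume",
    "write_docking_config",
    "parse_docking_config",
    "box_from_config",
    "EDGE_TO_RG",
    "OPTIMAL_RATIO",
    "DEFAULT_MIN_EDGE",
]

#: optimized cubic edge as a multiple of the ligand radius of gyration
EDGE_TO_RG = 2.857
#: the equivalent Rg-to-edge ratio (prints as 0.35 at two decimals)
OPTIMAL_RATIO = 1.0 / EDGE_TO_RG
#: minimum edge of a default-protocol box, Angstrom
DEFAULT_MIN_EDGE = 22.5

_PROTOCOLS = ("default", "optimized", "sweep", "custom")


@dataclass(frozen=True)
class DockingBox:
    """An axis-aligned docking search space.

    ``center`` and ``size`` are in Angstroms; ``protocol`` records how the
    box was built.  Optimized boxes are always cubic and default boxes
    never have an edge below 22.5 A — both are enforced here.
    """

    center: tuple[float, float, float]
    size: tuple[float, float, float]
    protocol: str = "custom"

    def __post_init__(self) -> None:
        center = tuple(float(c) for c in self.center)
        size = tuple(float(s) for s in self.size)
        if len(center) != 3 or len(size) != 3:
            raise ValueError("center and size must each have three components")
        if not (np.all(np.isfinite(center)) and np.all(np.isfinite(size))):
            raise ValueError("box center and size must be finite")
        if min(size) <= 0:
            raise ValueError("box sizes must be positive")
        if self.protocol not in _PROTOCOLS:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.protocol == "optimized" and not (
            abs(size[0] - size[1]) < 1e-9 and abs(size[0] - size[2]) < 1e-9
        ):
            raise ValueError("optimized boxes must be cubic")
        if self.protocol == "default" and min(size) < DEFAULT_MIN_EDGE - 1e-9:
            raise ValueError(
                f"default boxes must have every edge >= {DEFAULT_MIN_EDGE} A"
            )
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "size", size)

    @property
    def is_cubic(self) -> bool:
        sx, sy, sz = self.size
        return abs(sx - sy) < 1e-9 and abs(sx - sz) < 1e-9

    @property
    def edge(self) -> float:
        """Edge length of a cubic box."""
        if not self.is_cubic:
            raise ValueError("edge is only defined for cubic boxes")
        return self.size[0]

    @property
    def lo(self) -> np.ndarray:
        return np.asarray(self.center) - np.asarray(self.size) / 2.0

    @property
    def hi(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.size) / 2.0

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> bool:
        """Do all points lie inside the box (within ``tol``)?"""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return bool(
            np.all(points >= self.lo - tol) and np.all(points <= self.hi + tol)
        )


@dataclass(frozen=True)
class SweepSpec:
    """Edge grid for the box-size sweep: 2-36 A in 2 A steps by default."""

    edge_min: float = 2.0
    edge_max: float = 36.0
    edge_step: float = 2.0

    def __post_init__(self) -> None:
        if self.edge_min <= 0 or self.edge_step <= 0:
            raise ValueError("edge_min and edge_step must be positive")
        if self.edge_min > self.edge_max:
            raise ValueError("edge_min must not exceed edge_max")

    @property
    def edges(self) -> np.ndarray:
        # +step/2 guards the inclusive upper bound against float drift
        return np.arange(self.edge_min, self.edge_max + self.edge_step / 2.0,
                         self.edge_step)


def default_box(
    bound_ligand_coords: np.ndarray, seed: int | np.random.Generator = 0
) -> DockingBox:
    """Vina-style default box from the heavy atoms of a bound ligand.

    Procedure: start from the axis-aligned bounding box of the points;
    grow each dimension by 10 A (5 A per side, symmetric); then flip a
    fair seeded coin per dimension (x, y, z order) and grow one side by a
    further 5 A, shifting the center by +/-2.5 A; finally expand any
    dimension still below 22.5 A symmetrically about its current center.
    The resulting sizes are seed-independent; only the center depends on
    the coin flips.
    """
    coords = np.atleast_2d(np.asarray(bound_ligand_coords, dtype=float))
    if coords.size == 0:
        raise ValueError("need at least one ligand atom to build a default box")
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("bound ligand coordinates must be an (n, 3) array")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    extent = hi - lo
    center = (lo + hi) / 2.0
    size = extent + 10.0
    # one random side per dimension gains a further 5 A
    for axis in range(3):
        direction = 1.0 if rng.integers(0, 2) == 1 else -1.0
        size[axis] += 5.0
        center[axis] += direction * 2.5
    size = np.maximum(size, DEFAULT_MIN_EDGE)
    return DockingBox(tuple(center), tuple(size), protocol="default")


def optimized_box(rg: float, pocket: PocketSpec) -> DockingBox:
    """Ligand-size-adaptive cubic box: edge 2.857 x Rg, pocket-centered."""
    rg = float(rg)
    if not np.isfinite(rg) or rg <= 0:
        raise ValueError("radius of gyration must be positive and finite")
    edge = EDGE_TO_RG * rg
    return DockingBox(pocket.center, (edge, edge, edge), protocol="optimized")


def sweep_boxes(pocket: PocketSpec, spec: SweepSpec = SweepSpec()) -> list[DockingBox]:
    """Cubic boxes over the sweep grid, all sharing the pocket center."""
    return [
        DockingBox(pocket.center, (float(e),) * 3, protocol="sweep")
        for e in spec.edges
    ]


def relative_box_size(rg: float, box: DockingBox) -> float:
    """Rg-to-edge ratio; the x-axis of the box-size sweep.  Cubic boxes only."""
    if not box.is_cubic:
        raise ValueError("relative box size is undefined for non-cubic boxes")
    if rg < 0:
        raise ValueError("radius of gyration must be non-negative")
    return float(rg) / box.edge


def box_volume(box: DockingBox) -> float:
    """Volume of the search space in cubic Angstroms."""
    return float(np.prod(box.size))


def write_docking_config(
    box: DockingBox,
    receptor_path: str,
    ligand_path: str,
    out_path: str | Path,
    **extra: object,
) -> None:
    """Write a Vina-style ``key = value`` configuration file.

    Center and size values are written with three decimals, so a parse
    recovers the box to 1e-3 A.  Extra keyword arguments (for example
    ``exhaustiveness`` or ``num_modes``) are passed through verbatim.
    """
    cx, cy, cz = box.center
    sx, sy, sz = box.size
    lines = [
        f"receptor = {receptor_path}",
        f"ligand = {ligand_path}",
        f"center_x = {cx:.3f}",
        f"center_y = {cy:.3f}",
        f"center_z = {cz:.3f}",
        f"size_x = {sx:.3f}",
        f"size_y = {sy:.3f}",
        f"size_z = {sz:.3f}",
    ]
    for key, value in extra.items():
        lines.append(f"{key} = {value}")
    Path(out_path).write_text("\n".join(lines) + "\n")


def parse_docking_config(path: str | Path) -> dict[str, object]:
    """Parse a Vina-style configuration file back into a key/value dict.

    Numeric values are converted to floats; everything else stays a string.
    """
    out: dict[str, object] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        try:
            out[key] = float(value)
        except ValueError:
            out[key] = value
    return out


def box_from_config(config: dict[str, object], protocol: str = "custom") -> DockingBox:
    """Rebuild a :class:`DockingBox` from a parsed configuration dict."""
    try:
        center = tuple(float(config[f"center_{ax}"]) for ax in "xyz")
        size = tuple(float(config[f"size_{ax}"]) for ax in "xyz")
    except KeyError as exc:
        raise ValueError(f"configuration is missing box key {exc}") from exc
    return DockingBox(center, size, protocol=protocol)
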