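"""Ligand size descriptors and pose geometry.

The central quantity is the heavy-atom radius of gyration

    Rg = sqrt( (1/N) * sum_k | r_k - r_center |^2 )

where N is the number of heavy atoms, r_k their Cartesian coordinates and
r_center their unweighted geometric center.  No mass weighting is applied
and hydrogens are excluded throughout.  The module also provides the rigid
motions used when docking against predicted pockets (uniform random
reorientation, recentering onto a pocket center) and the distance criterion
for calling a pocket-center prediction successful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .chem_io import LigandStructure

__all__ = [
    "PocketSpec",
    "RgSummary",
    "geometric_center",
    "radius_of_gyration",
    "rg_from_coords",
    "rg_ensemble_summary",
    "random_rotation_matrix",
    "random_reorientation",
    "recenter_to_pocket",
    "pocket_prediction_success",
    "read_pocket_table",
    "POCKET_SUCCESS_CUTOFF",
]

#: predicted pocket centers farther than this from the experimental center
#: (strictly) count as prediction failures, in Angstroms
POCKET_SUCCESS_CUTOFF = 8.0


@dataclass(frozen=True)
class PocketSpec:
    """A binding-pocket center with its provenance.

    ``source`` records whether the center came from an experimental
    complex (geometric center of the bound ligand) or from a pocket
    predictor.
    """

    center: tuple[float, float, float]
    source: str = "experimental"

    def __post_init__(self) -> None:
        center = tuple(float(c) for c in self.center)
        if len(center) != 3 or not np.all(np.isfinite(center)):
            raise ValueError("pocket center must be three finite coordinates")
        object.__setattr__(self, "center", center)
        if self.source not in ("experimental", "predicted"):
            raise ValueError("source must be 'experimental' or 'predicted'")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class RgSummary:
    """Radius-of-gyration statistics over a conformer ensemble."""

    rg_single: float   # Rg of the designated low-energy conformer, Angstrom
    rg_mean: float     # mean Rg over the rotamer ensemble
    rg_sd: float       # population SD of Rg over the rotamer ensemble
    n_rotamers: int

    def __post_init__(self) -> None:
        if self.rg_single < 0 or self.rg_sd < 0 or self.n_rotamers < 1:
            raise ValueError("invalid Rg summary")


def geometric_center(coords: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean of a set of 3-D points."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] == 0:
        raise ValueError("coords must be a non-empty (n, 3) array")
    return coords.mean(axis=0)


def rg_from_coords(coords: np.ndarray) -> float:
    """Radius of gyration of a point set about its geometric center."""
    coords = np.asarray(coords, dtype=float)
    center = geometric_center(coords)
    return float(np.sqrt(np.mean(np.sum((coords - center) ** 2, axis=1))))


def radius_of_gyration(ligand: LigandStructure, conformer: int = 0) -> float:
    """Heavy-atom radius of gyration of one conformer, in Angstroms.

    Hydrogens are excluded and atoms are unweighted.  Raises ``ValueError``
    when the conformer has no heavy atoms.
    """
    heavy = ligand.heavy_coords(conformer)
    if heavy.shape[0] == 0:
        raise ValueError(f"ligand {ligand.name!r} has no heavy atoms")
    return rg_from_coords(heavy)


def rg_ensemble_summary(
    ligand: LigandStructure,
    rotamer_hook: Callable[[LigandStructure, int], np.ndarray] | None = None,
    n_rotamers: int = 100,
) -> RgSummary:
    """Summarise Rg over a rotamer ensemble.

    ``rg_single`` comes from the designated low-energy conformer (index 0).
    When the ligand carries extra conformers those are the rotamer
    ensemble; otherwise, if a ``rotamer_hook`` is supplied (for example a
    wrapper around an external rotamer generator) it is asked for
    ``n_rotamers`` conformers as an ``(n, n_atoms, 3)`` array.  A rigid
    ligand with no rotamers reports its single conformer as the ensemble.
    """
    rg_single = radius_of_gyration(ligand, 0)
    if ligand.n_conformers > 1:
        ensemble = ligand.conformers[1:]
    elif rotamer_hook is not None:
        ensemble = np.asarray(rotamer_hook(ligand, n_rotamers), dtype=float)
        if ensemble.ndim != 3 or ensemble.shape[1] != ligand.n_atoms:
            raise ValueError("rotamer hook returned a malformed ensemble")
    else:
        ensemble = ligand.conformers[:1]
    mask = ligand.heavy_mask
    rgs = np.array([rg_from_coords(conf[mask]) for conf in ensemble])
    return RgSummary(
        rg_single=rg_single,
        rg_mean=float(rgs.mean()),
        rg_sd=float(rgs.std()),
        n_rotamers=len(rgs),
    )


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn uniformly (Haar measure) over 3-D rotations.

    Built from a unit quaternion sampled uniformly on the 3-sphere: four
    independent standard normal deviates, normalised.  The rotational
    invariance of the multivariate normal makes the quaternion — and hence
    the rotation — exactly uniform.
    """
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_reorientation(
    coords: np.ndarray, seed: int | np.random.Generator
) -> np.ndarray:
    """Spin a conformer uniformly at random about its geometric center.

    The rotation is rigid: every pairwise interatomic distance is
    preserved.  The same seed always reproduces the same orientation.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    coords = np.asarray(coords, dtype=float)
    center = geometric_center(coords)
    rot = random_rotation_matrix(rng)
    return (coords - center) @ rot.T + center


def recenter_to_pocket(
    coords: np.ndarray,
    pocket: PocketSpec,
    heavy_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Translate a conformer so its heavy-atom center sits on the pocket.

    ``heavy_mask`` selects the atoms whose geometric center is matched to
    the pocket center (all atoms when omitted).  Internal geometry is
    untouched: the same translation is applied to every atom.
    """
    coords = np.asarray(coords, dtype=float)
    ref = coords if heavy_mask is None else coords[np.asarray(heavy_mask, dtype=bool)]
    shift = pocket.xyz - geometric_center(ref)
    return coords + shift


def pocket_prediction_success(
    predicted: PocketSpec, experimental: PocketSpec
) -> bool:
    """Is the predicted center strictly within 8 A of the experimental one?

    The inequality is strict: a center exactly 8.0 A away fails.
    """
    dist = float(np.linalg.norm(predicted.xyz - experimental.xyz))
    return dist < POCKET_SUCCESS_CUTOFF


def read_pocket_table(path: str | Path) -> dict[str, PocketSpec]:
    """Read pocket centers from a delimited table.

    Expected columns: ``id``, ``x``, ``y``, ``z`` and optionally
    ``source`` (defaults to ``experimental``).  The delimiter is sniffed,
    so comma-, tab- and whitespace-separated tables all work.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    table.columns = [c.strip().lower() for c in table.columns]
    required = {"id", "x", "y", "z"}
    if not required.issubset(table.columns):
        raise ValueError(f"pocket table must have columns {sorted(required)}")
    out: dict[str, PocketSpec] = {}
    for _, row in table.iterrows():
        source = str(row.get("source", "experimental")).strip() or "experimental"
        out[str(row["id"])] = PocketSpec(
            (float(row["x"]), float(row["y"]), float(row["z"])), source
        )
    return out
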