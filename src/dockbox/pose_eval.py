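"""Binding-pose evaluation against a reference pose.

Three complementary accuracy measures are computed in the fixed receptor
frame (no superposition, matching how docked poses are compared to the
crystallographic ligand):

* heavy-atom RMSD with a 1:1 atom correspondence,
* recovery of specific protein-ligand contacts (heavy-atom pairs within a
  distance cutoff), and
* recovery of binding residues (residues with any heavy atom near the
  ligand; all atoms of a residue are equivalent).

Contacts are defined by a plain distance cutoff, 4.5 A by default.  This
is a documented approximation to surface-complementarity contact programs
such as LPC; the cutoff is a parameter so users can calibrate it against
their reference tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .chem_io import LigandStructure, ProteinStructure

__all__ = [
    "ContactSet",
    "PoseAccuracy",
    "heavy_atom_rmsd",
    "specific_contacts",
    "binding_residues",
    "fraction_recovered",
    "evaluate_pose",
    "CONTACT_CUTOFF",
]

#: default heavy-atom contact distance, Angstrom (closed ball: d <= cutoff)
CONTACT_CUTOFF = 4.5


@dataclass(frozen=True)
class ContactSet:
    """A set of protein-ligand contacts at atom-pair or residue granularity.

    Atom-pair members are ``((chain, res_seq, atom_index), ligand_atom_index)``
    tuples; residue members are ``(chain, res_seq)`` tuples.
    """

    granularity: str  # "atom" | "residue"
    members: frozenset
    cutoff: float = CONTACT_CUTOFF

    def __post_init__(self) -> None:
        if self.granularity not in ("atom", "residue"):
            raise ValueError("granularity must be 'atom' or 'residue'")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    def residue_projection(self) -> "ContactSet":
        """Collapse atom-pair contacts to the residues involved."""
        if self.granularity == "residue":
            return self
        residues = frozenset(
            (atom_id[0], atom_id[1]) for atom_id, _ in self.members
        )
        return ContactSet("residue", residues, self.cutoff)


@dataclass(frozen=True)
class PoseAccuracy:
    """Accuracy of one predicted pose against the reference."""

    rmsd: float
    frac_binding_residues: float
    frac_specific_contacts: float

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        for frac in (self.frac_binding_residues, self.frac_specific_contacts):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("recovered fractions must lie in [0, 1]")


def _pose_coords(pose, heavy_only: bool = True) -> np.ndarray:
    """Heavy-atom coordinates from a LigandStructure or a raw array."""
    if isinstance(pose, LigandStructure):
        return pose.heavy_coords() if heavy_only else pose.coords()
    coords = np.asarray(pose, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("pose must be an (n, 3) coordinate array")
    return coords


def heavy_atom_rmsd(pose_a, pose_b) -> float:
    """RMSD over heavy atoms between two poses of the same molecule.

    The correspondence is positional (atom order); no superposition is
    applied, so the value reflects displacement in the shared receptor
    frame.  Symmetric ligands may therefore over-estimate their RMSD.
    """
    a = _pose_coords(pose_a)
    b = _pose_coords(pose_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"heavy-atom count mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    if a.shape[0] == 0:
        raise ValueError("cannot compute RMSD over zero atoms")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def specific_contacts(
    protein: ProteinStructure, ligand_pose, cutoff: float = CONTACT_CUTOFF
) -> ContactSet:
    """All protein-heavy-atom / ligand-heavy-atom pairs within ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    atom_ids, protein_coords = protein.heavy_atoms()
    ligand_coords = _pose_coords(ligand_pose)
    members: set = set()
    if protein_coords.shape[0] and ligand_coords.shape[0]:
        dists = cdist(protein_coords, ligand_coords)
        for i, j in zip(*np.nonzero(dists <= cutoff)):
            members.add((atom_ids[int(i)], int(j)))
    return ContactSet("atom", frozenset(members), cutoff)


def binding_residues(
    protein: ProteinStructure, ligand_pose, cutoff: float = CONTACT_CUTOFF
) -> ContactSet:
    """Residues with at least one heavy atom within ``cutoff`` of the ligand.

    All atoms of a residue are equivalent: a residue contributes one member
    no matter how many of its atoms touch the ligand.
    """
    atom_contacts = specific_contacts(protein, ligand_pose, cutoff)
    return atom_contacts.residue_projection()


def fraction_recovered(native: ContactSet, predicted: ContactSet) -> float:
    """Fraction of native contacts present in the predicted set.

    Both sets must share granularity and cutoff.  Undefined (an error)
    when the native set is empty.
    """
    if native.granularity != predicted.granularity:
        raise ValueError(
            f"granularity mismatch: {native.granularity} vs {predicted.granularity}"
        )
    if abs(native.cutoff - predicted.cutoff) > 1e-9:
        raise ValueError("contact sets were built with different cutoffs")
    if len(native) == 0:
        raise ValueError("fraction undefined: native contact set is empty")
    return len(native.members & predicted.members) / len(native)


def evaluate_pose(
    protein: ProteinStructure,
    native_pose,
    predicted_pose,
    cutoff: float = CONTACT_CUTOFF,
) -> PoseAccuracy:
    """RMSD plus contact/residue recovery of a predicted pose.

    ``native_pose`` defines the reference contact sets; both poses must
    present the same heavy atoms in the same order.
    """
    rmsd = heavy_atom_rmsd(native_pose, predicted_pose)
    native_atoms = specific_contacts(protein, native_pose, cutoff)
    predicted_atoms = specific_contacts(protein, predicted_pose, cutoff)
    frac_contacts = fraction_recovered(native_atoms, predicted_atoms)
    frac_residues = fraction_recovered(
        native_atoms.residue_projection(), predicted_atoms.residue_projection()
    )
    return PoseAccuracy(rmsd, frac_residues, frac_contacts)
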