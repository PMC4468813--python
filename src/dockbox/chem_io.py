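"""Structure I/O and dataset-curation filters.

Reads and writes ligands as SD (V2000) files via RDKit, proteins as PDB via
Biopython, and extracts coordinates from PDBQT docking output.  Curation
implements the benchmark filters used when assembling docking test sets:
ligands with 6-100 heavy atoms bound non-covalently, proteins of 50-600
residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from rdkit import Chem

from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "LigandStructure",
    "ProteinStructure",
    "ProteinResidue",
    "CurationReport",
    "ParseError",
    "read_ligand",
    "write_ligand",
    "read_protein",
    "read_pdbqt_coordinates",
    "curate_ligand",
    "curate_protein",
    "HEAVY_ATOM_MIN",
    "HEAVY_ATOM_MAX",
    "RESIDUE_MIN",
    "RESIDUE_MAX",
]

# Benchmark curation bounds (inclusive).
HEAVY_ATOM_MIN = 6
HEAVY_ATOM_MAX = 100
RESIDUE_MIN = 50
RESIDUE_MAX = 600

#: element symbols treated as hydrogen (never counted as heavy atoms)
HYDROGEN_SYMBOLS = frozenset({"H", "D", "T"})


class ParseError(ValueError):
    """A structure file could not be parsed."""


def _is_heavy(element: str) -> bool:
    return element.capitalize() not in HYDROGEN_SYMBOLS


@dataclass
class LigandStructure:
    """A named small molecule: atom elements plus one or more conformers.

    Parameters
    ----------
    name:
        Molecule identifier.
    elements:
        Element symbol per atom.  Atom order is shared by every conformer.
    conformers:
        Array of shape ``(n_conformers, n_atoms, 3)`` with Cartesian
        coordinates in Angstroms.  Conformer 0 is the designated
        low-energy conformer; any further conformers are rotamers.
    """

    name: str
    elements: list[str]
    conformers: np.ndarray

    def __post_init__(self) -> None:
        self.conformers = np.asarray(self.conformers, dtype=float)
        if self.conformers.ndim == 2:
            self.conformers = self.conformers[None, :, :]
        if len(self.elements) == 0:
            raise ValueError("ligand must contain at least one atom")
        if self.conformers.ndim != 3 or self.conformers.shape[2] != 3:
            raise ValueError("conformers must have shape (n_conf, n_atoms, 3)")
        if self.conformers.shape[1] != len(self.elements):
            raise ValueError(
                f"conformer atom count {self.conformers.shape[1]} does not "
                f"match element list length {len(self.elements)}"
            )
        if self.conformers.shape[0] < 1:
            raise ValueError("ligand must have at least one conformer")
        if not np.all(np.isfinite(self.conformers)):
            raise ValueError("ligand coordinates must be finite")

    # -- derived views ----------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_conformers(self) -> int:
        return int(self.conformers.shape[0])

    @property
    def heavy_mask(self) -> np.ndarray:
        """Boolean mask over atoms; True iff the element is not hydrogen."""
        return np.array([_is_heavy(el) for el in self.elements], dtype=bool)

    @property
    def n_heavy(self) -> int:
        return int(self.heavy_mask.sum())

    def coords(self, conformer: int = 0) -> np.ndarray:
        """Coordinates of one conformer, shape ``(n_atoms, 3)``."""
        return self.conformers[conformer]

    def heavy_coords(self, conformer: int = 0) -> np.ndarray:
        """Heavy-atom coordinates of one conformer."""
        return self.conformers[conformer][self.heavy_mask]

    def with_conformers(self, conformers: np.ndarray) -> "LigandStructure":
        """Copy of this ligand with a replaced conformer stack."""
        return LigandStructure(self.name, list(self.elements), conformers)


@dataclass
class ProteinResidue:
    """One residue: identity plus its atoms as (element, xyz) records."""

    chain_id: str
    res_seq: int
    name: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    het: bool = False

    @property
    def id(self) -> tuple[str, int]:
        return (self.chain_id, self.res_seq)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([_is_heavy(el) for el in self.elements], dtype=bool)


@dataclass
class ProteinStructure:
    """A protein: chains of residues, with HETATM groups kept separable."""

    name: str
    residues: list[ProteinResidue] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for res in self.residues:
            if res.id in seen:
                raise ValueError(f"duplicate residue identifier {res.id}")
            seen.add(res.id)
            if not np.all(np.isfinite(res.coords)):
                raise ValueError(f"non-finite coordinates in residue {res.id}")

    @property
    def chains(self) -> dict[str, list[ProteinResidue]]:
        out: dict[str, list[ProteinResidue]] = {}
        for res in self.residues:
            out.setdefault(res.chain_id, []).append(res)
        return out

    def polymer_residues(self) -> list[ProteinResidue]:
        """Residues from ATOM records (excludes heterogens and waters)."""
        return [r for r in self.residues if not r.het and r.name != "HOH"]

    @property
    def n_residues(self) -> int:
        return len(self.polymer_residues())

    def heavy_atoms(self) -> tuple[list[tuple[str, int, int]], np.ndarray]:
        """Flat view of polymer heavy atoms.

        Returns
        -------
        ids, coords:
            ``ids[i]`` is ``(chain_id, res_seq, atom_index_within_residue)``
            for the atom at ``coords[i]``.
        """
        ids: list[tuple[str, int, int]] = []
        coords: list[np.ndarray] = []
        for res in self.polymer_residues():
            mask = res.heavy_mask
            for j in np.nonzero(mask)[0]:
                ids.append((res.chain_id, res.res_seq, int(j)))
                coords.append(res.coords[j])
        return ids, (
            np.array(coords) if coords else np.empty((0, 3))
        )

    def extract_ligand(self, resname: str) -> LigandStructure:
        """Collect the HETATM group(s) named `resname` as a ligand."""
        elements: list[str] = []
        coords: list[np.ndarray] = []
        for res in self.residues:
            if res.het and res.name == resname:
                elements.extend(res.elements)
                coords.extend(res.coords)
        if not elements:
            raise KeyError(f"no HETATM residue named {resname!r}")
        return LigandStructure(resname, elements, np.array(coords))


@dataclass
class CurationReport:
    """Outcome of a curation filter for one record."""

    record_id: str
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.reasons


# ---------------------------------------------------------------------------
# SD format
# ---------------------------------------------------------------------------

def read_ligand(path: str | Path, merge_conformers: bool = True) -> LigandStructure:
    """Read a ligand from an SD (V2000) file.

    Multiple records with an identical atom sequence are merged as
    conformers of a single ligand (the common multi-conformer SD
    convention); the first record supplies the name.

    Raises
    ------
    ParseError
        If the file holds no molecule, a block is unreadable (the error
        names the failing molecule index), or records disagree in their
        atom sequences while ``merge_conformers`` is set.
    """
    path = Path(path)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    elements: list[str] | None = None
    name = path.stem
    conformers: list[np.ndarray] = []
    for index, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"unreadable molecule block at index {index} in {path}")
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        if mol.GetNumConformers() == 0:
            raise ParseError(f"molecule block {index} in {path} has no coordinates")
        pos = mol.GetConformer().GetPositions()
        if elements is None:
            elements = symbols
            if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
                name = mol.GetProp("_Name").strip()
        elif symbols != elements:
            raise ParseError(
                f"record {index} in {path} has a different atom sequence; "
                "multi-record SD files are merged as conformers only when "
                "atom sequences match"
            )
        conformers.append(np.asarray(pos, dtype=float))
        if not merge_conformers:
            break
    if elements is None:
        raise ParseError(f"no molecule blocks found in {path}")
    return LigandStructure(name, elements, np.stack(conformers))


def write_ligand(ligand: LigandStructure, path: str | Path) -> None:
    """Write a ligand as an SD file, one record per conformer.

    Coordinates are stored at the format's 4-decimal precision, so a
    read-back reproduces them to 1e-4 Angstrom.
    """
    if ligand.n_atoms == 0:  # pragma: no cover - blocked by the dataclass
        raise ValueError("refusing to write a ligand with no atoms")
    rw = Chem.RWMol()
    for el in ligand.elements:
        atom = Chem.Atom(el)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    mol = rw.GetMol()
    mol.SetProp("_Name", ligand.name)
    for conf_coords in ligand.conformers:
        conf = Chem.Conformer(ligand.n_atoms)
        for i, (x, y, z) in enumerate(conf_coords):
            conf.SetAtomPosition(i, (float(x), float(y), float(z)))
        mol.AddConformer(conf, assignId=True)
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for conf in mol.GetConformers():
            writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# PDB format
# ---------------------------------------------------------------------------

def _atom_element(atom) -> str:
    """Element of a Biopython atom, falling back to the atom name."""
    el = (atom.element or "").strip()
    if el:
        return el.capitalize()
    name = atom.get_name().strip()
    # PDB dialect tolerance: strip digits, take leading alpha characters.
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element for atom name {name!r}")
    if stripped[0] in "Hh":
        return "H"
    return stripped[0].upper()


def read_protein(path: str | Path, name: str | None = None) -> ProteinStructure:
    """Read a protein structure from a PDB file.

    Strict parsing: malformed coordinate columns raise a :class:`ParseError`
    rather than being silently zeroed.  HETATM groups are loaded alongside
    polymer residues and can be pulled out with
    :meth:`ProteinStructure.extract_ligand`.
    """
    path = Path(path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(name or path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"failed to parse PDB file {path}: {exc}") from exc
    residues: list[ProteinResidue] = []
    for model in structure:
        for chain in model:
            for res in chain:
                hetflag, resseq, _icode = res.get_id()
                elements = []
                coords = []
                for atom in res:
                    elements.append(_atom_element(atom))
                    coords.append(atom.get_coord())
                if not coords:
                    continue
                residues.append(
                    ProteinResidue(
                        chain_id=chain.get_id(),
                        res_seq=int(resseq),
                        name=res.get_resname().strip(),
                        elements=elements,
                        coords=np.array(coords, dtype=float),
                        het=hetflag.strip() != "",
                    )
                )
        break  # first model only
    if not residues:
        raise ParseError(f"no ATOM/HETATM records found in {path}")
    return ProteinStructure(name or path.stem, residues)


# ---------------------------------------------------------------------------
# PDBQT coordinate extraction
# ---------------------------------------------------------------------------

#: AutoDock atom types that denote hydrogen
_PDBQT_HYDROGEN_TYPES = frozenset({"H", "HD", "HS"})
#: AutoDock atom types whose element is not the leading character
_PDBQT_TYPE_TO_ELEMENT = {
    "A": "C",   # aromatic carbon
    "OA": "O",
    "NA": "N",
    "SA": "S",
    "CL": "Cl",
    "BR": "Br",
    "FE": "Fe",
    "ZN": "Zn",
    "MG": "Mg",
    "MN": "Mn",
    "CA": "Ca",
}


def read_pdbqt_coordinates(path: str | Path, name: str | None = None) -> LigandStructure:
    """Extract heavy-atom coordinates from a PDBQT file.

    Only ATOM/HETATM lines are interpreted; ROOT/BRANCH/TORSDOF and other
    docking bookkeeping records are ignored.  Partial charges and AutoDock
    atom types are never used beyond hydrogen identification.  Multiple
    MODEL blocks are read as conformers.
    """
    path = Path(path)
    models: list[tuple[list[str], list[list[float]]]] = [([], [])]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if models[-1][0]:
                    models.append(([], []))
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(
                    f"malformed coordinates on line {lineno} of {path}"
                ) from exc
            # the AutoDock atom type is the final field of the line
            atype = line.split()[-1].upper()
            if atype in _PDBQT_HYDROGEN_TYPES:
                continue
            element = _PDBQT_TYPE_TO_ELEMENT.get(
                atype, atype[:1].capitalize() if atype else "C"
            )
            models[-1][0].append(element)
            models[-1][1].append([x, y, z])
    models = [m for m in models if m[0]]
    if not models:
        raise ParseError(f"no coordinate lines found in {path}")
    elements = models[0][0]
    for elems, _ in models[1:]:
        if elems != elements:
            raise ParseError(f"MODEL blocks in {path} differ in atom sequence")
    conformers = np.array([coords for _, coords in models], dtype=float)
    return LigandStructure(name or path.stem, elements, conformers)


# ---------------------------------------------------------------------------
# Curation filters
# ---------------------------------------------------------------------------

def curate_ligand(ligand: LigandStructure, covalent: bool = False) -> CurationReport:
    """Apply the benchmark ligand filter: 6-100 heavy atoms, non-covalent.

    Bounds are inclusive.  Covalent attachment is an input flag taken from
    database annotation, not inferred from geometry.
    """
    reasons: list[str] = []
    n = ligand.n_heavy
    if n < HEAVY_ATOM_MIN:
        reasons.append("heavy_atom_min")
    if n > HEAVY_ATOM_MAX:
        reasons.append("heavy_atom_max")
    if covalent:
        reasons.append("covalent")
    return CurationReport(ligand.name, reasons)


def curate_protein(protein: ProteinStructure) -> CurationReport:
    """Apply the benchmark protein filter: 50-600 polymer residues, inclusive."""
    reasons: list[str] = []
    n = protein.n_residues
    if n < RESIDUE_MIN:
        reasons.append("residue_min")
    if n > RESIDUE_MAX:
        reasons.append("residue_max")
    return CurationReport(protein.name, reasons)
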