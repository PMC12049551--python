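"""Reading, pre-processing and writing of protein structures.

Structures are parsed with :mod:`gemmi` (PDB and mmCIF) into light-weight
domain objects.  Only the first model is kept; alternate locations are
resolved to the highest-occupancy conformer; author residue numbering
(with insertion codes) is the public key throughout the package — no
renumbering ever happens.  Scores are written back to PDB files through
the B-factor column so they can be color-mapped in any molecular viewer.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

logger = logging.getLogger("fluorosite")

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: Van der Waals radii (Å) from a fixed internal table (Bondi-type values),
#: so results do not depend on the version of any external library.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Fallback radius for metals / exotic elements retained after pre-processing.
DEFAULT_VDW_RADIUS = 1.80

STANDARD_AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Common non-standard residues mapped to their parent amino acid.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",  # selenocysteine (parent for geometry purposes)
    "CSO": "CYS", "CME": "CYS", "OCS": "CYS", "CSS": "CYS",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR",
    "MLY": "LYS", "KCX": "LYS", "LLP": "LYS",
    "HYP": "PRO", "PCA": "GLU", "FME": "MET", "MLE": "LEU",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

ResidueId = tuple[str, int, str]  # (chain id, author residue number, insertion code)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_id: ResidueId
    coordinates: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    is_hetero: bool = False
    vdw_radius: float = DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class ResidueRecord:
    residue_id: ResidueId
    amino_acid: str                 # 3-letter code (parent code for mapped residues)
    atoms: list[AtomRecord] = field(default_factory=list)
    original_name: str | None = None  # set when a non-standard residue was mapped
    is_standard: bool = True

    @property
    def has_cbeta(self) -> bool:
        return any(a.name == "CB" for a in self.atoms)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms])


@dataclass
class StructureModel:
    pdb_id: str
    residues: list[ResidueRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for r in self.residues:
            if r.residue_id[0] not in seen:
                seen.append(r.residue_id[0])
        return seen

    def residue(self, residue_id: ResidueId) -> ResidueRecord | None:
        for r in self.residues:
            if r.residue_id == residue_id:
                return r
        return None

    def standard_residues(self) -> list[ResidueRecord]:
        return [r for r in self.residues if r.is_standard]

    def atoms(self) -> Iterable[AtomRecord]:
        for r in self.residues:
            yield from r.atoms

    def atom_coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms()])


class StructureError(ValueError):
    """Raised for unreadable or empty structures."""


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    return el if el else "C"


def read_structure(path: str | Path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is used (NMR ensembles: later models are ignored
    with a log line).  Alternate locations are resolved to the
    highest-occupancy conformer.  HETATM records are flagged, not dropped;
    call :func:`preprocess_structure` to clean the model.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = format
    if fmt is None:
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    if len(st) > 1:
        logger.info("%s: %d models present, using the first", path.name, len(st))
    st.setup_entities()
    model = st[0]

    residues: list[ResidueRecord] = []
    serial = 0
    for chain in model:
        for res in chain:
            rid: ResidueId = (chain.name, res.seqid.num, (res.seqid.icode or " ").strip())
            name = res.name.strip().upper()
            het = res.het_flag == "H"
            if name in STANDARD_AMINO_ACIDS:
                aa, orig, std = name, None, True
            elif name in NONSTANDARD_PARENT:
                aa, orig, std = NONSTANDARD_PARENT[name], name, True
            else:
                aa, orig, std = name, None, False
            rec = ResidueRecord(residue_id=rid, amino_acid=aa,
                                original_name=orig, is_standard=std and not het)
            # resolve altlocs: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom_name in best:
                atom = best[atom_name]
                serial += 1
                el = _element_of(atom)
                rec.atoms.append(AtomRecord(
                    serial=serial, name=atom.name, element=el, residue_id=rid,
                    coordinates=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ, is_hetero=het,
                    vdw_radius=VDW_RADII.get(el, DEFAULT_VDW_RADIUS)))
            residues.append(rec)

    if not any(r.is_standard for r in residues):
        raise StructureError(f"{path}: no protein residues found")
    pdb_id = (st.name or path.stem).strip() or path.stem
    return StructureModel(pdb_id=pdb_id, residues=residues,
                          provenance={"source": str(path), "format": fmt, "log": []})


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def preprocess_structure(model: StructureModel,
                         keep_chains: Sequence[str] | None = None,
                         drop_hetero: bool = True) -> StructureModel:
    """Clean a parsed structure for scoring.

    Waters are always removed.  ``keep_chains`` restricts the model to the
    given chains (a homodimer that is a crystallization artefact is reduced
    to one chain this way).  Gaps in the author numbering are recorded in
    the provenance log, never interpolated.
    """
    if keep_chains is not None:
        missing = set(keep_chains) - set(model.chains)
        if missing:
            raise StructureError(f"keep_chains selects absent chains: {sorted(missing)}")

    log: list[str] = list(model.provenance.get("log", []))
    kept: list[ResidueRecord] = []
    for res in model.residues:
        chain = res.residue_id[0]
        name = res.original_name or res.amino_acid
        if name in WATER_NAMES:
            continue
        if keep_chains is not None and chain not in keep_chains:
            continue
        if drop_hetero and not res.is_standard:
            log.append(f"dropped hetero/non-standard residue {name} {res.residue_id}")
            continue
        kept.append(res)
    if not kept:
        raise StructureError("pre-processing removed every residue")

    # record numbering gaps per chain
    gaps: dict[str, list[int]] = {}
    by_chain: dict[str, list[int]] = {}
    for res in kept:
        by_chain.setdefault(res.residue_id[0], []).append(res.residue_id[1])
    for chain, nums in by_chain.items():
        missing_nums = [n for lo, hi in zip(nums, nums[1:]) if hi - lo > 1
                        for n in range(lo + 1, hi)]
        if missing_nums:
            gaps[chain] = missing_nums
            log.append(f"chain {chain}: missing residues {missing_nums}")

    prov = dict(model.provenance)
    prov.update({"log": log, "missing_residues": gaps,
                 "kept_chains": keep_chains if keep_chains is None else list(keep_chains)})
    return StructureModel(pdb_id=model.pdb_id, residues=kept, provenance=prov)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _pdb_atom_line(atom: AtomRecord, res: ResidueRecord, bfactor: float) -> str:
    name = atom.name
    # PDB atom-name column convention: element right-aligned in cols 13-14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    chain, num, icode = res.residue_id
    resname = res.original_name or res.amino_acid
    record = "HETATM" if atom.is_hetero else "ATOM  "
    x, y, z = atom.coordinates
    return (f"{record}{atom.serial % 100000:5d} {name:<4s} {resname:>3s} "
            f"{chain[:1]:1s}{num:4d}{icode or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{bfactor:6.2f}"
            f"          {atom.element:>2s}")


def write_pdb(model: StructureModel, path: str | Path,
              bfactors: Mapping[ResidueId, float] | None = None) -> None:
    """Write the model as a PDB file, optionally with per-residue B-factors."""
    lines = []
    last_chain = None
    for res in model.residues:
        b = 0.0 if bfactors is None else float(bfactors.get(res.residue_id, 0.0))
        if last_chain is not None and res.residue_id[0] != last_chain:
            lines.append("TER")
        last_chain = res.residue_id[0]
        for atom in res.atoms:
            lines.append(_pdb_atom_line(atom, res, b))
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_score_pdb(model: StructureModel,
                    per_residue_scores: Mapping[ResidueId, float],
                    path: str | Path) -> None:
    """Write a PDB with each atom's B-factor set to its residue score.

    Missing scores are written as 0.00 and logged; the fixed-width B-factor
    field limits magnitudes to 999.99.
    """
    for rid, s in per_residue_scores.items():
        if not math.isfinite(s):
            raise ValueError(f"non-finite score for {rid}")
        if abs(s) > 999.99:
            raise ValueError(f"score magnitude {s} for {rid} exceeds PDB B-factor field")
    missing = [r.residue_id for r in model.residues
               if r.residue_id not in per_residue_scores]
    if missing:
        logger.warning("write_score_pdb: %d residues without score set to 0.00: %s",
                       len(missing), missing[:5])
    write_pdb(model, path, bfactors=per_residue_scores)


def read_score_pdb(path: str | Path) -> dict[ResidueId, float]:
    """Recover per-residue scores from the B-factor column of a PDB file."""
    scores: dict[ResidueId, float] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith(("ATOM  ", "HETATM")):
            rid: ResidueId = (line[21], int(line[22:26]), line[26].strip())
            scores[rid] = float(line[60:66])
    return scores


def write_provenance(model: StructureModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.provenance, indent=2) + "\n")
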