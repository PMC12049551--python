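"""Per-residue parameter registry: the 28 features in four categories.

Categories: CS (conservation), SE (solvent exposure), SS (secondary
structure) and CR (cysteine resemblance).  Numeric geometry features
(solvent accessible surface area, half-sphere exposure, surface
distances, backbone dihedrals) are computed directly from the structure
with deterministic golden-spiral dot spheres; conservation features come
from a ConSurf grades file or from a user-supplied multiple sequence
alignment; secondary structure is assigned internally with the
Kabsch-Sander hydrogen-bond algorithm or read from an external DSSP
file.  Missing values are data, not errors: any parameter that cannot be
computed for a residue is set to the missing sentinel (NaN / None).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import dihedral, ideal_cbeta
from .structure_io import (STANDARD_AMINO_ACIDS, THREE_TO_ONE, VDW_RADII,
                           ResidueId, ResidueRecord, StructureModel)

logger = logging.getLogger("fluorosite")

# ---------------------------------------------------------------------------
# Fixed amino-acid property tables (documented constants)
# ---------------------------------------------------------------------------

#: Theoretical maximum accessible surface areas (Å², Tien/Wilke 2013),
#: used to normalize absolute ASA to relative ASA.
WILKE_MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Average residue masses (Da, monomer in chain).
RESIDUE_MASS: dict[str, float] = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09, "CYS": 103.14,
    "GLN": 128.13, "GLU": 129.12, "GLY": 57.05, "HIS": 137.14, "ILE": 113.16,
    "LEU": 113.16, "LYS": 128.17, "MET": 131.19, "PHE": 147.18, "PRO": 97.12,
    "SER": 87.08, "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}

#: Residue volumes (Å³, Zamyatnin).
RESIDUE_VOLUME: dict[str, float] = {
    "ALA": 88.6, "ARG": 173.4, "ASN": 114.1, "ASP": 111.1, "CYS": 108.5,
    "GLN": 143.8, "GLU": 138.4, "GLY": 60.1, "HIS": 153.2, "ILE": 166.7,
    "LEU": 166.7, "LYS": 168.6, "MET": 162.9, "PHE": 189.9, "PRO": 112.7,
    "SER": 89.0, "THR": 116.1, "TRP": 227.8, "TYR": 193.6, "VAL": 140.0,
}

CHARGE_CLASS: dict[str, str] = {
    **{aa: "neutral" for aa in STANDARD_AMINO_ACIDS},
    "ARG": "positive", "LYS": "positive", "HIS": "positive",
    "ASP": "negative", "GLU": "negative",
}

PROBE_RADIUS = 1.4       # Å, water probe
DEFAULT_N_POINTS = 960   # golden-spiral dots per atom sphere


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent accessible surface area
# ---------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _shrake_rupley(model: StructureModel, probe_radius: float,
                   n_points: int) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-atom ASA plus the solvent-exposed dot cloud.

    Returns (asa_per_atom, exposed_dots (M,3), atoms list).
    """
    atoms = list(model.atoms())
    if not atoms:
        raise ValueError("structure has no atoms")
    coords = np.array([a.coordinates for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    sphere = _golden_spiral(n_points)
    tree = cKDTree(coords)
    asa = np.zeros(len(atoms))
    exposed: list[np.ndarray] = []
    rmax = radii.max()
    for i in range(len(atoms)):
        dots = coords[i] + radii[i] * sphere
        nb = tree.query_ball_point(coords[i], radii[i] + rmax)
        nb = [j for j in nb if j != i]
        free = np.ones(n_points, dtype=bool)
        for j in nb:
            d2 = np.einsum("ij,ij->i", dots - coords[j], dots - coords[j])
            free &= d2 > radii[j] ** 2
        n_free = int(free.sum())
        asa[i] = 4.0 * np.pi * radii[i] ** 2 * n_free / n_points
        if n_free:
            exposed.append(dots[free])
    dots_all = np.vstack(exposed) if exposed else np.empty((0, 3))
    return asa, dots_all, atoms


def compute_sasa(model: StructureModel, probe_radius: float = PROBE_RADIUS,
                 n_points: int = DEFAULT_N_POINTS
                 ) -> dict[ResidueId, tuple[float, float]]:
    """Per-residue (absolute ASA Å², relative ASA) by Shrake-Rupley.

    Relative ASA divides by the Wilke maximum-ASA constant of the amino
    acid, clipped to [0, 1.2]; residues without a Wilke constant
    (non-standard) get NaN relative ASA.
    """
    asa, _, atoms = _shrake_rupley(model, probe_radius, n_points)
    per_res: dict[ResidueId, float] = {}
    for a, v in zip(atoms, asa):
        per_res[a.residue_id] = per_res.get(a.residue_id, 0.0) + v
    out: dict[ResidueId, tuple[float, float]] = {}
    for res in model.residues:
        abs_asa = per_res.get(res.residue_id, 0.0)
        max_asa = WILKE_MAX_ASA.get(res.amino_acid)
        rel = min(abs_asa / max_asa, 1.2) if max_asa else float("nan")
        out[res.residue_id] = (abs_asa, rel)
    return out


def sidechain_sasa(model: StructureModel, probe_radius: float = PROBE_RADIUS,
                   n_points: int = DEFAULT_N_POINTS) -> dict[ResidueId, float]:
    """Side-chain (non-backbone-atom) ASA per residue (Å²)."""
    backbone = {"N", "CA", "C", "O", "OXT"}
    asa, _, atoms = _shrake_rupley(model, probe_radius, n_points)
    out: dict[ResidueId, float] = {r.residue_id: 0.0 for r in model.residues}
    for a, v in zip(atoms, asa):
        if a.name not in backbone:
            out[a.residue_id] = out.get(a.residue_id, 0.0) + v
    return out


# ---------------------------------------------------------------------------
# Half-sphere exposure and neighbor counts
# ---------------------------------------------------------------------------

def _cbeta_position(res: ResidueRecord) -> np.ndarray | None:
    cb = res.atom("CB")
    if cb is not None:
        return cb.coordinates
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    if n is None or ca is None or c is None:
        return None
    return ideal_cbeta(n.coordinates, ca.coordinates, c.coordinates)


def compute_half_sphere_exposure(model: StructureModel, radius: float = 10.0
                                 ) -> dict[ResidueId, tuple[int, int]]:
    """(HSE-up, HSE-down): neighbor Cα counts in the half-spheres above and
    below the plane normal to the Cα→Cβ vector (virtual Cβ for glycine)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    std = [r for r in model.standard_residues() if r.atom("CA") is not None]
    if len(std) < 2:
        logger.warning("half-sphere exposure on <2 residues: all counts zero")
    ca = np.array([r.atom("CA").coordinates for r in std]) if std else np.empty((0, 3))
    out: dict[ResidueId, tuple[int, int]] = {}
    for i, res in enumerate(std):
        cb = _cbeta_position(res)
        if cb is None:
            out[res.residue_id] = (0, 0)
            continue
        u = cb - ca[i]
        norm = np.linalg.norm(u)
        u = u / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        d = ca - ca[i]
        dist = np.linalg.norm(d, axis=1)
        mask = (dist <= radius) & (dist > 0)
        above = int(np.sum(d[mask] @ u > 0))
        out[res.residue_id] = (above, int(mask.sum()) - above)
    return out


def coordination_number(model: StructureModel, radius: float = 10.0
                        ) -> dict[ResidueId, int]:
    hse = compute_half_sphere_exposure(model, radius)
    return {rid: up + down for rid, (up, down) in hse.items()}


# ---------------------------------------------------------------------------
# Surface distances
# ---------------------------------------------------------------------------

def compute_mean_surface_distance(model: StructureModel,
                                  probe_radius: float = PROBE_RADIUS,
                                  n_points: int = DEFAULT_N_POINTS
                                  ) -> dict[ResidueId, float]:
    """Mean burial depth of each residue's atoms below the solvent-exposed
    dot surface.  Per atom the depth is the distance to the nearest
    surface dot minus the atom's own solvent-sphere radius (vdW + probe),
    clipped at zero, so surface residues score near zero and buried
    residues score high."""
    _, dots, _ = _shrake_rupley(model, probe_radius, n_points)
    if len(dots) == 0:
        raise ValueError("no solvent-exposed surface dots (degenerate input)")
    tree = cKDTree(dots)
    out: dict[ResidueId, float] = {}
    for res in model.residues:
        if not res.atoms:
            out[res.residue_id] = float("nan")
            continue
        depths = [max(0.0, float(tree.query(a.coordinates)[0])
                      - (a.vdw_radius + probe_radius)) for a in res.atoms]
        out[res.residue_id] = float(np.mean(depths))
    return out


def atom_surface_distance(model: StructureModel, atom_name: str,
                          probe_radius: float = PROBE_RADIUS,
                          n_points: int = DEFAULT_N_POINTS
                          ) -> dict[ResidueId, float]:
    """Burial depth of a named atom (CA, or CB with glycine virtual Cβ)
    below the exposed dot surface (distance to the nearest dot minus the
    atom solvent-sphere radius, clipped at zero)."""
    _, dots, _ = _shrake_rupley(model, probe_radius, n_points)
    if len(dots) == 0:
        raise ValueError("no solvent-exposed surface dots (degenerate input)")
    tree = cKDTree(dots)
    offset = VDW_RADII["C"] + probe_radius
    out: dict[ResidueId, float] = {}
    for res in model.residues:
        if atom_name == "CB":
            pos = _cbeta_position(res)
        else:
            a = res.atom(atom_name)
            pos = None if a is None else a.coordinates
        if pos is None:
            out[res.residue_id] = float("nan")
        else:
            d, _ = tree.query(pos)
            out[res.residue_id] = max(0.0, float(d) - offset)
    return out


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander)
# ---------------------------------------------------------------------------

HB_CUTOFF = -0.5  # kcal/mol


def _chain_backbones(model: StructureModel) -> list[list[ResidueRecord]]:
    chains: dict[str, list[ResidueRecord]] = {}
    for res in model.standard_residues():
        chains.setdefault(res.residue_id[0], []).append(res)
    return list(chains.values())


def _hbond_energy(n: np.ndarray, h: np.ndarray | None,
                  c: np.ndarray, o: np.ndarray) -> float:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol) for donor
    N-H and acceptor C=O."""
    if h is None:
        return 0.0
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)


def assign_secondary_structure(model: StructureModel) -> dict[ResidueId, str]:
    """DSSP-style 8-state assignment driven by Kabsch-Sander hydrogen
    bonds (cutoff −0.5 kcal/mol): H/G/I helices, E/B strands and bridges,
    T turns, S bends, '-' coil; '?' for residues with missing backbone."""
    result: dict[ResidueId, str] = {}
    # flatten all chains; keep chain boundaries (no H-bonds across index
    # adjacency checks, but spatial bonds between chains are allowed)
    seqs: list[tuple[ResidueRecord, dict[str, np.ndarray] | None]] = []
    chain_of: list[int] = []
    for ci, chain in enumerate(_chain_backbones(model)):
        for res in chain:
            bb = {}
            for name in ("N", "CA", "C", "O"):
                a = res.atom(name)
                if a is None:
                    bb = None
                    break
                bb[name] = a.coordinates
            seqs.append((res, bb))
            chain_of.append(ci)
    n_res = len(seqs)
    for res, bb in seqs:
        result[res.residue_id] = "?" if bb is None else "-"

    # amide H: along the previous residue's C=O direction, 1.01 Å from N
    h_pos: list[np.ndarray | None] = []
    for i, (res, bb) in enumerate(seqs):
        if bb is None or res.amino_acid == "PRO":
            h_pos.append(None)
            continue
        if i == 0 or chain_of[i - 1] != chain_of[i] or seqs[i - 1][1] is None \
                or seqs[i - 1][0].residue_id[1] + 1 != res.residue_id[1]:
            h_pos.append(None)
            continue
        prev = seqs[i - 1][1]
        d = prev["C"] - prev["O"]
        h_pos.append(bb["N"] + 1.01 * d / np.linalg.norm(d))

    # hbond[i][j]: donor N-H of i, acceptor C=O of j
    valid = [i for i, (_, bb) in enumerate(seqs) if bb is not None]
    ca = {i: seqs[i][1]["CA"] for i in valid}
    tree = cKDTree(np.array([ca[i] for i in valid])) if valid else None
    idx_map = {k: i for k, i in enumerate(valid)}
    hbond: set[tuple[int, int]] = set()
    for i in valid:
        if h_pos[i] is None:
            continue
        for k in tree.query_ball_point(ca[i], 9.0):
            j = idx_map[k]
            if j == i or (chain_of[i] == chain_of[j] and abs(i - j) == 1):
                continue
            e = _hbond_energy(seqs[i][1]["N"], h_pos[i],
                              seqs[j][1]["C"], seqs[j][1]["O"])
            if e < HB_CUTOFF:
                hbond.add((i, j))

    def hb(a: int, b: int) -> bool:
        return (a, b) in hbond

    def same_chain(a: int, b: int) -> bool:
        return 0 <= a < n_res and 0 <= b < n_res and chain_of[a] == chain_of[b]

    # n-turns
    turn: dict[int, set[int]] = {3: set(), 4: set(), 5: set()}
    for nlen in (3, 4, 5):
        for i in range(n_res - nlen):
            if same_chain(i, i + nlen) and hb(i + nlen, i):
                turn[nlen].add(i)

    ss = [result[seqs[i][0].residue_id] for i in range(n_res)]

    def set_run(start: int, length: int, code: str, only_dash: bool = True) -> None:
        for k in range(start, start + length):
            if 0 <= k < n_res and (not only_dash or ss[k] == "-"):
                ss[k] = code

    # bridges / strands
    bridge = np.zeros(n_res, dtype=int)  # 0 none, 1 isolated, 2 extended
    partners: dict[int, list[int]] = {}
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            para = (hb(j, i - 1) and hb(i + 1, j)) or (hb(i, j - 1) and hb(j + 1, i))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if para or anti:
                partners.setdefault(i, []).append(j)
                partners.setdefault(j, []).append(i)
    for i, js in partners.items():
        # extended strand if a neighboring residue also forms a bridge
        ext = any(abs(k - i) == 1 for k in partners if k != i)
        bridge[i] = 2 if ext else 1

    # helices first (DSSP priority: H, then strands, then G, I, T, S)
    is_h = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res):
        if i - 1 in turn[4] and i in turn[4]:
            for k in range(i + 1, min(i + 5, n_res)):
                is_h[k] = True
    for i in range(n_res):
        if is_h[i]:
            ss[i] = "H"
    for i in range(n_res):
        if ss[i] == "-" and bridge[i] == 2:
            ss[i] = "E"
        elif ss[i] == "-" and bridge[i] == 1:
            ss[i] = "B"
    for nlen, code in ((3, "G"), (5, "I")):
        for i in range(1, n_res):
            if i - 1 in turn[nlen] and i in turn[nlen]:
                set_run(i + 1, nlen - 1, code)
    for nlen in (3, 4, 5):
        for i in turn[nlen]:
            set_run(i + 1, nlen - 1, "T")
    # bends
    for i in range(2, n_res - 2):
        if ss[i] != "-":
            continue
        if seqs[i - 2][1] is None or seqs[i][1] is None or seqs[i + 2][1] is None:
            continue
        if not (same_chain(i - 2, i) and same_chain(i, i + 2)):
            continue
        v1 = seqs[i][1]["CA"] - seqs[i - 2][1]["CA"]
        v2 = seqs[i + 2][1]["CA"] - seqs[i][1]["CA"]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70:
            ss[i] = "S"

    for i in range(n_res):
        if seqs[i][1] is not None:
            result[seqs[i][0].residue_id] = ss[i]
    return result


SS_3STATE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E",
             "T": "C", "S": "C", "-": "C", "?": "?"}


def to_three_state(ss: Mapping[ResidueId, str]) -> dict[ResidueId, str]:
    return {rid: SS_3STATE.get(code, "C") for rid, code in ss.items()}


def backbone_dihedrals(model: StructureModel
                       ) -> dict[ResidueId, tuple[float, float]]:
    """(φ, ψ) in degrees per residue; NaN at chain termini / missing atoms."""
    out: dict[ResidueId, tuple[float, float]] = {}
    for chain in _chain_backbones(model):
        for i, res in enumerate(chain):
            phi = psi = float("nan")
            n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
            if None not in (n, ca, c):
                if i > 0 and chain[i - 1].residue_id[1] + 1 == res.residue_id[1]:
                    cp = chain[i - 1].atom("C")
                    if cp is not None:
                        phi = dihedral(cp.coordinates, n.coordinates,
                                       ca.coordinates, c.coordinates)
                if i + 1 < len(chain) and chain[i + 1].residue_id[1] - 1 == res.residue_id[1]:
                    nn = chain[i + 1].atom("N")
                    if nn is not None:
                        psi = dihedral(n.coordinates, ca.coordinates,
                                       c.coordinates, nn.coordinates)
            out[res.residue_id] = (phi, psi)
    return out


# ---------------------------------------------------------------------------
# External annotation files
# ---------------------------------------------------------------------------

def parse_dssp_file(path: str | Path) -> dict[ResidueId, str]:
    """Parse a classic-format DSSP output file into residue → SS class."""
    lines = Path(path).read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.lstrip().startswith("#  RESIDUE"):
            start = i + 1
            break
    if start is None:
        raise ValueError(f"{path}: no DSSP data header ('#  RESIDUE' line) found")
    out: dict[ResidueId, str] = {}
    for line in lines[start:]:
        if len(line) < 17:
            continue
        if line[13] == "!":  # chain break
            continue
        try:
            num = int(line[5:10])
        except ValueError:
            logger.warning("unparsed DSSP line: %r", line[:20])
            continue
        chain = line[11].strip()
        icode = line[10].strip()
        code = line[16]
        out[(chain, num, icode)] = code if code != " " else "-"
    return out


def parse_consurf_grades(path: str | Path,
                         model: StructureModel | None = None
                         ) -> dict[ResidueId, tuple[float, int]]:
    """Parse a ConSurf grades table into residue → (score, grade 1-9).

    Negative normalized scores denote conserved residues (ConSurf sign
    convention).  When a model is given, more than 20% unmatched residues
    is an error.
    """
    out: dict[ResidueId, tuple[float, int]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if len(parts) < 5 or not parts[0].lstrip("-").isdigit():
            continue
        atom_field = None
        for tok in parts[1:4]:
            if ":" in tok and tok.split(":")[0][:3].isalpha():
                atom_field = tok
                break
        if atom_field is None:
            continue
        respart, chain = atom_field.split(":")[:2]
        try:
            resnum = int("".join(ch for ch in respart if ch.isdigit() or ch == "-"))
        except ValueError:
            continue
        try:
            fi = parts.index(atom_field)
            score = float(parts[fi + 1])
            grade = int(parts[fi + 2].rstrip("*"))
        except (ValueError, IndexError):
            continue
        out[(chain, resnum, "")] = (score, grade)
    if model is not None:
        std = model.standard_residues()
        matched = sum(1 for r in std
                      if (r.residue_id[0], r.residue_id[1], "") in out)
        if std and matched < 0.8 * len(std):
            raise ValueError(
                f"ConSurf grades match only {matched}/{len(std)} residues (>20% unmatched)")
    return out


def read_msa(path: str | Path) -> list[tuple[str, str]]:
    """Aligned FASTA → list of (id, aligned sequence)."""
    from Bio import AlignIO
    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq).upper()) for rec in aln]


def _map_msa_columns(model: StructureModel, chain: str,
                     ref_seq: str) -> dict[int, ResidueId]:
    """Map ungapped positions of the reference MSA row onto the chain's
    standard residues, in order."""
    residues = [r for r in model.standard_residues() if r.residue_id[0] == chain]
    ungapped = [i for i, c in enumerate(ref_seq) if c not in "-."]
    if len(ungapped) != len(residues):
        raise ValueError(
            f"MSA reference row has {len(ungapped)} residues but chain {chain} "
            f"has {len(residues)}: ungapped mapping fails")
    for col, res in zip(ungapped, residues):
        if THREE_TO_ONE.get(res.amino_acid, "X") != ref_seq[col]:
            raise ValueError(
                f"MSA mismatch at column {col}: {ref_seq[col]} vs "
                f"{res.amino_acid} {res.residue_id}")
    return dict(zip(ungapped, (r.residue_id for r in residues)))


def msa_column_stats(msa: Sequence[tuple[str, str]]
                     ) -> list[tuple[float, int, bool]]:
    """Per column: (Shannon entropy over amino acids, number of distinct
    amino-acid variants, cysteine present in any homolog)."""
    length = len(msa[0][1])
    stats = []
    for col in range(length):
        column = [seq[col] for _, seq in msa if seq[col] not in "-.X"]
        if not column:
            stats.append((float("nan"), 0, False))
            continue
        vals, counts = np.unique(column, return_counts=True)
        p = counts / counts.sum()
        h = float(-(p * np.log(p)).sum())
        stats.append((h, len(vals), "C" in vals))
    return stats


def compute_msa_conservation(model: StructureModel, msa: Sequence[tuple[str, str]],
                             chain: str, ref_row: int = 0
                             ) -> dict[ResidueId, float]:
    """Entropy-based conservation, rescaled to mean 0 / SD 1 over columns
    and signed so that conserved columns are negative (ConSurf
    convention).  Offline fallback when no ConSurf file is available."""
    colmap = _map_msa_columns(model, chain, msa[ref_row][1])
    stats = msa_column_stats(msa)
    cols = sorted(colmap)
    h = np.array([stats[c][0] for c in cols])
    sd = np.nanstd(h)
    z = (h - np.nanmean(h)) / (sd if sd > 0 else 1.0)
    return {colmap[c]: float(z[i]) for i, c in enumerate(cols)}


# ---------------------------------------------------------------------------
# Cysteine resemblance
# ---------------------------------------------------------------------------

def compute_cysteine_resemblance(residue: ResidueRecord) -> dict | None:
    """Similarity of the native amino acid to cysteine: identity, mass and
    volume deltas, charge class.  None for non-standard residues."""
    aa = residue.amino_acid
    if aa not in STANDARD_AMINO_ACIDS:
        return None
    return {
        "identity": aa,
        "mass_delta": RESIDUE_MASS[aa] - RESIDUE_MASS["CYS"],
        "volume_delta": RESIDUE_VOLUME[aa] - RESIDUE_VOLUME["CYS"],
        "charge_class": CHARGE_CLASS[aa],
    }


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterDefinition:
    id: int
    name: str
    category: str                     # CS / SE / SS / CR
    datatype: str                     # numeric / categorical
    doc: str = ""
    #: numeric: (low, high, n_bins); categorical: tuple of labels
    binning: tuple = ()
    #: True when the exact published definition was unavailable and the
    #: implementation follows the parameter's name (recorded in provenance)
    interpretation: bool = False

    @property
    def column(self) -> str:
        return f"p{self.id:02d}_{self.name}"


_SS8 = ("H", "G", "I", "E", "B", "T", "S", "-")
_AA20 = STANDARD_AMINO_ACIDS

REGISTRY: tuple[ParameterDefinition, ...] = (
    # --- SE: solvent exposure -------------------------------------------
    ParameterDefinition(1, "rel_surface_area_wilke", "SE", "numeric",
                        "relative ASA, Wilke max-ASA normalization", (0.0, 1.2, 12)),
    ParameterDefinition(2, "abs_surface_area", "SE", "numeric",
                        "absolute residue ASA (Å²)", (0.0, 250.0, 10), True),
    ParameterDefinition(3, "sidechain_surface_area", "SE", "numeric",
                        "side-chain ASA (Å²)", (0.0, 200.0, 10), True),
    ParameterDefinition(4, "hse_up_10", "SE", "numeric",
                        "first half-sphere exposure, 10 Å", (0, 30, 15)),
    ParameterDefinition(5, "hse_down_10", "SE", "numeric",
                        "second half-sphere exposure, 10 Å", (0, 30, 15), True),
    ParameterDefinition(6, "hse_ratio_10", "SE", "numeric",
                        "HSE-up fraction of all 10 Å neighbors", (0.0, 1.0, 10), True),
    ParameterDefinition(7, "coordination_number_10", "SE", "numeric",
                        "Cα neighbors within 10 Å", (0, 40, 20), True),
    ParameterDefinition(8, "hse_up_13", "SE", "numeric",
                        "first half-sphere exposure, 13 Å", (0, 50, 25), True),
    ParameterDefinition(9, "hse_down_13", "SE", "numeric",
                        "second half-sphere exposure, 13 Å", (0, 50, 25), True),
    ParameterDefinition(10, "calpha_surface_distance", "SE", "numeric",
                        "Cα distance to molecular surface (Å)", (0.0, 10.0, 10), True),
    ParameterDefinition(11, "mean_surface_distance", "SE", "numeric",
                        "mean atom distance to molecular surface (Å)", (0.0, 10.0, 10)),
    ParameterDefinition(12, "cbeta_surface_distance", "SE", "numeric",
                        "Cβ distance to molecular surface (Å)", (0.0, 10.0, 10), True),
    # --- CS: conservation ------------------------------------------------
    ParameterDefinition(13, "consurf_score", "CS", "numeric",
                        "ConSurf normalized score (negative = conserved)",
                        (-2.0, 2.0, 8)),
    ParameterDefinition(14, "consurf_grade", "CS", "categorical",
                        "ConSurf grade", tuple(str(g) for g in range(1, 10)), True),
    ParameterDefinition(15, "msa_conservation", "CS", "numeric",
                        "entropy-based MSA conservation (negative = conserved)",
                        (-3.0, 3.0, 8), True),
    ParameterDefinition(16, "variant_length_homologs", "CS", "numeric",
                        "number of distinct amino-acid variants in homologs",
                        (0, 20, 10), True),
    ParameterDefinition(17, "cysteine_in_homologs", "CS", "categorical",
                        "cysteine found at this position in homologs",
                        ("yes", "no")),
    # --- SS: secondary structure -----------------------------------------
    ParameterDefinition(18, "secondary_structure_dssp", "SS", "categorical",
                        "DSSP 8-state class", _SS8),
    ParameterDefinition(19, "secondary_structure_3state", "SS", "categorical",
                        "3-state secondary structure", ("H", "E", "C"), True),
    ParameterDefinition(20, "phi", "SS", "numeric",
                        "backbone φ (deg)", (-180.0, 180.0, 12), True),
    ParameterDefinition(21, "psi", "SS", "numeric",
                        "backbone ψ (deg)", (-180.0, 180.0, 12), True),
    ParameterDefinition(22, "ss_segment_length", "SS", "numeric",
                        "length of the 3-state segment containing the residue",
                        (0, 30, 15), True),
    ParameterDefinition(23, "ss_boundary_distance", "SS", "numeric",
                        "residues to the nearest segment boundary", (0, 15, 15), True),
    ParameterDefinition(24, "is_loop", "SS", "categorical",
                        "residue in a loop/coil segment", ("yes", "no"), True),
    # --- CR: cysteine resemblance ----------------------------------------
    ParameterDefinition(25, "amino_acid_identity", "CR", "categorical",
                        "native amino acid at the site", _AA20),
    ParameterDefinition(26, "mass_delta_cys", "CR", "numeric",
                        "residue mass minus cysteine mass (Da)", (-50.0, 90.0, 14), True),
    ParameterDefinition(27, "amino_acid_charge", "CR", "categorical",
                        "charge class of the native amino acid",
                        ("positive", "negative", "neutral")),
    ParameterDefinition(28, "volume_delta_cys", "CR", "numeric",
                        "residue volume minus cysteine volume (Å³)",
                        (-50.0, 125.0, 14), True),
)

#: The default four-parameter selection (one per category).
DEFAULT_SELECTION: tuple[int, int, int, int] = (11, 13, 18, 25)

REGISTRY_BY_ID: dict[int, ParameterDefinition] = {d.id: d for d in REGISTRY}
CATEGORIES = ("CS", "SE", "SS", "CR")


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

class ParameterTable:
    """Per-residue values of the registered parameters.

    Wraps a DataFrame keyed by (pdb_id, chain, residue_number, icode),
    one column per registry parameter.
    """

    KEY_COLUMNS = ("pdb_id", "chain", "residue_number", "icode")

    def __init__(self, frame: pd.DataFrame,
                 registry: Sequence[ParameterDefinition] = REGISTRY) -> None:
        self.frame = frame.reset_index(drop=True)
        self.registry = tuple(registry)

    def column_name(self, pid: int) -> str:
        return REGISTRY_BY_ID[pid].column if pid in REGISTRY_BY_ID else \
            next(d.column for d in self.registry if d.id == pid)

    def column(self, pid: int) -> pd.Series:
        return self.frame[self.column_name(pid)]

    def residue_ids(self) -> list[ResidueId]:
        return [(row.chain, int(row.residue_number), row.icode or "")
                for row in self.frame.itertuples()]

    def completeness(self) -> dict[int, float]:
        out = {}
        for d in self.registry:
            col = self.frame[d.column]
            out[d.id] = float(col.notna().mean()) if len(col) else 0.0
        return out

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".definitions.json")
        import json
        sidecar.write_text(json.dumps([
            {"id": d.id, "name": d.name, "category": d.category,
             "datatype": d.datatype, "doc": d.doc, "binning": list(d.binning),
             "interpretation": d.interpretation}
            for d in self.registry], indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterTable":
        return cls(pd.read_csv(path, keep_default_na=True,
                               dtype={"icode": str}).fillna({"icode": ""}))


def _segment_features(ss3: Mapping[ResidueId, str], rids: Sequence[ResidueId]
                      ) -> dict[ResidueId, tuple[float, float]]:
    """(segment length, distance to nearest boundary) on the 3-state string."""
    by_chain: dict[str, list[ResidueId]] = {}
    for rid in rids:
        by_chain.setdefault(rid[0], []).append(rid)
    out: dict[ResidueId, tuple[float, float]] = {}
    for chain_rids in by_chain.values():
        codes = [ss3.get(rid, "?") for rid in chain_rids]
        i = 0
        while i < len(codes):
            j = i
            while j < len(codes) and codes[j] == codes[i]:
                j += 1
            seg_len = j - i
            for k in range(i, j):
                out[chain_rids[k]] = (float(seg_len),
                                      float(min(k - i, j - 1 - k)))
            i = j
    return out


def build_parameter_table(model: StructureModel,
                          annotations: Mapping | None = None,
                          registry: Sequence[ParameterDefinition] = REGISTRY,
                          n_points: int = DEFAULT_N_POINTS) -> ParameterTable:
    """Compute every registry parameter for every standard residue.

    ``annotations`` may contain:
      ``consurf``: path to (or parsed map of) a ConSurf grades file;
      ``dssp``: path to (or parsed map of) a DSSP output file;
      ``msa``: ``(path_or_alignment, chain)`` aligned FASTA of homologs.

    Parameters that cannot be computed (no ConSurf/MSA given, missing
    backbone) are set to the missing sentinel; per-parameter completeness
    fractions are logged and stored in the model provenance.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    annotations = dict(annotations or {})
    std = model.standard_residues()
    rids = [r.residue_id for r in std]
    wanted = {d.id for d in registry}

    values: dict[int, dict[ResidueId, object]] = {}

    def need(*ids: int) -> bool:
        return any(i in wanted for i in ids)

    if need(1, 2, 3, 10, 11, 12):
        # one dot-surface computation feeds all ASA / surface-distance features
        asa_atoms, dots, atoms = _shrake_rupley(model, PROBE_RADIUS, n_points)
        per_res: dict[ResidueId, float] = {}
        per_res_sc: dict[ResidueId, float] = {}
        backbone = {"N", "CA", "C", "O", "OXT"}
        for a, v in zip(atoms, asa_atoms):
            per_res[a.residue_id] = per_res.get(a.residue_id, 0.0) + v
            if a.name not in backbone:
                per_res_sc[a.residue_id] = per_res_sc.get(a.residue_id, 0.0) + v
        values[2] = {rid: per_res.get(rid, 0.0) for rid in rids}
        values[1] = {}
        for rid, res in zip(rids, std):
            mx = WILKE_MAX_ASA.get(res.amino_acid)
            values[1][rid] = min(values[2][rid] / mx, 1.2) if mx else float("nan")
        values[3] = {rid: per_res_sc.get(rid, 0.0) for rid in rids}
        if len(dots) == 0:
            raise ValueError("no solvent-exposed surface dots (degenerate input)")
        dot_tree = cKDTree(dots)
        values[11] = {}
        values[10] = {}
        values[12] = {}
        c_offset = VDW_RADII["C"] + PROBE_RADIUS
        for rid, res in zip(rids, std):
            if res.atoms:
                depths = [max(0.0, float(dot_tree.query(a.coordinates)[0])
                              - (a.vdw_radius + PROBE_RADIUS))
                          for a in res.atoms]
                values[11][rid] = float(np.mean(depths))
            else:
                values[11][rid] = float("nan")
            ca = res.atom("CA")
            values[10][rid] = max(0.0, float(dot_tree.query(ca.coordinates)[0])
                                  - c_offset) if ca is not None else float("nan")
            cb = _cbeta_position(res)
            values[12][rid] = max(0.0, float(dot_tree.query(cb)[0]) - c_offset) \
                if cb is not None else float("nan")
    if need(4, 5, 6):
        hse = compute_half_sphere_exposure(model, 10.0)
        values[4] = {rid: float(hse[rid][0]) for rid in rids}
        values[5] = {rid: float(hse[rid][1]) for rid in rids}
        values[6] = {rid: (hse[rid][0] / s if (s := sum(hse[rid])) else float("nan"))
                     for rid in rids}
    if need(7):
        values[7] = {rid: float(v) for rid, v in
                     coordination_number(model, 10.0).items()}
    if need(8, 9):
        hse13 = compute_half_sphere_exposure(model, 13.0)
        values[8] = {rid: float(hse13[rid][0]) for rid in rids}
        values[9] = {rid: float(hse13[rid][1]) for rid in rids}
    # conservation
    consurf = annotations.get("consurf")
    if consurf is not None and need(13, 14):
        grades = consurf if isinstance(consurf, Mapping) else \
            parse_consurf_grades(consurf, model)
        values[13] = {rid: grades.get((rid[0], rid[1], ""), (float("nan"), None))[0]
                      for rid in rids}
        values[14] = {rid: (str(g[1]) if (g := grades.get((rid[0], rid[1], "")))
                            and g[1] is not None else None) for rid in rids}
    msa_in = annotations.get("msa")
    if msa_in is not None and need(15, 16, 17):
        msa, chain = msa_in
        if not isinstance(msa, (list, tuple)):
            msa = read_msa(msa)
        colmap = _map_msa_columns(model, chain, msa[0][1])
        stats = msa_column_stats(msa)
        cons = compute_msa_conservation(model, msa, chain)
        values[15] = dict(cons)
        values[16] = {rid: float(stats[c][1]) for c, rid in colmap.items()}
        values[17] = {rid: ("yes" if stats[c][2] else "no")
                      for c, rid in colmap.items()}
        # when no ConSurf file is present the MSA fallback also fills #13
        if 13 in wanted and 13 not in values:
            values[13] = dict(cons)

    # secondary structure
    if need(18, 19, 22, 23, 24):
        dssp_in = annotations.get("dssp")
        if dssp_in is not None:
            ss8 = dssp_in if isinstance(dssp_in, Mapping) else parse_dssp_file(dssp_in)
            ss8 = {rid: ss8.get(rid, "?") for rid in rids}
        else:
            ss8 = assign_secondary_structure(model)
        ss3 = to_three_state(ss8)
        values[18] = {rid: (c if c in _SS8 else None) for rid, c in ss8.items()}
        values[19] = {rid: (c if c in ("H", "E", "C") else None)
                      for rid, c in ss3.items()}
        seg = _segment_features(ss3, rids)
        values[22] = {rid: seg.get(rid, (float("nan"),) * 2)[0] for rid in rids}
        values[23] = {rid: seg.get(rid, (float("nan"),) * 2)[1] for rid in rids}
        values[24] = {rid: ("yes" if ss3.get(rid) == "C" else "no") for rid in rids}
    if need(20, 21):
        dih = backbone_dihedrals(model)
        values[20] = {rid: dih[rid][0] for rid in rids}
        values[21] = {rid: dih[rid][1] for rid in rids}

    # cysteine resemblance
    if need(25, 26, 27, 28):
        for rid, res in zip(rids, std):
            cr = compute_cysteine_resemblance(res)
            values.setdefault(25, {})[rid] = cr["identity"] if cr else None
            values.setdefault(26, {})[rid] = cr["mass_delta"] if cr else float("nan")
            values.setdefault(27, {})[rid] = cr["charge_class"] if cr else None
            values.setdefault(28, {})[rid] = cr["volume_delta"] if cr else float("nan")

    rows = []
    for rid, res in zip(rids, std):
        row: dict[str, object] = {"pdb_id": model.pdb_id, "chain": rid[0],
                                  "residue_number": rid[1], "icode": rid[2],
                                  "amino_acid": res.amino_acid}
        for d in registry:
            v = values.get(d.id, {}).get(rid)
            if d.datatype == "numeric":
                row[d.column] = float("nan") if v is None else float(v)
            else:
                row[d.column] = v
        rows.append(row)
    table = ParameterTable(pd.DataFrame(rows), registry)
    comp = table.completeness()
    logger.info("parameter completeness: %s",
                {k: round(v, 3) for k, v in comp.items()})
    model.provenance.setdefault("parameter_completeness", {}).update(
        {str(k): v for k, v in comp.items()})
    return table
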