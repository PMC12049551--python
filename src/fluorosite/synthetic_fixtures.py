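"""Synthetic structures and label databases for tests and benchmarks.

Everything the pipeline consumes can be generated here without any
download: ideal-geometry peptides (helix, sheet, coil), jittered-lattice
globules that mimic protein packing density, blocking-atom arrangements
(wall, shell) for accessible-volume tests, label databases with planted
per-parameter enrichments, and the benchmark manifest for the
distance-estimator comparison.  Every generator is deterministic under
its seed and emits structures that round-trip through ``structure_io``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .geometry import (ANGLE_CA_C_N, ANGLE_CA_C_O, ANGLE_C_N_CA, ANGLE_N_CA_C,
                       BOND_CA_C, BOND_C_N, BOND_C_O, BOND_N_CA, ideal_cbeta,
                       place_atom, rotation_matrix)
from .structure_io import (STANDARD_AMINO_ACIDS, VDW_RADII, AtomRecord,
                           ResidueRecord, StructureModel)

FIXTURE_KINDS = ("helix", "sheet", "coil", "globule", "wall", "shell")


@dataclass
class FixtureSpec:
    kind: str
    n_residues: int = 12
    seed: int = 0
    #: kind-specific geometry knobs (see the individual builders)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"one of {FIXTURE_KINDS}")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")


# ---------------------------------------------------------------------------
# Backbone builders
# ---------------------------------------------------------------------------

def _backbone_from_torsions(phi_psi: Sequence[tuple[float, float]],
                            omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O/CB coordinates for a peptide with the given (φ, ψ)."""
    n_res = len(phi_psi)
    residues: list[dict[str, np.ndarray]] = []
    # seed first residue in a canonical frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          BOND_N_CA, ANGLE_C_N_CA, omega)
        c_i = place_atom(prev["C"], n_i, ca_i,
                         BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl O from psi (trans to the next N); CB from ideal geometry
    for i, res in enumerate(residues):
        psi = phi_psi[i][1]
        res["O"] = place_atom(res["N"], res["CA"], res["C"],
                              BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        res["CB"] = ideal_cbeta(res["N"], res["CA"], res["C"])
    return residues


def _assemble(pdb_id: str, chains: Sequence[tuple[str, Sequence[str], Sequence[dict]]],
              start_number: int = 1) -> StructureModel:
    """Pack per-residue atom dicts into a StructureModel."""
    model = StructureModel(pdb_id=pdb_id, provenance={"source": "synthetic", "log": []})
    serial = 0
    for chain_id, seq, residues in chains:
        for i, (aa, atoms) in enumerate(zip(seq, residues)):
            rid = (chain_id, start_number + i, "")
            rec = ResidueRecord(residue_id=rid, amino_acid=aa)
            for name in ("N", "CA", "C", "O", "CB"):
                if name not in atoms:
                    continue
                if name == "CB" and aa == "GLY":
                    continue
                serial += 1
                el = name[0]
                rec.atoms.append(AtomRecord(
                    serial=serial, name=name, element=el, residue_id=rid,
                    coordinates=np.asarray(atoms[name], dtype=float),
                    vdw_radius=VDW_RADII[el]))
            model.residues.append(rec)
    return model


def _blocker_residues(chain: str, coords: np.ndarray, serial0: int,
                      name: str = "BLK") -> list[ResidueRecord]:
    """One single-carbon pseudo-residue per blocking atom (PDB-safe)."""
    out = []
    for j, xyz in enumerate(coords):
        rid = (chain, j + 1, "")
        rec = ResidueRecord(residue_id=rid, amino_acid=name, is_standard=False)
        rec.atoms.append(AtomRecord(
            serial=serial0 + j, name="C", element="C", residue_id=rid,
            coordinates=xyz, is_hetero=True, vdw_radius=VDW_RADII["C"]))
        out.append(rec)
    return out


def _random_sequence(rng: np.random.Generator, n: int) -> list[str]:
    return [STANDARD_AMINO_ACIDS[i]
            for i in rng.integers(0, len(STANDARD_AMINO_ACIDS), n)]


# ---------------------------------------------------------------------------
# Fixture kinds
# ---------------------------------------------------------------------------

# antiparallel two-strand register: rigid placement of the partner strand,
# frozen after a one-off scan for Kabsch-Sander H-bond energies < -0.5
SHEET_STRAND_SEPARATION = 4.7   # Å between strand axes
SHEET_REGISTER_SHIFT = 0.0      # Å shift along the strand axis


def generate_toy_structure(spec: FixtureSpec) -> StructureModel:
    """Build an ideal-geometry toy structure for the given spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    p = spec.params

    if spec.kind == "helix":
        phi_psi = [(-57.0, -47.0)] * n
        residues = _backbone_from_torsions(phi_psi)
        seq = p.get("sequence") or ["ALA"] * n
        return _assemble("helix", [("A", seq, residues)])

    if spec.kind == "coil":
        # fully extended chain: no backbone hydrogen bonds form
        phi_psi = [(180.0, 180.0)] * n
        residues = _backbone_from_torsions(phi_psi)
        seq = p.get("sequence") or ["ALA"] * n
        return _assemble("coil", [("A", seq, residues)])

    if spec.kind == "sheet":
        phi_psi = [(-139.0, 135.0)] * n
        strand1 = _backbone_from_torsions(phi_psi)
        # orient strand axis along x
        axis = strand1[-1]["CA"] - strand1[0]["CA"]
        rot = _align_to_x(axis)
        origin = strand1[0]["CA"].copy()
        strand1 = [{k: rot @ (v - origin) for k, v in r.items()} for r in strand1]
        # antiparallel partner: flip about the y axis, offset in y
        flip = rotation_matrix(np.array([0.0, 1.0, 0.0]), 180.0)
        shift = np.array([
            strand1[-1]["CA"][0] + p.get("register_shift", SHEET_REGISTER_SHIFT),
            p.get("separation", SHEET_STRAND_SEPARATION), 0.0])
        strand2 = [{k: flip @ v + shift for k, v in r.items()} for r in strand1]
        seq = ["ALA"] * n
        return _assemble("sheet", [("A", seq, strand1), ("B", seq, strand2)])

    if spec.kind == "globule":
        return _globule(rng, n, spacing=p.get("spacing", 5.0),
                        jitter=p.get("jitter", 0.55))

    if spec.kind == "wall":
        # one ALA residue with its CB pointing at a dense plane of atoms
        offset = p.get("offset", 5.0)        # Å from CB to the wall plane
        half = p.get("half_extent", 30.0)
        wall_spacing = p.get("wall_spacing", 1.8)
        residues = _backbone_from_torsions([(180.0, 180.0)])
        model = _assemble("wall", [("A", ["ALA"], residues)])
        cb = model.residues[0].atom("CB").coordinates
        # wall plane normal +x at x = cb_x + offset
        ys = np.arange(-half, half + 1e-9, wall_spacing)
        pts = np.array([[cb[0] + offset, y, z] for y in ys for z in ys])
        model.residues.extend(_blocker_residues("W", pts, serial0=1000))
        return model

    if spec.kind == "shell":
        # residues fully enclosed in a dense blocking matrix: every solvent
        # probe position around the cluster is occluded, so SASA is zero
        inner = _globule(rng, n, spacing=5.4, jitter=0.4)
        coords = inner.atom_coordinates()
        center = coords.mean(axis=0)
        radius = p.get("radius",
                       np.linalg.norm(coords - center, axis=1).max()
                       + p.get("margin", 5.0))
        spacing = p.get("matrix_spacing", 1.6)
        grid = np.arange(-radius, radius + spacing, spacing)
        pts = np.array([[x, y, z] for x in grid for y in grid for z in grid
                        if x * x + y * y + z * z <= radius * radius]) + center
        from scipy.spatial import cKDTree
        d, _ = cKDTree(coords).query(pts)
        pts = pts[d > p.get("clearance", 2.2)]
        inner.pdb_id = "shell"
        inner.residues.extend(_blocker_residues("S", pts, serial0=9000))
        return inner

    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def _align_to_x(axis: np.ndarray) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, x)
    s = np.linalg.norm(v)
    if s < 1e-12:
        return np.eye(3)
    c = float(np.dot(axis, x))
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k * ((1 - c) / s ** 2)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral unit-sphere points."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def _globule(rng: np.random.Generator, n: int, spacing: float,
             jitter: float) -> StructureModel:
    """Residues packed on a jittered cubic lattice inside a sphere.

    The lattice spacing is chosen so that roughly protein-like density is
    reached: a substantial buried core (~30% of residues with relative
    ASA < 0.1) plus an exposed surface stratum.
    """
    # enough lattice sites inside a sphere to host n residues
    radius = spacing * ((3 * n) / (4 * np.pi * 0.9)) ** (1 / 3) + spacing
    grid = np.arange(-radius, radius + spacing, spacing)
    sites = np.array([[x, y, z] for x in grid for y in grid for z in grid
                      if x * x + y * y + z * z <= radius * radius])
    order = np.argsort(np.linalg.norm(sites, axis=1))  # fill from the core out
    sites = sites[order[:n]]
    if len(sites) < n:
        raise ValueError("lattice too small; increase spacing or radius")
    sites = sites + rng.normal(0.0, jitter, sites.shape)

    # template residue centered at its CA
    template = _backbone_from_torsions([(-60.0, -40.0)])[0]
    template = {k: v - template["CA"] for k, v in template.items()}
    seq = _random_sequence(rng, n)
    residues = []
    for center in sites:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = rotation_matrix(axis, float(rng.uniform(0, 360)))
        residues.append({k: rot @ v + center for k, v in template.items()})
    return _assemble("globule", [("A", seq, residues)])


def synthetic_conservation(model: StructureModel, seed: int = 0
                           ) -> dict[tuple, tuple[float, int]]:
    """Synthetic per-residue conservation annotation (ConSurf-like map).

    Scores are standard-normal with the conserved-negative sign
    convention; grades bin the score into 1 (variable) … 9 (conserved).
    Feeds the conservation parameters in tests without any homolog data.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for res in model.standard_residues():
        score = float(rng.normal())
        grade = int(np.clip(np.ceil((1 - (score + 3) / 6) * 9), 1, 9))
        rid = res.residue_id
        out[(rid[0], rid[1], "")] = (score, grade)
    return out


# ---------------------------------------------------------------------------
# Synthetic label databases
# ---------------------------------------------------------------------------

def generate_label_database(background_table, enrichments: Mapping | None,
                            n_labeled: int, seed: int,
                            cysteine_fraction: float = 0.9):
    """Sample a synthetic database of "successfully labeled" residues.

    ``background_table`` is a ParameterTable (see ``residue_parameters``);
    ``enrichments`` maps parameter ids to either a callable
    ``value -> weight`` or a dict ``{category/bin label: multiplier}``.
    A residue's sampling weight is the product of the per-parameter
    weights evaluated on its values; multipliers of 1 everywhere give a
    uniform subsample.  Mutation types are drawn 90% cysteine / 10%
    unnatural amino acid, the mix observed in curated labeling data.
    """
    from .training import LabelDatabase, LabelRecord  # local import, no cycle at import time

    rng = np.random.default_rng(seed)
    df = background_table.frame
    if n_labeled > len(df):
        raise ValueError("n_labeled exceeds number of residues")
    weights = np.ones(len(df))
    for pid, spec in (enrichments or {}).items():
        col = df[background_table.column_name(pid)]
        if callable(spec):
            w = np.array([1.0 if v is None or (isinstance(v, float) and np.isnan(v))
                          else float(spec(v)) for v in col])
        else:
            w = np.array([float(spec.get(v, 1.0)) if v == v and v is not None else 1.0
                          for v in col])
        if np.any(w < 0):
            raise ValueError("enrichment multipliers must be >= 0")
        weights *= w
    if weights.sum() == 0:
        raise ValueError("all sampling weights are zero")
    probs = weights / weights.sum()
    idx = rng.choice(len(df), size=n_labeled, replace=False, p=probs)

    assays = ("smFRET", "imaging", "bulk-FRET", "other")
    records = []
    for i in idx:
        row = df.iloc[i]
        mutation = "cysteine" if rng.random() < cysteine_fraction else "UAA"
        records.append(LabelRecord(
            pdb_id=str(row["pdb_id"]), chain=str(row["chain"]),
            residue_number=int(row["residue_number"]),
            icode=str(row.get("icode", "") or ""),
            soluble=True, stoichiometry="monomer", homology_model=False,
            mutation_type=mutation,
            assay_type=assays[int(rng.integers(0, len(assays)))],
            fluorophore="synthetic-dye", reference="synthetic"))
    return LabelDatabase(records=records)


# ---------------------------------------------------------------------------
# AV benchmark manifests
# ---------------------------------------------------------------------------

DEFAULT_DYE_GRID: tuple[dict, ...] = (
    {"linker_length": 10.0, "linker_width": 4.5, "dye_radii": (3.0,)},
    {"linker_length": 12.5, "linker_width": 4.5, "dye_radii": (3.5,)},
    {"linker_length": 15.0, "linker_width": 4.5, "dye_radii": (4.0,)},
    {"linker_length": 17.5, "linker_width": 4.5, "dye_radii": (4.5,)},
    {"linker_length": 20.0, "linker_width": 4.5, "dye_radii": (5.0,)},
)


def run_av_benchmark(manifest: Sequence[dict], grid_spacing: float = 1.0):
    """Evaluate all three distance estimators over a benchmark manifest.

    Returns a DataFrame with one row per (pair, dye variant):
    ``r_cbeta``, ``r_ssm`` and ``r_grid`` (NaN where the grid AV came up
    empty).  Structures and accessible volumes are cached across entries.
    """
    import pandas as pd
    from .av_distance import (FluorophoreParams, cbeta_distance,
                              grid_accessible_volume, ssm_distance)

    structures: dict[tuple, StructureModel] = {}
    av_cache: dict[tuple, object] = {}
    rows = []
    for entry in manifest:
        skey = tuple(sorted(entry["structure"].items()))
        if skey not in structures:
            structures[skey] = generate_toy_structure(FixtureSpec(**entry["structure"]))
        model = structures[skey]
        dye = FluorophoreParams(**entry["dye"])
        ri = tuple(entry["pair"][0])
        rj = tuple(entry["pair"][1])
        mps = []
        for rid in (ri, rj):
            akey = (skey, dye.linker_length, dye.max_dye_radius, rid)
            if akey not in av_cache:
                av_cache[akey] = grid_accessible_volume(model, rid, dye,
                                                        grid_spacing)
            mps.append(av_cache[akey].mean_position)
        r_grid = float("nan") if any(m is None for m in mps) else \
            float(np.linalg.norm(mps[0] - mps[1]))
        rows.append({
            "seed": entry["structure"]["seed"],
            "linker_length": dye.linker_length,
            "dye_radius": dye.max_dye_radius,
            "r_cbeta": cbeta_distance(model, ri, rj),
            "r_ssm": ssm_distance(model, ri, rj, dye),
            "r_grid": r_grid,
        })
    return pd.DataFrame(rows)


def generate_av_test_set(n_structures: int = 10, n_pairs: int = 10,
                         dye_param_grid: Sequence[dict] = DEFAULT_DYE_GRID,
                         seed: int = 0, n_residues: int = 110) -> list[dict]:
    """Benchmark manifest: (structure spec, residue pair, dye params) tuples.

    Pairs are drawn among the more exposed half of each globule's residues
    (the stratum a labeling experiment would target, where accessible
    volumes are non-empty).  Deterministic under the seed.
    """
    from .residue_parameters import compute_sasa

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    manifest: list[dict] = []
    for si in range(n_structures):
        struct_seed = int(rng.integers(0, 2 ** 31 - 1))
        spec = FixtureSpec(kind="globule", n_residues=n_residues, seed=struct_seed)
        model = generate_toy_structure(spec)
        sasa = compute_sasa(model, n_points=240)
        rel = {rid: v[1] for rid, v in sasa.items()}
        cutoff = float(np.median(list(rel.values())))
        exposed = sorted([rid for rid, v in rel.items() if v >= cutoff])
        pairs = set()
        while len(pairs) < n_pairs:
            i, j = rng.choice(len(exposed), size=2, replace=False)
            pairs.add(tuple(sorted((int(i), int(j)))))
        for (i, j) in sorted(pairs):
            for dye in dye_param_grid:
                manifest.append({
                    "structure": {"kind": "globule", "n_residues": n_residues,
                                  "seed": struct_seed},
                    "pair": (exposed[i], exposed[j]),
                    "dye": dict(dye),
                })
    return manifest
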