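"""Interdye distance prediction: Cβ, spherical-sector and grid-AV models.

Three estimators of the distance between two dyes attached via flexible
linkers, in increasing cost and accuracy:

* the bare Cβ–Cβ distance (ignores dye and linker geometry entirely);
* the spherical-sector model (SSM): the accessible volume of a dye on a
  linker of length R is approximated by a spherical sector, which gives
  a closed-form relation between the center of mass d' of the blocking
  protein atoms within reach and the mean dye position d,

      d = (1 − (3/4)·R̃/|d'|) · d',

  with an effective radius R̃ = R + ε + (dye radius + atom vdW): the ε
  term (~0.5 Å) corrects for the fluorophore core and the clash distance
  accounts for the accessible volume holding dye *centers*.  The
  prefactor is negative whenever |d'| < (3/4)R̃, so the mean position is
  displaced *away* from the blocking mass; it vanishes at |d'| = (3/4)R̃
  and the relation is exact in the half-space (hemisphere) limit.  The
  SSM is a screening tool, orders of magnitude faster than a grid AV;
* the grid accessible volume: all grid positions within linker reach of
  the attachment Cβ are tested for dye-size clashes against the protein
  and for linker reachability (a geodesic path of length ≤ R through
  sterically passable space); the mean dye position is the centroid of
  the allowed positions.

Mean-position distances R_MP systematically underestimate the
FRET-averaged distance R⟨E⟩ at short range because averaging FRET
efficiency over the two volumes weights short dye-dye distances more;
the conversion uses an exponential correction R⟨E⟩ = R_MP + a·e^(−R_MP/b)
whose constants are calibrated once per dye pair against the grid-AV
efficiency average.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .residue_parameters import _cbeta_position
from .structure_io import ResidueId, ResidueRecord, StructureModel

logger = logging.getLogger("fluorosite")


# ---------------------------------------------------------------------------
# Dye parameters
# ---------------------------------------------------------------------------

@dataclass
class FluorophoreParams:
    name: str = "generic"
    linker_length: float = 15.0     # R, Å
    linker_width: float = 4.5       # Å
    dye_radii: tuple[float, ...] = (3.5,)   # 1-3 radii, Å
    epsilon: float = 0.5            # fluorophore-core correction to R, Å
    forster_radius: float | None = None     # R0, Å (pair property)

    def __post_init__(self) -> None:
        if self.linker_length <= 0:
            raise ValueError("linker_length must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.forster_radius is not None and self.forster_radius <= 0:
            raise ValueError("forster_radius must be positive")

    @property
    def max_dye_radius(self) -> float:
        return max(self.dye_radii)


#: Shipped dye-pair presets (Förster radii in Å as commonly used for
#: these pairs); linker/dye geometry defaults are FPS-class values and
#: can be overridden per dye.
DYE_PAIR_PRESETS: dict[str, FluorophoreParams] = {
    "alexa555-alexa647": FluorophoreParams("alexa555-alexa647", 20.0, 4.5,
                                           (5.0, 4.5, 1.5), 0.5, 51.0),
    "atto532-atto643": FluorophoreParams("atto532-atto643", 15.0, 4.5,
                                         (5.0, 4.5, 1.5), 0.5, 58.0),
    "alexa546-alexa647": FluorophoreParams("alexa546-alexa647", 20.0, 4.5,
                                           (5.0, 4.5, 1.5), 0.5, 65.0),
    "generic": FluorophoreParams("generic", 15.0, 4.5, (3.5,), 0.5, 50.0),
}


@dataclass
class AccessibleVolume:
    attachment: np.ndarray          # Cβ (or virtual Cβ), Å
    grid_spacing: float
    points: np.ndarray              # (N,3) allowed grid positions
    mean_position: np.ndarray | None

    @property
    def empty(self) -> bool:
        return self.mean_position is None

    def to_xyz(self, path) -> None:
        """Export the allowed point cloud as an XYZ file for viewers."""
        lines = [str(len(self.points)), "accessible volume"]
        lines += [f"D {x:.3f} {y:.3f} {z:.3f}" for x, y, z in self.points]
        from pathlib import Path
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class DistanceResult:
    residue_ids: tuple[ResidueId, ResidueId]
    r_cbeta: float
    r_mp: float | None
    r_fret_avg: float | None
    efficiency: float | None
    estimator: str


# ---------------------------------------------------------------------------
# Cβ distance
# ---------------------------------------------------------------------------

def _attachment_point(res: ResidueRecord) -> np.ndarray:
    pos = _cbeta_position(res)
    if pos is None:
        raise ValueError(f"residue {res.residue_id} lacks backbone atoms for "
                         "a (virtual) Cβ attachment point")
    return pos


def cbeta_distance(model: StructureModel, res_i: ResidueId, res_j: ResidueId
                   ) -> float:
    """Euclidean distance between the (virtual) Cβ atoms of two residues."""
    ri, rj = model.residue(res_i), model.residue(res_j)
    if ri is None or rj is None:
        raise ValueError("residue not found in model")
    return float(np.linalg.norm(_attachment_point(ri) - _attachment_point(rj)))


# ---------------------------------------------------------------------------
# Grid accessible volume
# ---------------------------------------------------------------------------

def grid_accessible_volume(model: StructureModel, residue: ResidueId,
                           dye: FluorophoreParams, grid_spacing: float = 1.0
                           ) -> AccessibleVolume:
    """FPS-style single-volume grid AV around the residue's Cβ.

    A grid point is allowed iff (a) a dye sphere of the largest dye
    radius centered there clashes with no protein atom (atom vdW + dye
    radius), and (b) it is linker-reachable: connected to the attachment
    by a geodesic of length ≤ R through positions with linker-width
    clearance.  Zero allowed points yield an empty AV (flagged, not an
    exception).
    """
    from skimage.graph import MCP_Geometric

    res = model.residue(residue)
    if res is None:
        raise ValueError(f"residue {residue} not in model")
    attach = _attachment_point(res)
    r_link = dye.linker_length
    h = grid_spacing

    n_half = int(math.ceil(r_link / h)) + 1
    axis = np.arange(-n_half, n_half + 1) * h
    shape = (len(axis),) * 3
    origin = attach - n_half * h

    coords = model.atom_coordinates()
    radii = np.array([a.vdw_radius for a in model.atoms()])
    dist_attach = np.linalg.norm(coords - attach, axis=1)
    # the attachment atom itself carries the linker bond: exclude it
    near = (dist_attach <= r_link + radii.max() + dye.max_dye_radius + h) \
        & (dist_attach > 1e-6)
    coords, radii = coords[near], radii[near]

    def clash_mask(clearance: float, add_vdw: bool = True) -> np.ndarray:
        """True where a probe of the given radius clashes with an atom."""
        blocked = np.zeros(shape, dtype=bool)
        for xyz, rv in zip(coords, radii):
            rr = (rv + clearance) if add_vdw else clearance
            ijk = (xyz - origin) / h
            lo = np.maximum(np.ceil(ijk - rr / h).astype(int), 0)
            hi = np.minimum(np.floor(ijk + rr / h).astype(int), len(axis) - 1)
            if np.any(lo > hi):
                continue
            gx = axis[lo[0]:hi[0] + 1, None, None] + attach[0] - xyz[0]
            gy = axis[None, lo[1]:hi[1] + 1, None] + attach[1] - xyz[1]
            gz = axis[None, None, lo[2]:hi[2] + 1] + attach[2] - xyz[2]
            d2 = gx ** 2 + gy ** 2 + gz ** 2
            blocked[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] |= \
                d2 <= rr ** 2
        return blocked

    dye_blocked = clash_mask(dye.max_dye_radius)
    # the linker tube threads close to the protein (it is covalently
    # attached next to backbone atoms), so its clearance is measured to
    # atom centers with the half-width alone
    link_blocked = clash_mask(dye.linker_width / 2.0, add_vdw=False)

    # sphere of linker reach
    gx = axis[:, None, None]
    gy = axis[None, :, None]
    gz = axis[None, None, :]
    r2 = gx ** 2 + gy ** 2 + gz ** 2
    in_sphere = r2 <= r_link ** 2

    passable = (~link_blocked) & in_sphere
    center = (n_half, n_half, n_half)
    # the first covalent linker segment leaves the Cβ regardless of the
    # width clearance: open a small seed sphere around the attachment
    seed_radius = max(1.5 * h, 2.0)
    passable |= r2 <= seed_radius ** 2
    passable[center] = True

    costs = np.where(passable, 1.0, np.inf)
    mcp = MCP_Geometric(costs, sampling=(h, h, h))
    dist, _ = mcp.find_costs([center])

    allowed = in_sphere & (~dye_blocked) & (dist <= r_link)
    idx = np.argwhere(allowed)
    if len(idx) == 0:
        logger.info("empty accessible volume at %s", residue)
        return AccessibleVolume(attach, h, np.empty((0, 3)), None)
    points = origin + idx * h
    return AccessibleVolume(attach, h, points, points.mean(axis=0))


# ---------------------------------------------------------------------------
# Spherical-sector model
# ---------------------------------------------------------------------------

#: Representative atom van der Waals radius (carbon) entering the
#: dye-center clash distance of the effective sector radius.
REPRESENTATIVE_VDW = 1.7


def ssm_effective_radius(dye: FluorophoreParams) -> float:
    """Effective sector radius R̃ = R + ε + (dye radius + atom vdW).

    The accessible volume holds dye *centers*, which are excluded within
    (atom vdW + dye radius) of every atom; the spherical-sector relation
    therefore operates on the linker length enlarged by the ε core
    correction plus that clash distance.
    """
    return (dye.linker_length + dye.epsilon + dye.max_dye_radius
            + REPRESENTATIVE_VDW)


def spherical_sector_offset(d_prime: np.ndarray, r_eff: float) -> np.ndarray:
    """The sector-model relation d = (1 − (3/4)·R̃/|d'|)·d'.

    For |d'| < (3/4)·R̃ — the regime of the sector geometry, where the
    complementary (inaccessible) sector's center of mass sits closer than
    3R̃/4 — the prefactor is negative and d points *away* from the
    blocking mass; |d| + |d'| = (3/4)·R̃, exact in the hemisphere limit.
    The offset vanishes at the root |d'| = (3/4)·R̃ and for |d'| ≈ 0
    (symmetric occlusion: no preferred direction).
    """
    norm = float(np.linalg.norm(d_prime))
    if norm < 1e-9:
        return np.zeros(3)
    return (1.0 - 0.75 * r_eff / norm) * np.asarray(d_prime, dtype=float)


def ssm_mean_position(model: StructureModel, residue: ResidueId,
                      dye: FluorophoreParams,
                      _atom_cache: np.ndarray | None = None) -> np.ndarray:
    """Mean-position offset d of the dye from the attachment Cβ.

    d' is the center of mass of the protein atoms within the effective
    radius R̃ of the attachment (the attachment atom itself excluded — it
    carries the linker bond); d follows the spherical-sector relation.
    No atoms within reach (free dye) gives d = 0.  Returns the offset
    vector; the mean dye position is attachment + d.
    """
    res = model.residue(residue)
    if res is None:
        raise ValueError(f"residue {residue} not in model")
    attach = _attachment_point(res)
    r_eff = ssm_effective_radius(dye)
    coords = _atom_cache if _atom_cache is not None else model.atom_coordinates()
    rel = coords - attach
    d2 = np.einsum("ij,ij->i", rel, rel)
    within = (d2 <= r_eff ** 2) & (d2 > 1e-12)
    if not np.any(within):
        return np.zeros(3)
    return spherical_sector_offset(rel[within].mean(axis=0), r_eff)


def ssm_distance(model: StructureModel, res_i: ResidueId, res_j: ResidueId,
                 dye_i: FluorophoreParams, dye_j: FluorophoreParams | None = None
                 ) -> float:
    """Mean-position distance R_MP from the spherical-sector model."""
    dye_j = dye_j or dye_i
    cache = model.atom_coordinates()
    ri = model.residue(res_i)
    rj = model.residue(res_j)
    pi = _attachment_point(ri) + ssm_mean_position(model, res_i, dye_i, cache)
    pj = _attachment_point(rj) + ssm_mean_position(model, res_j, dye_j, cache)
    return float(np.linalg.norm(pi - pj))


def grid_av_distance(model: StructureModel, res_i: ResidueId, res_j: ResidueId,
                     dye_i: FluorophoreParams,
                     dye_j: FluorophoreParams | None = None,
                     grid_spacing: float = 1.0) -> float | None:
    """Mean-position distance R_MP between two grid accessible volumes;
    None when either AV is empty."""
    dye_j = dye_j or dye_i
    av_i = grid_accessible_volume(model, res_i, dye_i, grid_spacing)
    av_j = grid_accessible_volume(model, res_j, dye_j, grid_spacing)
    if av_i.empty or av_j.empty:
        return None
    return float(np.linalg.norm(av_i.mean_position - av_j.mean_position))


# ---------------------------------------------------------------------------
# FRET efficiency and FRET-averaged distances
# ---------------------------------------------------------------------------

def fret_efficiency(r: float, r0: float) -> float:
    """Förster relation E = 1/(1 + (R/R0)^6)."""
    if r < 0:
        raise ValueError("distance must be >= 0")
    if r0 <= 0:
        raise ValueError("Förster radius must be positive")
    return 1.0 / (1.0 + (r / r0) ** 6)


def efficiency_to_distance(e: float, r0: float) -> float:
    if not 0 < e < 1:
        raise ValueError("efficiency must be in (0, 1)")
    return r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)


def av_fret_averaged_distance(av_d: AccessibleVolume, av_a: AccessibleVolume,
                              r0: float, max_points: int = 1500,
                              seed: int = 0) -> float:
    """Grid-AV oracle for R⟨E⟩: FRET efficiency averaged isotropically
    over all donor/acceptor position pairs, converted back to a distance.

    Point clouds larger than ``max_points`` are subsampled with a seeded
    generator (deterministic).
    """
    if av_d.empty or av_a.empty:
        raise ValueError("cannot average over an empty accessible volume")
    rng = np.random.default_rng(seed)

    def sample(points: np.ndarray) -> np.ndarray:
        if len(points) <= max_points:
            return points
        return points[rng.choice(len(points), max_points, replace=False)]

    pd_, pa_ = sample(av_d.points), sample(av_a.points)
    diff = pd_[:, None, :] - pa_[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    e_avg = float(np.mean(1.0 / (1.0 + (r / r0) ** 6)))
    e_avg = min(max(e_avg, 1e-12), 1 - 1e-12)
    return efficiency_to_distance(e_avg, r0)


#: Default exponential-correction constants (a, b) per dye pair, from a
#: one-off calibration against the grid-AV efficiency average on the
#: synthetic benchmark set (see calibrate_correction and docs/methods.md).
DEFAULT_CORRECTION: dict[str, tuple[float, float]] = {
    "alexa555-alexa647": (22.71, 23.03),
    "atto532-atto643": (13.21, 22.64),
    "alexa546-alexa647": (20.93, 28.11),
    "generic": (15.34, 20.53),
}


def mp_to_fret_averaged(r_mp: float, dye_pair: str | tuple[float, float] = "generic"
                        ) -> float:
    """Convert a mean-position distance to a FRET-averaged distance with
    the exponential short-range correction R⟨E⟩ = R_MP + a·e^(−R_MP/b).

    ``dye_pair`` is a calibrated pair name or an explicit (a, b) tuple.
    The correction is positive, monotone in R_MP and vanishes at long
    range.
    """
    if r_mp < 0:
        raise ValueError("R_MP must be >= 0")
    if isinstance(dye_pair, str):
        if dye_pair not in DEFAULT_CORRECTION:
            if "generic" not in DEFAULT_CORRECTION:
                raise ValueError(f"no calibration for dye pair {dye_pair!r}")
            a, b = DEFAULT_CORRECTION["generic"]
        else:
            a, b = DEFAULT_CORRECTION[dye_pair]
    else:
        a, b = dye_pair
    return float(r_mp + a * math.exp(-r_mp / b))


def fit_exponential_correction(r_mp: np.ndarray, delta: np.ndarray
                               ) -> tuple[float, float]:
    """Least-squares fit of delta = a·exp(−R_MP/b).  Returns (a, b)."""
    r_mp = np.asarray(r_mp, dtype=float)
    delta = np.asarray(delta, dtype=float)
    try:
        popt, _ = curve_fit(lambda r, a, b: a * np.exp(-r / b), r_mp, delta,
                            p0=(max(delta.max(), 1.0), 20.0), maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"correction fit did not converge: {exc}; "
                           f"residual range {delta.min():.2f}..{delta.max():.2f}"
                           ) from exc
    return float(popt[0]), float(popt[1])


def calibrate_correction(structures: Sequence[StructureModel],
                         pairs: Sequence[tuple[ResidueId, ResidueId]] | None,
                         dye: FluorophoreParams, seed: int = 0,
                         grid_spacing: float = 1.0,
                         min_pairs: int = 20) -> tuple[float, float]:
    """Calibrate (a, b) of the exponential correction for one dye pair.

    For residue pairs across the fixture structures, R_MP and the
    grid-AV efficiency-averaged R⟨E⟩ are computed and the residual
    R⟨E⟩ − R_MP is fitted to a·exp(−R_MP/b).  ``pairs`` is one pair list
    per structure; None samples pairs at random (seeded).
    """
    if dye.forster_radius is None:
        raise ValueError("dye pair needs a Förster radius for calibration")
    rng = np.random.default_rng(seed)
    r_mps: list[float] = []
    deltas: list[float] = []
    for si, model in enumerate(structures):
        if pairs is not None:
            plist = pairs[si]
        else:
            rids = [r.residue_id for r in model.standard_residues()]
            plist = []
            for _ in range(6):
                i, j = rng.choice(len(rids), 2, replace=False)
                plist.append((rids[i], rids[j]))
        avs: dict[ResidueId, AccessibleVolume] = {}
        for (ri, rj) in plist:
            for rid in (ri, rj):
                if rid not in avs:
                    avs[rid] = grid_accessible_volume(model, rid, dye, grid_spacing)
            if avs[ri].empty or avs[rj].empty:
                continue
            r_mp = float(np.linalg.norm(avs[ri].mean_position
                                        - avs[rj].mean_position))
            r_e = av_fret_averaged_distance(avs[ri], avs[rj], dye.forster_radius,
                                            seed=seed)
            r_mps.append(r_mp)
            deltas.append(r_e - r_mp)
    if len(r_mps) < min_pairs:
        raise ValueError(f"only {len(r_mps)} usable pairs (< {min_pairs})")
    return fit_exponential_correction(np.array(r_mps), np.array(deltas))


# ---------------------------------------------------------------------------
# Combined per-pair result
# ---------------------------------------------------------------------------

def distance_result(model: StructureModel, res_i: ResidueId, res_j: ResidueId,
                    dye: FluorophoreParams, estimator: str = "ssm",
                    grid_spacing: float = 1.0,
                    correction: str | tuple[float, float] = "generic"
                    ) -> DistanceResult:
    """One residue pair scored with the requested estimator
    ("cbeta", "ssm" or "grid_av")."""
    r_cb = cbeta_distance(model, res_i, res_j)
    if estimator == "cbeta":
        r_mp = r_cb
    elif estimator == "ssm":
        r_mp = ssm_distance(model, res_i, res_j, dye)
    elif estimator == "grid_av":
        r_mp = grid_av_distance(model, res_i, res_j, dye, grid_spacing=grid_spacing)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if r_mp is None:
        return DistanceResult((res_i, res_j), r_cb, None, None, None, estimator)
    r_e = mp_to_fret_averaged(r_mp, correction)
    eff = None if dye.forster_radius is None else \
        fret_efficiency(r_e, dye.forster_radius)
    return DistanceResult((res_i, res_j), r_cb, r_mp, r_e, eff, estimator)
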