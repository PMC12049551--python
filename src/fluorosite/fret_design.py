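"""FRET pair scoring and the screen-then-refine selection workflow.

For a single structure the FRET score of a residue pair weights the two
label scores by how close the predicted FRET efficiency is to the point
of maximum sensitivity, E = 0.5:

    FS = sqrt(LS_i·LS_j) · (1 − 2·|1/2 − E_ij|)

For two interconverting structures A and B the FRET difference score
rewards pairs whose efficiency shifts between the conformations:

    FSΔ = sqrt(LS_i^A·LS_i^B) · sqrt(LS_j^A·LS_j^B) · |E^A − E^B|

The standard workflow screens all candidate pairs with the fast
spherical-sector distance estimator and then refines the best
``refine_top`` pairs (default 300) with the grid accessible-volume
simulation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .av_distance import (AccessibleVolume, FluorophoreParams, cbeta_distance,
                          fret_efficiency, grid_accessible_volume,
                          mp_to_fret_averaged, ssm_mean_position,
                          _attachment_point)
from .structure_io import ResidueId, StructureModel

logger = logging.getLogger("fluorosite")

NEGATIVE_CONTROL_FSD = 0.05   # FSΔ below this with high FS in both states


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _check_efficiency(e: float) -> None:
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"FRET efficiency {e} outside [0, 1]")


def sensitivity_factor(e: float) -> float:
    """The efficiency weighting 1 − 2·|1/2 − E|, maximal at E = 0.5."""
    _check_efficiency(e)
    return 1.0 - 2.0 * abs(0.5 - e)


def fret_score(ls_i: float, ls_j: float, e_ij: float) -> float:
    """Single-structure FRET score FS = sqrt(LS_i·LS_j)·(1 − 2|1/2 − E|)."""
    if ls_i < 0 or ls_j < 0:
        raise ValueError("label scores must be >= 0")
    return math.sqrt(ls_i * ls_j) * sensitivity_factor(e_ij)


def fret_delta_score(ls_i_a: float, ls_i_b: float, ls_j_a: float,
                     ls_j_b: float, e_a: float, e_b: float) -> float:
    """Two-structure FRET difference score
    FSΔ = sqrt(LS_i^A LS_i^B)·sqrt(LS_j^A LS_j^B)·|E^A − E^B|."""
    for ls in (ls_i_a, ls_i_b, ls_j_a, ls_j_b):
        if ls < 0:
            raise ValueError("label scores must be >= 0")
    _check_efficiency(e_a)
    _check_efficiency(e_b)
    return (math.sqrt(ls_i_a * ls_i_b) * math.sqrt(ls_j_a * ls_j_b)
            * abs(e_a - e_b))


@dataclass
class FretPairScore:
    res_i: ResidueId
    res_j: ResidueId
    ls_i: dict[str, float]          # per structure key ("A", "B")
    ls_j: dict[str, float]
    efficiency: dict[str, float]
    score: float                    # FS (one structure) or FSΔ (two)
    estimator: str                  # ssm / grid_av
    r_mp: dict[str, float] = field(default_factory=dict)
    r_cbeta: dict[str, float] = field(default_factory=dict)
    screen_score: float | None = None


# ---------------------------------------------------------------------------
# Screen-then-refine workflow
# ---------------------------------------------------------------------------

def _pair_geometry_ssm(model: StructureModel, rids: Sequence[ResidueId],
                       dye: FluorophoreParams) -> dict[ResidueId, np.ndarray]:
    cache = model.atom_coordinates()
    out = {}
    for rid in rids:
        res = model.residue(rid)
        out[rid] = _attachment_point(res) + ssm_mean_position(model, rid, dye, cache)
    return out


def _efficiency_from_mp(r_mp: float, dye: FluorophoreParams,
                        correction) -> float:
    r_e = mp_to_fret_averaged(r_mp, correction)
    return fret_efficiency(r_e, dye.forster_radius)


def screen_pairs(models: StructureModel | Sequence[StructureModel],
                 label_scores: Mapping[ResidueId, float] |
                 Sequence[Mapping[ResidueId, float]],
                 dye: FluorophoreParams,
                 ls_min: float = 1.0, refine_top: int = 300,
                 grid_spacing: float = 1.0,
                 correction: str | tuple[float, float] = "generic",
                 allow_interchain: bool = False) -> list[FretPairScore]:
    """Score all candidate residue pairs; SSM screen, grid-AV refinement.

    One structure → FS ranking; two structures (same residue keys by
    (chain, number, icode) identity) → FSΔ ranking.  Stage 1 keeps pairs
    whose geometric-mean label score is ≥ ``ls_min``; stage 2 re-scores
    the best ``refine_top`` pairs with the grid accessible volume.  By
    default only same-chain pairs are formed.
    """
    if isinstance(models, StructureModel):
        models = [models]
        label_scores = [label_scores]
    models = list(models)
    scores = [dict(s) for s in (label_scores if not isinstance(label_scores, Mapping)
                                else [label_scores])]
    if len(models) not in (1, 2):
        raise ValueError("one or two structures required")
    two = len(models) == 2
    keys = ("A", "B")[: len(models)]
    if dye.forster_radius is None:
        raise ValueError("dye pair needs a Förster radius")

    # residues scorable in every structure
    common = set(scores[0])
    for s in scores[1:]:
        common &= set(s)
    common = {rid for rid in common if all(models[k].residue(rid) is not None
                                           for k in range(len(models)))}
    if two and not common:
        raise ValueError("no overlapping scorable residues between structures")
    rids = sorted(common)
    if len(rids) < 2:
        raise ValueError("need >= 2 scorable residues")

    mp_pos = [_pair_geometry_ssm(m, rids, dye) for m in models]
    cb_pos = [{rid: _attachment_point(m.residue(rid)) for rid in rids}
              for m in models]

    results: list[FretPairScore] = []
    for a in range(len(rids)):
        for b in range(a + 1, len(rids)):
            ri, rj = rids[a], rids[b]
            if not allow_interchain and ri[0] != rj[0]:
                continue
            ls_i = {k: scores[ki][ri] for ki, k in enumerate(keys)}
            ls_j = {k: scores[ki][rj] for ki, k in enumerate(keys)}
            pair_ls = np.exp(np.mean(np.log(np.maximum(
                [v for v in (*ls_i.values(), *ls_j.values())], 1e-300))))
            if pair_ls < ls_min:
                continue
            eff, r_mp, r_cb = {}, {}, {}
            for ki, k in enumerate(keys):
                d = float(np.linalg.norm(mp_pos[ki][ri] - mp_pos[ki][rj]))
                r_mp[k] = d
                r_cb[k] = float(np.linalg.norm(cb_pos[ki][ri] - cb_pos[ki][rj]))
                eff[k] = _efficiency_from_mp(d, dye, correction)
            if two:
                score = fret_delta_score(ls_i["A"], ls_i["B"], ls_j["A"],
                                         ls_j["B"], eff["A"], eff["B"])
            else:
                score = fret_score(ls_i["A"], ls_j["A"], eff["A"])
            results.append(FretPairScore(ri, rj, ls_i, ls_j, eff, score,
                                         "ssm", r_mp, r_cb, screen_score=score))
    if not results:
        logger.warning("screen_pairs: no pair passes ls_min=%s", ls_min)
        return []
    results.sort(key=lambda p: (-p.score, p.res_i, p.res_j))

    if refine_top > 0:
        av_cache: list[dict[ResidueId, AccessibleVolume]] = [{} for _ in models]

        def get_av(ki: int, rid: ResidueId) -> AccessibleVolume:
            if rid not in av_cache[ki]:
                av_cache[ki][rid] = grid_accessible_volume(
                    models[ki], rid, dye, grid_spacing)
            return av_cache[ki][rid]

        for p in results[:refine_top]:
            eff = {}
            ok = True
            for ki, k in enumerate(keys):
                av_i, av_j = get_av(ki, p.res_i), get_av(ki, p.res_j)
                if av_i.empty or av_j.empty:
                    ok = False
                    break
                d = float(np.linalg.norm(av_i.mean_position - av_j.mean_position))
                p.r_mp[k] = d
                eff[k] = _efficiency_from_mp(d, dye, correction)
            if not ok:
                continue
            p.efficiency = eff
            p.estimator = "grid_av"
            if two:
                p.score = fret_delta_score(p.ls_i["A"], p.ls_i["B"], p.ls_j["A"],
                                           p.ls_j["B"], eff["A"], eff["B"])
            else:
                p.score = fret_score(p.ls_i["A"], p.ls_j["A"], eff["A"])
        results.sort(key=lambda p: (-p.score, p.res_i, p.res_j))
    return results


def negative_controls(results: Sequence[FretPairScore],
                      fs_min: float = 0.2,
                      fsd_max: float = NEGATIVE_CONTROL_FSD
                      ) -> list[FretPairScore]:
    """Two-structure pairs with high FS in both states but FSΔ ≈ 0:
    distance near the Förster radius and insensitive to the
    conformational change — useful experimental controls."""
    out = []
    for p in results:
        if set(p.efficiency) != {"A", "B"}:
            continue
        fs_a = fret_score(p.ls_i["A"], p.ls_j["A"], p.efficiency["A"])
        fs_b = fret_score(p.ls_i["B"], p.ls_j["B"], p.efficiency["B"])
        if fs_a >= fs_min and fs_b >= fs_min and p.score <= fsd_max:
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# Matrix export
# ---------------------------------------------------------------------------

MATRIX_MODES = ("cbeta_delta", "ssm_delta", "fs", "fs_delta")


def pair_matrix(results: Sequence[FretPairScore], mode: str) -> pd.DataFrame:
    """Symmetric residue × residue matrix of a pair quantity; diagonal
    empty (NaN).  ``cbeta_delta``/``ssm_delta`` are distance changes
    between structures A and B (plain distances when only A exists)."""
    if mode not in MATRIX_MODES:
        raise ValueError(f"mode must be one of {MATRIX_MODES}")
    rids = sorted({p.res_i for p in results} | {p.res_j for p in results})
    labels = [f"{c}{n}{i}" for c, n, i in rids]
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    pos = {rid: lab for rid, lab in zip(rids, labels)}
    for p in results:
        if mode == "cbeta_delta":
            v = abs(p.r_cbeta.get("A", np.nan) - p.r_cbeta["B"]) \
                if "B" in p.r_cbeta else p.r_cbeta.get("A", np.nan)
        elif mode == "ssm_delta":
            v = abs(p.r_mp.get("A", np.nan) - p.r_mp["B"]) \
                if "B" in p.r_mp else p.r_mp.get("A", np.nan)
        elif mode == "fs":
            v = fret_score(p.ls_i["A"], p.ls_j["A"], p.efficiency["A"])
        else:
            v = p.score if "B" in p.efficiency else np.nan
        li, lj = pos[p.res_i], pos[p.res_j]
        mat.loc[li, lj] = v
        mat.loc[lj, li] = v
    return mat


def pair_matrix_export(results: Sequence[FretPairScore], mode: str,
                       path: str | Path) -> None:
    units = {"cbeta_delta": "Angstrom", "ssm_delta": "Angstrom",
             "fs": "dimensionless", "fs_delta": "dimensionless"}[mode]
    mat = pair_matrix(results, mode)
    with open(path, "w") as fh:
        fh.write(f"# mode={mode} units={units}\n")
        mat.to_csv(fh)


def results_to_frame(results: Sequence[FretPairScore]) -> pd.DataFrame:
    rows = []
    for p in results:
        row = {"chain_i": p.res_i[0], "residue_i": p.res_i[1],
               "chain_j": p.res_j[0], "residue_j": p.res_j[1],
               "score": p.score, "estimator": p.estimator,
               "screen_score": p.screen_score}
        for k in p.efficiency:
            row[f"E_{k}"] = p.efficiency[k]
            row[f"R_MP_{k}"] = p.r_mp.get(k)
            row[f"LS_i_{k}"] = p.ls_i.get(k)
            row[f"LS_j_{k}"] = p.ls_j.get(k)
        rows.append(row)
    return pd.DataFrame(rows)


def summary_json(results: Sequence[FretPairScore], path: str | Path,
                 top_k: int = 20, settings: Mapping | None = None) -> None:
    payload = {
        "settings": dict(settings or {}),
        "n_pairs": len(results),
        "top_pairs": results_to_frame(list(results)[:top_k]).to_dict("records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
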