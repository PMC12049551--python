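"""Combined label score: geometric mean of the selected parameter scores.

For each residue, the raw value of every selected parameter is mapped to
its trained PS bin and the label score is LS = (PS₁·…·PSₙ)^(1/n).  LS is
zero whenever any selected PS is zero, and the default "strict"
missing-value policy flags a residue as failed when a selected parameter
has no value (the "reduce" policy instead averages the available ones
and records how many were used).  The default selection takes one
parameter per category: mean surface distance (SE, #11), conservation
score (CS, #13), DSSP secondary structure (SS, #18) and the native amino
acid at the site (CR, #25).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .residue_parameters import (DEFAULT_SELECTION, REGISTRY_BY_ID,
                                 ParameterTable)
from .structure_io import ResidueId
from .training import ParameterScoreModel, fit_enhancement_slope, log_bin_edges

logger = logging.getLogger("fluorosite")


@dataclass
class LabelScoreResult:
    residue_id: ResidueId
    parameter_scores: dict[int, float] = field(default_factory=dict)
    label_score: float = 0.0
    n_used: int = 0
    failed: bool = False


def compute_label_score(table: ParameterTable, model: ParameterScoreModel,
                        selection: Sequence[int] = DEFAULT_SELECTION,
                        policy: str = "strict",
                        allow_same_category: bool = False
                        ) -> list[LabelScoreResult]:
    """Score every residue of the table with the trained model.

    ``selection`` must draw at most one parameter per category (the
    categories were designed to be mutually weakly correlated; two
    parameters of one category double-count the same information) unless
    ``allow_same_category`` overrides the check.  ``policy`` is "strict"
    (missing parameter → failed residue, LS = 0) or "reduce" (geometric
    mean over the available parameters, n_used recorded).
    """
    if policy not in ("strict", "reduce"):
        raise ValueError(f"unknown missing-value policy {policy!r}")
    cats = [REGISTRY_BY_ID[pid].category for pid in selection if pid in REGISTRY_BY_ID]
    if not allow_same_category and len(set(cats)) != len(cats):
        raise ValueError(f"selection {list(selection)} uses a category twice; "
                         "pass allow_same_category=True to override")
    for pid in selection:
        if pid not in model:
            raise ValueError(f"parameter #{pid} is not trained in this model")

    results: list[LabelScoreResult] = []
    rids = table.residue_ids()
    for row_idx, rid in enumerate(rids):
        ps_values: dict[int, float] = {}
        missing = 0
        for pid in selection:
            value = table.column(pid).iloc[row_idx]
            ps, _ = model[pid].lookup(value)
            if math.isnan(ps):
                missing += 1
            else:
                ps_values[pid] = ps
        if missing and policy == "strict":
            results.append(LabelScoreResult(rid, ps_values, 0.0, 0, failed=True))
            continue
        if not ps_values:
            results.append(LabelScoreResult(rid, ps_values, 0.0, 0, failed=True))
            continue
        vals = np.array(list(ps_values.values()))
        ls = 0.0 if np.any(vals == 0) else float(np.exp(np.mean(np.log(vals))))
        results.append(LabelScoreResult(rid, ps_values, ls, len(vals), False))
    n_failed = sum(r.failed for r in results)
    if n_failed:
        logger.info("compute_label_score: %d/%d residues failed (missing values)",
                    n_failed, len(results))
    return results


def rank_residues(results: Sequence[LabelScoreResult],
                  top_fraction: float | None = None,
                  bottom_fraction: float | None = None
                  ) -> list[LabelScoreResult]:
    """Order residues by descending LS, ties broken by (chain, residue
    number, icode) ascending.

    ``top_fraction`` / ``bottom_fraction`` select the best or worst slice
    of the ranking — the positive/negative-control protocol (e.g. the
    best and worst 10%).
    """
    if not results:
        raise ValueError("no results to rank")
    ordered = sorted(results, key=lambda r: (-r.label_score, r.residue_id))
    if top_fraction is not None:
        return ordered[: int(len(ordered) * top_fraction)]
    if bottom_fraction is not None:
        k = int(len(ordered) * bottom_fraction)
        return ordered[len(ordered) - k:]
    return ordered


def enrichment_ratio(ls_all: np.ndarray, ls_labeled: np.ndarray,
                     log_bins: np.ndarray | None = None,
                     n_boot: int = 0, seed: int = 0) -> dict:
    """Per-bin ratio of the normalized labeled and background LS
    histograms on shared geometric bins, with an optional bootstrap CI.

    Ratios are NaN where the background bin is empty and 0 where only the
    labeled bin is empty.
    """
    ls_all = np.asarray(ls_all, dtype=float)
    ls_labeled = np.asarray(ls_labeled, dtype=float)
    if len(ls_all) == 0 or len(ls_labeled) == 0:
        raise ValueError("both samples must be non-empty")
    edges = log_bin_edges() if log_bins is None else np.asarray(log_bins)

    def norm_hist(x: np.ndarray) -> np.ndarray:
        h, _ = np.histogram(x[x > 0], bins=edges)
        return h / max(h.sum(), 1)

    pa = norm_hist(ls_all)
    pl = norm_hist(ls_labeled)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pa > 0, pl / pa, np.nan)
    out = {"bin_edges": edges, "ratio": ratio, "p_all": pa, "p_labeled": pl}
    if n_boot >= 2:
        rng = np.random.default_rng(seed)
        reps = np.empty((n_boot, len(ratio)))
        for b in range(n_boot):
            res = rng.choice(ls_labeled, size=len(ls_labeled), replace=True)
            pr = norm_hist(res)
            with np.errstate(divide="ignore", invalid="ignore"):
                reps[b] = np.where(pa > 0, pr / pa, np.nan)
        out["ci_lower"] = np.nanpercentile(reps, 2.5, axis=0)
        out["ci_upper"] = np.nanpercentile(reps, 97.5, axis=0)
    return out


def results_to_frame(results: Sequence[LabelScoreResult],
                     table: ParameterTable | None = None) -> pd.DataFrame:
    """Results as a DataFrame (residue key, per-parameter PS, LS, flags)."""
    rows = []
    for r in results:
        row: dict = {"chain": r.residue_id[0], "residue_number": r.residue_id[1],
                     "icode": r.residue_id[2], "label_score": r.label_score,
                     "n_used": r.n_used, "failed": r.failed}
        for pid, v in r.parameter_scores.items():
            row[f"PS_{pid:02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_csv(results: Sequence[LabelScoreResult], path: str | Path,
                      table: ParameterTable | None = None) -> None:
    results_to_frame(results, table).to_csv(path, index=False)
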