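"""Estimation of parameter scores from a database of labeled residues.

The parameter score of a parameter value s is the odds ratio
PS(s) = P(s|l) / P(s): how much more often the value occurs among
successfully labeled residues than among all residues.  The prior P(l)
is deliberately not estimated — published labeling data only reports
successes, so the prior is unknowable from the literature, and it only
rescales the ranking.  Uncertainties come from Poisson counting
statistics propagated through the ratio.  The module also provides the
diagnostics used to choose a parameter set: information measures of a PS
distribution (mean-square deviation from uniformity, Gini coefficient,
bin-number-adapted Shannon entropy), pairwise correlation estimators
matched to the datatypes (Pearson, interclass/ANOVA, Cramer's V), the
joined set correlation, and the t / dynamic-range / enhancement-slope
metrics computed on label-score distributions.
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

from .residue_parameters import (REGISTRY, REGISTRY_BY_ID, ParameterDefinition,
                                 ParameterTable)

logger = logging.getLogger("fluorosite")

MISSING = float("nan")


# ---------------------------------------------------------------------------
# Label database
# ---------------------------------------------------------------------------

MUTATION_TYPES = ("cysteine", "UAA")
ASSAY_TYPES = ("smFRET", "imaging", "bulk-FRET", "other")

MANDATORY_COLUMNS = ("pdb_id", "chain", "residue_number", "mutation_type")


@dataclass(frozen=True)
class LabelRecord:
    pdb_id: str
    chain: str
    residue_number: int
    icode: str = ""
    soluble: bool = True
    stoichiometry: str = "monomer"
    homology_model: bool = False
    mutation_type: str = "cysteine"
    assay_type: str = "other"
    fluorophore: str = ""
    reference: str = ""

    def __post_init__(self) -> None:
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"mutation_type {self.mutation_type!r} not in "
                             f"{MUTATION_TYPES}")
        if self.assay_type not in ASSAY_TYPES:
            raise ValueError(f"assay_type {self.assay_type!r} not in {ASSAY_TYPES}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.pdb_id, self.chain, self.residue_number)


@dataclass
class LabelDatabase:
    records: list[LabelRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[tuple[str, str, int]]:
        return {r.key for r in self.records}

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([r.__dict__ for r in self.records]).to_csv(path, index=False)


def load_label_database(path: str | Path) -> LabelDatabase:
    """Load and validate a label-database CSV (case-insensitive header).

    Duplicate (pdb id, chain, residue number) rows are collapsed with a
    warning; a missing mandatory column is an error naming it.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"label database {path}: missing mandatory column "
                             f"{col!r}")
    records: list[LabelRecord] = []
    seen: set[tuple[str, str, int]] = set()
    dupes = 0
    for row in df.to_dict("records"):
        key = (str(row["pdb_id"]), str(row["chain"]), int(row["residue_number"]))
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        records.append(LabelRecord(
            pdb_id=key[0], chain=key[1], residue_number=key[2],
            icode=str(row.get("icode", "") or ""),
            soluble=bool(row.get("soluble", True)),
            stoichiometry=str(row.get("stoichiometry", "monomer")),
            homology_model=bool(row.get("homology_model", False)),
            mutation_type=str(row.get("mutation_type", "cysteine")),
            assay_type=str(row.get("assay_type", "other")),
            fluorophore=str(row.get("fluorophore", "")),
            reference=str(row.get("reference", ""))))
    if dupes:
        logger.warning("label database %s: collapsed %d duplicate residue rows",
                       path, dupes)
    return LabelDatabase(records=records)


def labeled_mask(table: ParameterTable, database: LabelDatabase) -> np.ndarray:
    """Boolean mask over table rows marking residues present in the database."""
    keys = database.keys()
    df = table.frame
    return np.array([(str(p), str(c), int(n)) in keys
                     for p, c, n in zip(df["pdb_id"], df["chain"],
                                        df["residue_number"])])


# ---------------------------------------------------------------------------
# Parameter score estimation
# ---------------------------------------------------------------------------

@dataclass
class ParameterScoreEntry:
    """Trained, binned PS(s) for one parameter with counting errors."""
    parameter_id: int
    datatype: str                       # numeric / categorical
    bin_edges: np.ndarray | None        # numeric only, len n_bins+1
    categories: tuple | None            # categorical only
    p_s: np.ndarray
    p_sl: np.ndarray
    ps: np.ndarray                      # NaN where P(s)=0 (excluded bin)
    sigma_ps: np.ndarray
    n_all: int
    n_labeled: int
    counts_all: np.ndarray
    counts_labeled: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.p_s)

    def bin_index(self, value) -> int | None:
        """Bin of a value; numeric out-of-range values clamp to edge bins."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if self.datatype == "categorical":
            try:
                return self.categories.index(value)
            except ValueError:
                return None
        idx = int(np.searchsorted(self.bin_edges, value, side="right") - 1)
        if idx < 0:
            logger.debug("value %s below binning range: clamped", value)
            return 0
        if idx >= self.n_bins:
            logger.debug("value %s above binning range: clamped", value)
            return self.n_bins - 1
        return idx

    def lookup(self, value) -> tuple[float, float]:
        """(PS, σ_PS) for a raw parameter value; (NaN, NaN) if missing."""
        idx = self.bin_index(value)
        if idx is None:
            return (MISSING, MISSING)
        return (float(self.ps[idx]), float(self.sigma_ps[idx]))


def _binning_from_definition(d: ParameterDefinition):
    if d.datatype == "numeric":
        lo, hi, nb = d.binning
        return ("numeric", np.linspace(float(lo), float(hi), int(nb) + 1))
    return ("categorical", tuple(d.binning))


def estimate_parameter_score(all_values: Sequence, labeled_mask: np.ndarray,
                             binning, parameter_id: int = 0,
                             datatype: str | None = None) -> ParameterScoreEntry:
    """Estimate PS = P(s|l)/P(s) on a shared binning with counting errors.

    ``binning``: either a ParameterDefinition, ("numeric", edges) or
    ("categorical", labels).  Bins with P(s)=0 are excluded (PS = NaN, not
    infinite); bins with P(s|l)=0 give PS = 0 with the one-count upper
    bound as error.  Errors follow Poisson statistics:
    σ_sl = sqrt(P(s|l)/n_l), σ_s = sqrt(P(s)/n), propagated into
    σ_PS = PS·sqrt(σ_sl²/P(s|l)² + σ_s²/P(s)²).
    """
    if isinstance(binning, ParameterDefinition):
        parameter_id = binning.id
        datatype = binning.datatype
        kind, spec = _binning_from_definition(binning)
    else:
        kind, spec = binning
        datatype = datatype or kind

    vals = pd.Series(list(all_values))
    mask = np.asarray(labeled_mask, dtype=bool)
    if len(vals) != len(mask):
        raise ValueError("labeled_mask length mismatch")

    if kind == "numeric":
        edges = np.asarray(spec, dtype=float)
        nb = len(edges) - 1
        x = pd.to_numeric(vals, errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(x)
        xi = np.clip(np.searchsorted(edges, x[ok], side="right") - 1, 0, nb - 1)
        counts_all = np.bincount(xi, minlength=nb).astype(float)
        xl = x[ok & mask]
        xli = np.clip(np.searchsorted(edges, xl, side="right") - 1, 0, nb - 1)
        counts_lab = np.bincount(xli, minlength=nb).astype(float)
        categories = None
    else:
        categories = tuple(spec)
        nb = len(categories)
        idx = {c: i for i, c in enumerate(categories)}
        counts_all = np.zeros(nb)
        counts_lab = np.zeros(nb)
        for v, m in zip(vals, mask):
            if v in idx:
                counts_all[idx[v]] += 1
                if m:
                    counts_lab[idx[v]] += 1
        edges = None

    n_all = counts_all.sum()
    n_lab = counts_lab.sum()
    if n_lab == 0:
        raise ValueError("empty labeled set (no non-missing labeled values)")

    p_s = counts_all / n_all
    p_sl = counts_lab / n_lab
    ps = np.full(nb, np.nan)
    sigma = np.full(nb, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        nonzero = p_s > 0
        ps[nonzero] = p_sl[nonzero] / p_s[nonzero]
        sig_s = np.sqrt(p_s / n_all)
        sig_sl = np.sqrt(p_sl / n_lab)
        both = nonzero & (p_sl > 0)
        sigma[both] = ps[both] * np.sqrt((sig_sl[both] / p_sl[both]) ** 2
                                         + (sig_s[both] / p_s[both]) ** 2)
        # P(s|l)=0: PS=0, error from a one-count upper bound
        zero_lab = nonzero & (p_sl == 0)
        sigma[zero_lab] = (1.0 / n_lab) / p_s[zero_lab]
    return ParameterScoreEntry(
        parameter_id=parameter_id, datatype=datatype,
        bin_edges=edges, categories=categories,
        p_s=p_s, p_sl=p_sl, ps=ps, sigma_ps=sigma,
        n_all=int(n_all), n_labeled=int(n_lab),
        counts_all=counts_all, counts_labeled=counts_lab)


@dataclass
class ParameterScoreModel:
    """Trained PS entries keyed by parameter id, JSON-serializable."""
    entries: dict[int, ParameterScoreEntry] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __contains__(self, pid: int) -> bool:
        return pid in self.entries

    def __getitem__(self, pid: int) -> ParameterScoreEntry:
        return self.entries[pid]

    def to_json(self, path: str | Path) -> None:
        payload = {"metadata": self.metadata, "entries": {}}
        for pid, e in self.entries.items():
            payload["entries"][str(pid)] = {
                "parameter_id": e.parameter_id, "datatype": e.datatype,
                "bin_edges": None if e.bin_edges is None else list(e.bin_edges),
                "categories": None if e.categories is None else list(e.categories),
                "p_s": list(e.p_s), "p_sl": list(e.p_sl),
                "ps": [None if not math.isfinite(v) else v for v in e.ps],
                "sigma_ps": [None if not math.isfinite(v) else v for v in e.sigma_ps],
                "n_all": e.n_all, "n_labeled": e.n_labeled,
                "counts_all": list(e.counts_all),
                "counts_labeled": list(e.counts_labeled)}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ParameterScoreModel":
        payload = json.loads(Path(path).read_text())
        model = cls(metadata=payload.get("metadata", {}))
        for pid, e in payload["entries"].items():
            model.entries[int(pid)] = ParameterScoreEntry(
                parameter_id=e["parameter_id"], datatype=e["datatype"],
                bin_edges=None if e["bin_edges"] is None else np.array(e["bin_edges"]),
                categories=None if e["categories"] is None else tuple(e["categories"]),
                p_s=np.array(e["p_s"]), p_sl=np.array(e["p_sl"]),
                ps=np.array([np.nan if v is None else v for v in e["ps"]]),
                sigma_ps=np.array([np.nan if v is None else v for v in e["sigma_ps"]]),
                n_all=e["n_all"], n_labeled=e["n_labeled"],
                counts_all=np.array(e["counts_all"]),
                counts_labeled=np.array(e["counts_labeled"]))
        return model


def train_parameter_scores(table: ParameterTable, database: LabelDatabase,
                           parameter_ids: Sequence[int] | None = None,
                           min_coverage: float = 0.5) -> ParameterScoreModel:
    """Train PS entries for the given parameters (default: whole registry).

    The database must cover the table's residues: fewer than
    ``min_coverage`` matched records is an error.
    """
    mask = labeled_mask(table, database)
    coverage = mask.sum() / max(len(database), 1)
    if coverage < min_coverage:
        unmatched = sorted(database.keys())[:10]
        raise ValueError(f"only {mask.sum()}/{len(database)} database records "
                         f"match the parameter tables; first keys: {unmatched}")
    ids = list(parameter_ids) if parameter_ids is not None else \
        [d.id for d in table.registry]
    model = ParameterScoreModel(metadata={
        "n_residues": int(len(table.frame)), "n_labeled": int(mask.sum()),
        "coverage": float(coverage), "parameters": ids})
    for pid in ids:
        d = REGISTRY_BY_ID[pid]
        col = table.column(pid)
        try:
            model.entries[pid] = estimate_parameter_score(col, mask, d)
        except ValueError as exc:
            logger.warning("parameter #%d not trained: %s", pid, exc)
    return model


# ---------------------------------------------------------------------------
# Information measures of a PS distribution
# ---------------------------------------------------------------------------

def information_measures(ps: "ParameterScoreEntry | np.ndarray"
                         ) -> tuple[float, float, float]:
    """(MSD, Gini, adapted Shannon entropy H) of a PS distribution.

    MSD is the mean-square deviation of PS from 1 (the uninformative
    value); Gini measures concentration of the PS mass; H normalizes the
    Shannon entropy of the PS distribution by ln(n) so that H = 1 for a
    flat distribution and H = 0 for a one-hot one.  Missing (NaN) bins
    are excluded.
    """
    x = ps.ps if isinstance(ps, ParameterScoreEntry) else np.asarray(ps, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise ValueError("need >= 2 non-missing PS bins")
    msd = float(np.mean((x - 1.0) ** 2))
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero PS distribution")
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    gini = float(np.sum((2 * i - n - 1) * xs) / (n * total))
    p = x / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum() / np.log(n))
    return msd, gini, h


# ---------------------------------------------------------------------------
# Correlation estimators
# ---------------------------------------------------------------------------

def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt((xm ** 2).sum() * (ym ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((xm * ym).sum() / denom)


def interclass_correlation(categories: Sequence, values: np.ndarray) -> float:
    """One-way intraclass correlation ICC(1) between a categorical grouping
    and a numeric variable: r = (MST − MSE) / (MST + (n0 − 1)·MSE) with the
    between-group mean square MST, within-group mean square MSE and the
    average group size n0 = (n − Σn_i²/n)/(k − 1)."""
    values = np.asarray(values, dtype=float)
    cats = pd.Series(list(categories))
    groups = [values[(cats == c).to_numpy()] for c in cats.unique()]
    k = len(groups)
    n = len(values)
    if k < 2:
        logger.warning("interclass correlation undefined for a single category")
        return float("nan")
    grand = values.mean()
    mst = sum(len(g) * (g.mean() - grand) ** 2 for g in groups) / (k - 1)
    mse_num = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if n - k <= 0:
        return float("nan")
    mse = mse_num / (n - k)
    n0 = (n - sum(len(g) ** 2 for g in groups) / n) / (k - 1)
    denom = mst + (n0 - 1) * mse
    if denom == 0:
        return float("nan")
    return float((mst - mse) / denom)


def cramers_v(x: Sequence, y: Sequence) -> float:
    """Cramer's V between two categorical variables: sqrt(χ²/(n·(min(k,l)−1)))."""
    tab = pd.crosstab(pd.Series(list(x)), pd.Series(list(y))).to_numpy(dtype=float)
    k, l = tab.shape
    if min(k, l) < 2:
        logger.warning("Cramer's V undefined: a column has a single category")
        return float("nan")
    n = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(expected > 0,
                                  (tab - expected) ** 2 / expected, 0.0))
    return float(math.sqrt(chi2 / (n * (min(k, l) - 1))))


def parameter_correlation(x: Sequence, y: Sequence,
                          x_type: str = "numeric", y_type: str = "numeric"
                          ) -> tuple[float, str]:
    """Correlation between two parameter columns, estimator auto-selected
    by datatype: Pearson (numeric-numeric), interclass (categorical-
    numeric), Cramer's V (categorical-categorical).  Rows with missing
    values in either column are dropped; < 3 complete pairs is an error.
    """
    xs = pd.Series(list(x))
    ys = pd.Series(list(y))
    ok = xs.notna() & ys.notna()
    xs, ys = xs[ok], ys[ok]
    if len(xs) < 3:
        raise ValueError("need >= 3 paired non-missing observations")
    if x_type == "numeric" and y_type == "numeric":
        return pearson_correlation(xs.to_numpy(float), ys.to_numpy(float)), "pearson"
    if x_type == "categorical" and y_type == "categorical":
        return cramers_v(xs, ys), "cramers_v"
    if x_type == "categorical":
        return interclass_correlation(xs, ys.to_numpy(float)), "interclass"
    return interclass_correlation(ys, xs.to_numpy(float)), "interclass"


def set_correlation(parameter_ids: Sequence[int],
                    pairwise_r: Mapping[tuple[int, int], float],
                    squared: bool = True) -> float:
    """Joined correlation of a parameter set over its unordered pairs.

    Default is the 2-norm sqrt(Σ r_ij²); ``squared=False`` gives the
    literal un-squared radicand variant sqrt(Σ r_ij).
    """
    ids = list(parameter_ids)
    total = 0.0
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            key = (ids[a], ids[b])
            r = pairwise_r.get(key, pairwise_r.get(key[::-1]))
            if r is None or (isinstance(r, float) and math.isnan(r)):
                raise ValueError(f"missing pairwise correlation for {key}")
            total += r ** 2 if squared else r
    return math.sqrt(total)


# ---------------------------------------------------------------------------
# Parameter-set selection metrics on label scores
# ---------------------------------------------------------------------------

LOG_BIN_BASE = 1.5
LOG_BIN_RANGE = range(-12, 12)  # bin intervals [1.5^i, 1.5^(i+1))


def log_bin_edges() -> np.ndarray:
    return LOG_BIN_BASE ** np.arange(LOG_BIN_RANGE.start, LOG_BIN_RANGE.stop + 1,
                                     dtype=float)


def selection_metrics(ls_all: np.ndarray, ls_labeled: np.ndarray
                      ) -> tuple[float, float, float]:
    """(t value, dynamic range, enhancement slope m) of a label-score set.

    t compares the mean LS of labeled vs all residues with Welch-style
    SEM combination; dynamic range is the SD of ln(LS) over all residues
    (zeros excluded from the log statistics, counted); m is the slope of
    the log-binned ln(P(LS|l)/P(LS)) vs ln(LS) least-squares fit.
    """
    ls_all = np.asarray(ls_all, dtype=float)
    ls_labeled = np.asarray(ls_labeled, dtype=float)
    if len(ls_all) == 0 or len(ls_labeled) == 0:
        raise ValueError("both score sets must be non-empty")

    mu_l, mu_all = ls_labeled.mean(), ls_all.mean()
    sem_l = ls_labeled.std(ddof=1) / math.sqrt(len(ls_labeled)) \
        if len(ls_labeled) > 1 else 0.0
    sem_all = ls_all.std(ddof=1) / math.sqrt(len(ls_all)) if len(ls_all) > 1 else 0.0
    denom = math.sqrt(sem_l ** 2 + sem_all ** 2)
    t = 0.0 if denom == 0 else float((mu_l - mu_all) / denom)

    pos_all = ls_all[ls_all > 0]
    n_zero = int((ls_all <= 0).sum())
    if n_zero:
        logger.info("selection_metrics: %d zero scores excluded from log stats",
                    n_zero)
    dynamic_range = float(np.std(np.log(pos_all))) if len(pos_all) else 0.0

    try:
        m, _ = fit_enhancement_slope(ls_all, ls_labeled)
    except ValueError as exc:
        logger.warning("enhancement slope not fit: %s", exc)
        m = float("nan")
    return t, dynamic_range, m


def fit_enhancement_slope(ls_all: np.ndarray, ls_labeled: np.ndarray
                          ) -> tuple[float, float]:
    """Least-squares fit of ln(P(LS|l)/P(LS)) = m·ln(LS) + ln(c) on
    geometric bins [1.5^i, 1.5^(i+1)); empty bins are skipped.  Returns
    (m, c)."""
    edges = log_bin_edges()
    a = np.asarray(ls_all, dtype=float)
    b = np.asarray(ls_labeled, dtype=float)
    ha, _ = np.histogram(a[a > 0], bins=edges)
    hb, _ = np.histogram(b[b > 0], bins=edges)
    pa = ha / max(ha.sum(), 1)
    pb = hb / max(hb.sum(), 1)
    good = (ha > 0) & (hb > 0)
    if good.sum() < 2:
        raise ValueError("fewer than 2 populated log bins for the slope fit")
    centers = np.sqrt(edges[:-1] * edges[1:])
    x = np.log(centers[good])
    y = np.log(pb[good] / pa[good])
    m, logc = np.polyfit(x, y, 1)
    return float(m), float(math.exp(logc))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_scores(database: LabelDatabase, table: ParameterTable,
                     n_boot: int, seed: int,
                     selection: Sequence[int] | None = None
                     ) -> dict:
    """Residue-level bootstrap of the labeled set.

    Each replicate resamples the labeled records with replacement,
    retrains the PS entries and recomputes the labeled-residue LS
    histogram on the geometric log bins.  Returns the per-bin
    2.5/97.5-percentile envelope plus the point estimate.
    """
    from .label_score import compute_label_score

    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    selection = tuple(selection or (11, 13, 18, 25))
    rng = np.random.default_rng(seed)
    edges = log_bin_edges()

    def labeled_hist(db: LabelDatabase) -> np.ndarray:
        model = train_parameter_scores(table, db, parameter_ids=selection,
                                       min_coverage=0.0)
        results = compute_label_score(table, model, selection, policy="reduce")
        mask = labeled_mask(table, db)
        ls = np.array([r.label_score for r in results])[mask]
        h, _ = np.histogram(ls[ls > 0], bins=edges)
        return h / max(h.sum(), 1)

    point = labeled_hist(database)
    reps = np.empty((n_boot, len(point)))
    for b in range(n_boot):
        idx = rng.integers(0, len(database), len(database))
        reps[b] = labeled_hist(LabelDatabase([database.records[i] for i in idx]))
    lo = np.percentile(reps, 2.5, axis=0, method="lower")
    hi = np.percentile(reps, 97.5, axis=0, method="higher")
    return {"bin_edges": edges, "point": point, "lower": lo, "upper": hi,
            "replicates": reps}


# ---------------------------------------------------------------------------
# ROC validation
# ---------------------------------------------------------------------------

def roc_curve(scores_all: np.ndarray, labeled: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over LS thresholds, labeled residues as positives; AUC by
    trapezoid."""
    from sklearn.metrics import roc_curve as _roc, auc as _auc

    labeled = np.asarray(labeled, dtype=bool)
    if labeled.all() or not labeled.any():
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, _ = _roc(labeled.astype(int), np.asarray(scores_all, dtype=float))
    return fpr, tpr, float(_auc(fpr, tpr))
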