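import math

import numpy as np
import pytest

from fluorosite import (estimate_parameter_score, information_measures,
                        load_label_database, parameter_correlation,
                        roc_curve, selection_metrics, set_correlation,
                        bootstrap_scores, labeled_mask)
from fluorosite.training import (LabelDatabase, LabelRecord,
                                 ParameterScoreModel, cramers_v,
                                 fit_enhancement_slope,
                                 interclass_correlation, log_bin_edges)

DB_CSV = """\
pdb_id,chain,residue_number,mutation_type,assay_type,fluorophore,reference
1ABC,A,17,cysteine,smFRET,Alexa647,doi:x
1ABC,A,52,cysteine,imaging,Cy3,doi:x
2DEF,B,101,UAA,bulk-FRET,ATTO643,doi:y
"""


class TestLabelDatabase:
    def test_three_row_fixture(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text(DB_CSV)
        db = load_label_database(p)
        assert len(db) == 3
        assert db.records[2].mutation_type == "UAA"

    def test_duplicate_collapsed_with_warning(self, tmp_path, caplog):
        p = tmp_path / "db.csv"
        p.write_text(DB_CSV + "1ABC,A,17,cysteine,smFRET,Alexa555,doi:z\n")
        with caplog.at_level("WARNING", logger="fluorosite"):
            db = load_label_database(p)
        assert len(db) == 3
        assert "duplicate" in caplog.text

    def test_missing_mandatory_column_named(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text("pdb_id,chain,fluorophore\n1ABC,A,Cy3\n")
        with pytest.raises(ValueError, match="residue_number"):
            load_label_database(p)

    def test_case_insensitive_header(self, tmp_path):
        p = tmp_path / "db.csv"
        p.write_text(DB_CSV.replace("pdb_id", "PDB_ID"))
        assert len(load_label_database(p)) == 3


class TestParameterScore:
    def test_null_case_ps_is_one_within_errors(self, rng):
        """Labeled values drawn identically to the background: every PS is
        compatible with 1 within 2σ."""
        values = rng.uniform(0, 1, 20000)
        mask = np.zeros(20000, dtype=bool)
        mask[rng.choice(20000, 2000, replace=False)] = True
        entry = estimate_parameter_score(
            values, mask, ("numeric", np.linspace(0, 1, 6)))
        for ps, sig in zip(entry.ps, entry.sigma_ps):
            assert abs(ps - 1.0) < 2 * sig

    def test_two_bin_closed_form(self):
        """Background uniform over 2 bins, labeled all in bin 1 → PS=(2,0)."""
        values = np.array([0.25] * 50 + [0.75] * 50)
        mask = np.array([True] * 10 + [False] * 90)
        entry = estimate_parameter_score(values, mask,
                                         ("numeric", np.array([0, 0.5, 1.0])))
        assert entry.ps[0] == pytest.approx(2.0)
        assert entry.ps[1] == 0.0
        assert entry.sigma_ps[1] > 0  # one-count upper bound

    def test_planted_enrichment_recovered(self, rng):
        """×3 enrichment planted in one bin is recovered within 2σ at n=10⁴."""
        n = 10000
        values = rng.uniform(0, 1, n)
        in_bin = values < 0.2
        weights = np.where(in_bin, 3.0, 1.0)
        idx = rng.choice(n, 1500, replace=False,
                         p=weights / weights.sum())
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        entry = estimate_parameter_score(
            values, mask, ("numeric", np.linspace(0, 1, 6)))
        expected = 3.0 / (0.2 * 3.0 + 0.8)  # renormalized odds ratio
        assert abs(entry.ps[0] - expected) < 2 * entry.sigma_ps[0]

    def test_probability_normalization_and_scale_freedom(self, rng):
        values = np.concatenate([rng.normal(0, 1, 3000),
                                 rng.normal(1, 1, 500)])
        mask = np.concatenate([np.zeros(3000, bool), np.ones(500, bool)])
        binning = ("numeric", np.linspace(-4, 5, 10))
        e1 = estimate_parameter_score(values, mask, binning)
        assert e1.p_s.sum() == pytest.approx(1.0, abs=1e-9)
        assert e1.p_sl.sum() == pytest.approx(1.0, abs=1e-9)
        # k-fold duplication leaves PS unchanged, shrinks σ by sqrt(k)
        k = 4
        e2 = estimate_parameter_score(np.tile(values, k), np.tile(mask, k),
                                      binning)
        np.testing.assert_allclose(e2.ps, e1.ps, equal_nan=True)
        finite = np.isfinite(e1.sigma_ps) & (e1.p_sl > 0)
        np.testing.assert_allclose(e2.sigma_ps[finite],
                                   e1.sigma_ps[finite] / math.sqrt(k))

    def test_categorical_counting(self):
        values = ["H"] * 60 + ["E"] * 30 + ["C"] * 10
        mask = np.array([True] * 30 + [False] * 70)
        entry = estimate_parameter_score(values, mask,
                                         ("categorical", ("H", "E", "C")))
        assert entry.ps[0] == pytest.approx(1.0 / 0.6)
        assert entry.ps[1] == 0.0

    def test_empty_labeled_set_errors(self):
        with pytest.raises(ValueError, match="labeled"):
            estimate_parameter_score([1.0, 2.0], np.array([False, False]),
                                     ("numeric", np.array([0.0, 1.5, 3.0])))

    def test_json_round_trip(self, null_model, tmp_path):
        p = tmp_path / "model.json"
        null_model.to_json(p)
        back = ParameterScoreModel.from_json(p)
        for pid, e in null_model.entries.items():
            np.testing.assert_allclose(back[pid].ps, e.ps, equal_nan=True)
            assert back[pid].n_labeled == e.n_labeled


class TestInformationMeasures:
    def test_equal_distribution(self):
        msd, gini, h = information_measures(np.ones(4))
        assert msd == 0.0
        assert gini == 0.0
        assert h == pytest.approx(1.0)

    def test_one_hot_limit(self):
        msd, gini, h = information_measures(np.array([2.0, 0.0]))
        assert h == 0.0
        assert msd == pytest.approx(((2 - 1) ** 2 + 1) / 2)

    def test_gini_matches_mean_absolute_difference(self, rng):
        """The sorted-rank Gini equals the brute-force pairwise formula
        G = Σ|x_i − x_j| / (2 n² mean)."""
        for _ in range(20):
            x = rng.uniform(0, 5, size=rng.integers(3, 30))
            _, gini, _ = information_measures(x)
            brute = np.abs(x[:, None] - x[None, :]).sum() / (2 * len(x) ** 2
                                                             * x.mean())
            assert gini == pytest.approx(brute, abs=1e-12)

    def test_too_few_bins_errors(self):
        with pytest.raises(ValueError):
            information_measures(np.array([1.0]))


from hypothesis import given, settings, strategies as st


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.01, max_value=50.0),
                min_size=2, max_size=25))
def test_information_measures_invariants(ps):
    """For any positive PS vector: MSD ≥ 0, Gini ∈ [0, 1), H ∈ [0, 1], and
    the rank-based Gini equals the pairwise mean-absolute-difference
    form."""
    x = np.array(ps)
    msd, gini, h = information_measures(x)
    assert msd >= 0.0
    assert 0.0 <= gini < 1.0
    assert -1e-12 <= h <= 1.0 + 1e-12
    brute = np.abs(x[:, None] - x[None, :]).sum() / (2 * len(x) ** 2 * x.mean())
    assert gini == pytest.approx(brute, abs=1e-9)


class TestCorrelations:
    def test_linear_relation_pearson_one(self):
        x = np.arange(10.0)
        r, est = parameter_correlation(x, 2 * x + 1)
        assert est == "pearson"
        assert r == pytest.approx(1.0)

    def test_perfect_association_cramers_v_one(self):
        x = ["a"] * 20 + ["b"] * 20
        y = ["u"] * 20 + ["v"] * 20
        r, est = parameter_correlation(x, y, "categorical", "categorical")
        assert est == "cramers_v"
        assert r == pytest.approx(1.0)

    def test_independent_table_cramers_v_zero(self):
        # 3×4 table with exactly proportional counts → χ² = 0
        x, y = [], []
        for i, ni in enumerate([12, 24, 36]):
            for j, w in enumerate([1, 2, 3, 6]):
                x += [f"c{i}"] * (ni * w // 12)
                y += [f"d{j}"] * (ni * w // 12)
        assert cramers_v(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_interclass_matches_hand_computation(self):
        """Two groups, hand-evaluated MST/MSE/n0 chain."""
        cats = ["a", "a", "a", "b", "b", "b"]
        vals = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
        # group means 2 and 8, grand mean 5:
        # MST = (3*(2-5)^2 + 3*(8-5)^2)/(2-1) = 54
        # MSE = ((1+0+1)+(1+0+1))/(6-2) = 1
        # n0  = (6 - (9+9)/6)/(2-1) = 3
        # r = (54-1)/(54+2*1) = 53/56
        r = interclass_correlation(cats, vals)
        assert r == pytest.approx(53 / 56)

    def test_single_category_flagged_nan(self):
        r, est = parameter_correlation(["a"] * 5, ["u", "u", "v", "v", "u"],
                                       "categorical", "categorical")
        assert math.isnan(r)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            parameter_correlation([1.0, 2.0], [1.0, 2.0])


class TestSetCorrelation:
    def test_all_zero(self):
        r = set_correlation([1, 2, 3, 4], {(i, j): 0.0 for i in range(1, 5)
                                           for j in range(i + 1, 5)})
        assert r == 0.0

    def test_uniform_half_closed_form(self):
        pw = {(i, j): 0.5 for i in range(1, 5) for j in range(i + 1, 5)}
        assert set_correlation([1, 2, 3, 4], pw) == \
            pytest.approx(math.sqrt(6 * 0.25))
        # literal (un-squared) variant
        assert set_correlation([1, 2, 3, 4], pw, squared=False) == \
            pytest.approx(math.sqrt(3.0))

    def test_permutation_invariance(self, rng):
        ids = [11, 13, 18, 25]
        pw = {}
        for a in range(4):
            for b in range(a + 1, 4):
                pw[(ids[a], ids[b])] = float(rng.uniform(-1, 1))
        r1 = set_correlation(ids, pw)
        r2 = set_correlation(ids[::-1], pw)
        assert r1 == pytest.approx(r2)

    def test_missing_pair_errors(self):
        with pytest.raises(ValueError, match="missing"):
            set_correlation([1, 2, 3], {(1, 2): 0.1, (1, 3): 0.2})


class TestSelectionMetrics:
    def test_identical_samples_t_zero(self, rng):
        ls = rng.lognormal(0, 0.5, 500)
        t, _, _ = selection_metrics(ls, ls)
        assert t == pytest.approx(0.0)

    def test_all_equal_zero_dynamic_range(self):
        ls = np.full(100, 1.3)
        t, dr, m = selection_metrics(ls, ls)
        assert dr == 0.0
        assert math.isnan(m)  # single populated log bin: slope unfit
        with pytest.raises(ValueError, match="populated"):
            fit_enhancement_slope(ls, ls)

    def test_dynamic_range_is_log_sd(self, rng):
        ls = rng.lognormal(0, 0.7, 5000)
        _, dr, _ = selection_metrics(ls, ls)
        assert dr == pytest.approx(0.7, rel=0.05)

    def test_planted_slope_recovered(self, rng):
        """Labeled residues re-weighted ∝ LS² give enhancement slope ≈ 2."""
        ls_all = rng.lognormal(0, 0.7, 100000)
        w = ls_all ** 2
        labeled = rng.choice(ls_all, 20000, p=w / w.sum())
        m, _ = fit_enhancement_slope(ls_all, labeled)
        assert m == pytest.approx(2.0, abs=0.3)


class TestBootstrap:
    def test_seed_determinism(self, null_database, globule_table):
        a = bootstrap_scores(null_database, globule_table, n_boot=5, seed=9)
        b = bootstrap_scores(null_database, globule_table, n_boot=5, seed=9)
        np.testing.assert_array_equal(a["replicates"], b["replicates"])

    def test_two_replicates_envelope_is_min_max(self, null_database,
                                                globule_table):
        out = bootstrap_scores(null_database, globule_table, n_boot=2, seed=1)
        np.testing.assert_array_equal(out["lower"],
                                      out["replicates"].min(axis=0))
        np.testing.assert_array_equal(out["upper"],
                                      out["replicates"].max(axis=0))

    def test_envelope_covers_point_estimate(self, null_database,
                                            globule_table):
        out = bootstrap_scores(null_database, globule_table, n_boot=60, seed=2)
        occupied = out["point"] > 0
        inside = (out["point"] >= out["lower"]) & \
            (out["point"] <= out["upper"])
        assert inside[occupied].mean() >= 0.95


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.9, 1.0])
        labels = np.array([False, False, True, True])
        _, _, auc = roc_curve(scores, labels)
        assert auc == 1.0

    def test_null_scores_auc_half(self, rng):
        scores = rng.uniform(0, 1, 10000)
        labels = rng.random(10000) < 0.5
        _, _, auc = roc_curve(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_sign_reversal_complements_auc(self, rng):
        scores = rng.normal(size=500) + np.where(rng.random(500) < 0.3, 1, 0)
        labels = rng.random(500) < 0.5
        _, _, auc = roc_curve(scores, labels)
        _, _, auc_rev = roc_curve(-scores, labels)
        assert auc_rev == pytest.approx(1 - auc)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([1.0, 2.0]), np.array([True, True]))
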