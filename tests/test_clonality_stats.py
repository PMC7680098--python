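import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

import radclone as rc
from conftest import make_sheet
from oracles import brute_force_min_within_between, exact_rank_sum_p


def dist_matrix(values, labels):
    return rc.DistanceMatrix(sample_ids=labels, values=np.asarray(values, dtype=float))


class TestMinWithinBetween:
    def test_counts_for_fifteen_by_three_design(self):
        rng = np.random.default_rng(0)
        labels = [f"FC{c:02d}-{k}" for c in range(15) for k in range(3)]
        circle_of = {s: s.split("-")[0] for s in labels}
        d = dist_matrix(squareform(pdist(rng.random((45, 5)))), labels)
        sheet = make_sheet(circle_of)
        within, between = rc.min_within_between(d, sheet)
        assert len(within) == 15
        assert len(between) == 105  # C(15, 2)

    def test_specific_minimum_recovered(self):
        labels = ["a1", "a2", "b1", "b2"]
        vals = np.ones((4, 4)) - np.eye(4)
        vals[0, 1] = vals[1, 0] = 0.2
        d = dist_matrix(vals, labels)
        sheet = make_sheet({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        within, between = rc.min_within_between(d, sheet)
        assert within["A"] == pytest.approx(0.2)
        assert within["B"] == pytest.approx(1.0)
        assert between[("A", "B")] == pytest.approx(1.0)

    def test_agreement_with_exhaustive_pair_scan(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            circles = [f"C{i}" for i in range(6)]
            sample_circles = [c for c in circles for _ in range(int(rng.integers(2, 5)))]
            labels = [f"{c}-{i}" for i, c in enumerate(sample_circles)]
            n = len(labels)
            d = dist_matrix(squareform(pdist(rng.random((n, 4)))), labels)
            sheet = make_sheet(dict(zip(labels, sample_circles)))
            within, between = rc.min_within_between(d, sheet)
            exp_w, exp_b = brute_force_min_within_between(d.values, sample_circles)
            assert within == pytest.approx(exp_w)
            assert between == pytest.approx(exp_b)

    def test_singleton_circle_excluded_from_within(self):
        labels = ["a1", "a2", "b1"]
        d = dist_matrix(squareform(pdist([[0.0], [1.0], [2.0]])), labels)
        sheet = make_sheet({"a1": "A", "a2": "A", "b1": "B"})
        within, between = rc.min_within_between(d, sheet)
        assert set(within) == {"A"}
        assert set(between) == {("A", "B")}

    def test_invariant_to_relabeling_within_circles(self):
        rng = np.random.default_rng(9)
        vals = squareform(pdist(rng.random((6, 3))))
        labels = [f"s{i}" for i in range(6)]
        circles = ["A", "A", "A", "B", "B", "B"]
        d1 = dist_matrix(vals, labels)
        sheet1 = make_sheet(dict(zip(labels, circles)))
        # swap the two A-labels s0 and s2 (same partition, different names)
        perm = [2, 1, 0, 3, 4, 5]
        d2 = dist_matrix(vals[np.ix_(perm, perm)], [labels[i] for i in perm])
        sheet2 = make_sheet(dict(zip([labels[i] for i in perm], circles)))
        w1, b1 = rc.min_within_between(d1, sheet1)
        w2, b2 = rc.min_within_between(d2, sheet2)
        assert w1 == pytest.approx(w2)
        assert b1 == pytest.approx(b2)


class TestWilcoxonRankSum:
    def test_complete_separation_exact_p(self):
        res = rc.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res["statistic"] == 0.0
        assert res["p_value"] == pytest.approx(0.1)  # 2/C(6,3)=2/20
        assert res["method"] == "exact"

    def test_identical_multisets_give_p_one(self):
        res = rc.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["p_value"] == pytest.approx(1.0)

    def test_degenerate_constant_data_warns(self):
        with pytest.warns(UserWarning):
            res = rc.wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert res["p_value"] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rc.wilcoxon_rank_sum([], [1.0])

    def test_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            m = int(rng.integers(3, 8))
            x = rng.random(n) * 10
            y = rng.random(m) * 10 + rng.normal()
            got = rc.wilcoxon_rank_sum(x, y)
            assert got["method"] == "exact"
            assert got["p_value"] == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_large_samples_use_tie_corrected_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 40).astype(float)
        res = rc.wilcoxon_rank_sum(x, y)
        assert res["method"] == "asymptotic"
        assert 0 <= res["p_value"] <= 1

    def test_type_one_error_calibrated_on_true_null(self):
        """At the study sizes (15 vs 105), iid same-distribution samples
        reject at ~alpha."""
        rng = np.random.default_rng(77)
        alpha = 0.05
        n_rep = 400
        rejections = sum(
            rc.wilcoxon_rank_sum(rng.random(15), rng.random(105))["p_value"] < alpha
            for _ in range(n_rep)
        )
        from scipy import stats

        lo, hi = stats.binom.interval(0.999, n_rep, alpha)
        assert lo <= rejections <= hi


class TestDistanceDecay:
    def _sheet_with_centers(self, centers):
        circle_of = {}
        for i, c in enumerate(centers):
            circle_of[f"c{i}a"] = f"C{i}"
            circle_of[f"c{i}b"] = f"C{i}"
        return make_sheet(circle_of, {f"C{i}": xy for i, xy in enumerate(centers)})

    def test_exact_line_recovered(self):
        centers = [(0, 0), (3, 4), (6, 8), (9, 12)]  # pair distances 5,10,15,...
        sheet = self._sheet_with_centers(centers)
        centers_map = sheet.centers()
        between = {}
        for i in range(4):
            for j in range(i + 1, 4):
                (x1, y1), (x2, y2) = centers_map[f"C{i}"], centers_map[f"C{j}"]
                s = np.hypot(x1 - x2, y1 - y2)
                between[(f"C{i}", f"C{j}")] = 2 * s + 1
        res = rc.distance_decay(between, sheet)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["r"] == pytest.approx(1.0)

    def test_constant_genetic_distance_is_degenerate(self):
        sheet = self._sheet_with_centers([(0, 0), (5, 0), (0, 7)])
        between = {(a, b): 1.5 for a, b in [("C0", "C1"), ("C0", "C2"), ("C1", "C2")]}
        res = rc.distance_decay(between, sheet)
        assert res["degenerate"] is True
        assert res["slope"] == 0.0 and res["r"] == 0.0

    def test_zero_spatial_variance_rejected(self):
        sheet = self._sheet_with_centers([(0, 0), (0, 0), (0, 0)])
        between = {(a, b): 1.0 for a, b in [("C0", "C1"), ("C0", "C2"), ("C1", "C2")]}
        with pytest.raises(ValueError, match="spatial"):
            rc.distance_decay(between, sheet)

    def test_panmictic_design_has_no_spatial_trend(self):
        """Mean slope over seeds within 2 SE of zero when geography is irrelevant."""
        slopes = []
        for seed in range(20):
            cfg = rc.SimulationConfig(
                n_circles=8, samples_per_circle=2, ploidy_mix={2: 1.0},
                n_sites=400, seed=300 + seed,
            )
            vt, sheet, _, _ = rc.simulate_population(cfg)
            d = rc.genetic_distance_matrix(rc.recode_genotypes(vt))
            _, between = rc.min_within_between(d, sheet)
            slopes.append(rc.distance_decay(between, sheet)["slope"])
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        # 3-SE band: a z-type check at the ~0.3% level on the null slope
        assert abs(slopes.mean()) < 3 * se + 1e-12


class TestInbreeding:
    def _matrix(self, values, samples):
        values = np.asarray(values, dtype=float)
        return rc.RecodedGenotypeMatrix(
            site_ids=[f"s{i}" for i in range(values.shape[0])],
            sample_ids=samples, values=values, provenance={},
        )

    def test_fully_homozygous_sample_has_f_one(self):
        m = self._matrix(
            [[0.0, 0.5], [1.0, 0.5], [0.0, 0.5], [1.0, 0.5]], ["hom", "het"]
        )
        res = rc.inbreeding_coefficient(m)
        assert res.f_per_sample["hom"] == pytest.approx(1.0)
        assert res.f_per_sample["het"] < 0

    def test_monomorphic_sites_rejected(self):
        m = self._matrix([[0.0, 0.0], [1.0, 1.0]], ["a", "b"])
        with pytest.raises(ValueError, match="monomorphic"):
            rc.inbreeding_coefficient(m)

    def test_bootstrap_ci_brackets_mean(self):
        rng = np.random.default_rng(8)
        values = (rng.integers(0, 3, size=(400, 10)) / 2.0)
        m = self._matrix(values, [f"s{i}" for i in range(10)])
        res = rc.inbreeding_coefficient(m, ci_method="bootstrap", seed=1)
        assert res.ci_low <= res.mean_f <= res.ci_high

    def test_outbred_diploids_recover_zero(self):
        means = []
        for seed in range(5):
            cfg = rc.SimulationConfig(
                n_circles=8, samples_per_circle=2, ploidy_mix={2: 1.0},
                n_sites=4000, selfing_F=0.0, seed=500 + seed,
            )
            vt, _, _, _ = rc.simulate_population(cfg)
            res = rc.inbreeding_coefficient(rc.recode_genotypes(vt))
            means.append(res.mean_f)
        assert abs(np.mean(means)) < 0.05


class TestReport:
    def test_clonal_design_power(self):
        """Full clonality: every within-minimum is 0 and the rank-sum test
        rejects decisively at the study's sample sizes."""
        cfg = rc.SimulationConfig(
            n_circles=15, samples_per_circle=3, clonal_circles=1.0,
            ploidy_mix={2: 1.0}, error_rate=0.0, n_sites=1000, seed=13,
        )
        vt, sheet, _, _ = rc.simulate_population(cfg)
        d = rc.genetic_distance_matrix(rc.recode_genotypes(vt))
        report = rc.clonality_report(d, sheet)
        assert all(v == 0.0 for v in report.within_min.values())
        assert len(report.within_min) == 15 and len(report.between_min) == 105
        assert report.wilcoxon["p_value"] < 0.01

    def test_report_serializes_to_json(self, tmp_path, default_cohort):
        vt, sheet, _, _ = default_cohort
        d = rc.genetic_distance_matrix(rc.recode_genotypes(vt))
        report = rc.clonality_report(d, sheet)
        path = tmp_path / "report.json"
        report.to_json(path)
        import json

        data = json.loads(path.read_text())
        assert set(data) == {"within_min", "between_min", "wilcoxon", "decay",
                             "clone_pairs"}
        assert data["wilcoxon"]["n_x"] == len(report.within_min)
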