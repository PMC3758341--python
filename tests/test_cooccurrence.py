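import itertools
import math

import numpy as np
import pytest
from scipy import stats

from imco import (
    GeneIM,
    OrthologPair,
    OrthologTable,
    SyntheticConfig,
    ValidationError,
    build_pairs,
    estimate_points,
    exon_points,
    filter_min_obs,
    generate_pairs,
    imco_by_exon_product,
    q_hm_from_counts,
    spearman_trend,
)


def make_pair(i, psi, im_h, im_m, exons_h=3, exons_m=3):
    return OrthologPair(f"h{i}", f"m{i}", psi, im_h, im_m, exons_h, exons_m)


def random_pairs(rng, n):
    return [
        make_pair(i, float(rng.uniform(30, 100)), bool(rng.random() < 0.6),
                  bool(rng.random() < 0.5), int(rng.integers(1, 15)),
                  int(rng.integers(1, 15)))
        for i in range(n)
    ]


class TestBuildPairs:
    def _genes(self, ids, species):
        return [GeneIM(g, True, 2, 4, species) for g in ids]

    def test_all_resolvable(self):
        table = OrthologTable(rows=[("h1", "m1"), ("h2", "m2"), ("h3", "m3")])
        ids = {(f"h{i}", f"m{i}"): 80.0 for i in (1, 2, 3)}
        pairs = build_pairs(self._genes(["h1", "h2", "h3"], "human"),
                            self._genes(["m1", "m2", "m3"], "other"), table, ids)
        assert len(pairs) == 3

    def test_missing_annotation_dropped(self):
        table = OrthologTable(rows=[("h1", "m1"), ("h2", "m2"), ("h3", "m3")])
        ids = {(f"h{i}", f"m{i}"): 80.0 for i in (1, 2, 3)}
        pairs = build_pairs(self._genes(["h1", "h2", "h3"], "human"),
                            self._genes(["m1", "m3"], "other"), table, ids)
        assert len(pairs) == 2

    def test_empty_table(self):
        assert build_pairs([], [], OrthologTable(rows=[]), {}) == []


class TestEstimatePoints:
    def test_counting_rule(self):
        pairs = [make_pair(i, 80.2, i < 3, True) for i in range(4)]
        (pt,) = estimate_points(pairs)
        assert pt.x == 80.0 and pt.n_pairs == 4
        assert pt.imco == pytest.approx(0.75)

    def test_degenerate_all_im(self):
        pairs = [make_pair(i, 90.0, True, True) for i in range(5)]
        (pt,) = estimate_points(pairs)
        assert pt.imco == pt.p_im_h == pt.p_im_m == 1.0
        assert pt.q_hm == pytest.approx(1.0)

    def test_perfectly_coupled_species(self):
        # im_h == im_m always with marginal 0.6 -> q_hm = 1/0.6
        flags = [True] * 6 + [False] * 4
        pairs = [make_pair(i, 85.0, f, f) for i, f in enumerate(flags)]
        (pt,) = estimate_points(pairs)
        assert pt.imco == pytest.approx(0.6)
        assert pt.q_hm == pytest.approx(1 / 0.6)

    def test_rounding_half_up(self):
        pairs = [make_pair(0, 79.5, True, True), make_pair(1, 80.4, True, True)]
        (pt,) = estimate_points(pairs)
        assert pt.x == 80.0 and pt.n_pairs == 2

    def test_pair_conservation(self, rng):
        pairs = random_pairs(rng, 500)
        points = estimate_points(pairs)
        assert sum(p.n_pairs for p in points) == 500

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            estimate_points([])

    def test_factorization_identity_and_bounds(self, rng):
        # Q_HM * P(IM_H|x) * P(IM_M|x) reproduces IMco exactly
        for _ in range(50):
            pairs = random_pairs(rng, int(rng.integers(5, 200)))
            for pt in estimate_points(pairs):
                assert pt.imco <= min(pt.p_im_h, pt.p_im_m) + 1e-15
                if pt.q_hm is not None:
                    assert abs(pt.imco - pt.q_hm * pt.p_im_h * pt.p_im_m) <= 1e-12


class TestQhmFromCounts:
    def test_independence_identity(self):
        assert q_hm_from_counts(100, 50, 40, 20) == pytest.approx(1.0)

    def test_zero_joint(self):
        assert q_hm_from_counts(10, 6, 6, 0) == 0.0

    def test_full_coupling(self):
        assert q_hm_from_counts(10, 6, 6, 6) == pytest.approx(10 * 6 / 36)

    def test_undefined_when_species_empty(self):
        assert q_hm_from_counts(10, 0, 6, 0) is None

    def test_sqrt_form_equivalence(self, rng):
        # n*n_hm/(n_h*n_m) equals the square-root conditional form
        for _ in range(100):
            n = int(rng.integers(2, 200))
            n_h = int(rng.integers(1, n + 1))
            n_m = int(rng.integers(1, n + 1))
            n_hm = int(rng.integers(0, min(n_h, n_m) + 1))
            direct = q_hm_from_counts(n, n_h, n_m, n_hm)
            sqrt_form = math.sqrt(
                ((n_hm / n_m) * (n_hm / n_h)) / ((n_h / n) * (n_m / n))
            )
            assert direct == pytest.approx(sqrt_form, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            q_hm_from_counts(10, 6, 6, 7)


class TestFilterMinObs:
    def _points(self, counts):
        pairs = []
        i = 0
        for x, n in enumerate(counts):
            for _ in range(n):
                pairs.append(make_pair(i, 60.0 + x, True, True))
                i += 1
        return estimate_points(pairs)

    def test_threshold_rule(self):
        points = self._points([1, 4, 5, 9])
        kept = filter_min_obs(points, 5)
        assert [p.n_pairs for p in kept] == [5, 9]

    def test_min_one_is_identity(self):
        points = self._points([1, 4, 5, 9])
        assert filter_min_obs(points, 1) == points

    def test_all_filtered_warns(self, caplog):
        points = self._points([2, 3])
        with caplog.at_level("WARNING"):
            assert filter_min_obs(points, 10) == []
        assert "min_n" in caplog.text

    def test_retained_points_unchanged(self):
        points = self._points([1, 4, 5, 9])
        kept = filter_min_obs(points, 5)
        assert all(k in points for k in kept)


class TestExonAggregations:
    def test_mean_exons(self):
        pairs = [make_pair(0, 90.0, True, True, 4, 2),
                 make_pair(1, 90.0, True, True, 6, 8)]
        df = exon_points(pairs)
        assert df.loc[0, "mean_exons_h"] == 5.0
        assert df.loc[0, "mean_exons_m"] == 5.0

    def test_single_pair(self):
        df = exon_points([make_pair(0, 70.0, True, True, 9, 2)])
        assert df.loc[0, "mean_exons_h"] == 9 and df.loc[0, "n_pairs"] == 1

    def test_matches_independent_tally(self, rng):
        pairs = random_pairs(rng, 300)
        df = exon_points(pairs)
        groups = {}
        for p in pairs:
            x = math.floor(p.psi + 0.5)
            groups.setdefault(x, []).append(p)
        assert len(df) == len(groups)
        for r in df.itertuples(index=False):
            grp = groups[int(r.x)]
            assert r.n_pairs == len(grp)
            assert r.mean_exons_h == pytest.approx(
                sum(p.exons_h for p in grp) / len(grp)
            )

    def test_imco_by_product(self):
        pairs = [make_pair(i, 80.0, i < 2, True, 3, 4) for i in range(4)]
        df = imco_by_exon_product(pairs)
        assert df.loc[0, "product"] == 12 and df.loc[0, "imco"] == 0.5

    def test_single_exon_genes_without_im(self):
        pairs = [make_pair(i, 80.0, False, False, 1, 1) for i in range(5)]
        df = imco_by_exon_product(pairs)
        assert df.loc[0, "product"] == 1 and df.loc[0, "imco"] == 0.0

    def test_product_matches_tally(self, rng):
        pairs = random_pairs(rng, 300)
        df = imco_by_exon_product(pairs)
        tally = {}
        for p in pairs:
            key = p.exons_h * p.exons_m
            n, k = tally.get(key, (0, 0))
            tally[key] = (n + 1, k + int(p.im_h and p.im_m))
        for r in df.itertuples(index=False):
            n, k = tally[r.product]
            assert r.n_pairs == n and r.imco == pytest.approx(k / n)


class TestSpearmanTrend:
    def test_perfect_increase(self):
        t = spearman_trend([1, 2, 3, 4, 5], [2, 4, 5, 7, 9])
        assert t.rho == pytest.approx(1.0)

    def test_perfect_decrease(self):
        t = spearman_trend([1, 2, 3, 4, 5], [9, 7, 5, 4, 2])
        assert t.rho == pytest.approx(-1.0)

    def test_exact_p_matches_naive_enumeration(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        ys = [2.1, 1.0, 4.0, 3.5, 6.0, 5.0]
        t = spearman_trend(xs, ys)
        rho_obs = stats.spearmanr(xs, ys).statistic
        count = 0
        for perm in itertools.permutations(ys):
            rho_p = stats.spearmanr(xs, perm).statistic
            if abs(rho_p) >= abs(rho_obs) - 1e-12:
                count += 1
        assert t.p_value == pytest.approx(count / math.factorial(6), abs=1e-10)

    def test_t_approximation_branch(self):
        rng = np.random.default_rng(5)
        xs = rng.normal(size=30)
        ys = xs + rng.normal(size=30)
        t = spearman_trend(xs, ys)
        ref = stats.spearmanr(xs, ys)
        assert t.rho == pytest.approx(ref.statistic)
        assert t.p_value == pytest.approx(ref.pvalue)

    def test_validation(self):
        with pytest.raises(ValidationError):
            spearman_trend([1, 2], [1, 2])
        with pytest.raises(ValidationError):
            spearman_trend([1, 2, 3], [1, 2])


class TestIndependenceCalibration:
    def test_uncoupled_species_give_q_hm_near_one(self):
        config = SyntheticConfig(n_pairs=20_000, seed=42)
        assert config.im_model.coupling == 0.0
        pairs, _ = generate_pairs(config)
        points = [p for p in estimate_points(pairs)
                  if p.n_pairs >= 50 and p.q_hm is not None]
        weights = np.array([p.n_pairs for p in points])
        q = np.array([p.q_hm for p in points])
        mean_q = float(np.sum(weights * q) / np.sum(weights))
        assert 0.9 <= mean_q <= 1.1
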