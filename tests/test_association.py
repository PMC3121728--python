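import itertools
import math
from math import comb

import numpy as np
import pytest

from cghcohort import association as assoc
from cghcohort.io_formats import CaseMeta, Config


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration of the point-probability two-sided rule."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    k_min, k_max = max(0, c1 - (n - r1)), min(r1, c1)
    weights = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(k_min, k_max + 1)}
    w_obs = weights[a]
    return sum(w for w in weights.values() if w <= w_obs) / comb(n, c1)


class TestFisherExact:
    def test_balanced_table(self):
        assert assoc.fisher_exact_2x2(2, 2, 2, 2) == pytest.approx(1.0)

    def test_complete_separation(self):
        # only the two extreme tables have probability <= 1/252
        assert assoc.fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_degenerate_margin(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert assoc.fisher_exact_2x2(0, 0, 3, 3) == 1.0

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            assoc.fisher_exact_2x2(-1, 1, 1, 1)

    def test_matches_enumeration_small_n(self):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        if (a + b) in (0, n) or (a + c) in (0, n):
                            continue
                        assert assoc.fisher_exact_2x2(a, b, c, d) == pytest.approx(
                            fisher_oracle(a, b, c, d), abs=1e-9
                        )


def mw_enumeration_oracle(x, y):
    """Brute-force two-sided exact p: all labelings, pairwise-count U."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        ys = [pooled[i] for i in range(len(pooled)) if i not in subset]
        u1 = sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)
        return min(u1, len(xs) * len(ys) - u1)

    u_obs = u_of(tuple(range(n1)))
    labelings = list(itertools.combinations(range(len(pooled)), n1))
    hits = sum(1 for s in labelings if u_of(s) <= u_obs + 1e-9)
    return u_obs, hits / len(labelings)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = assoc.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples(self):
        _, p = assoc.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([1.5, 2.5, 9], [2.5, 3, 1]),
            ([1, 1, 2], [1, 2, 2]),
            ([0.1, 0.4, 0.4, 2.0], [0.4, 1.1, 3.0]),
        ],
    )
    def test_exact_mode_matches_enumeration(self, x, y):
        u, p = assoc.mann_whitney_u(x, y)
        u_oracle, p_oracle = mw_enumeration_oracle(x, y)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(p_oracle)

    def test_large_sample_approximation_sane(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        y = rng.normal(1.2, 1, 40)
        _, p = assoc.mann_whitney_u(x, y)
        assert p < 1e-4
        _, p_null = assoc.mann_whitney_u(x, rng.normal(0, 1, 40))
        assert p_null > 0.01

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            assoc.mann_whitney_u([], [1.0])


def _null_matrix(rng, n_per_breed=30, n_regions=8, p_carrier=0.5):
    n = 2 * n_per_breed
    indicator = (rng.random((n, n_regions)) < p_carrier).astype(np.int8)
    breeds = np.array(["BMD"] * n_per_breed + ["FCR"] * n_per_breed, dtype=object)
    regions = [
        assoc.Region("CFA1", float(10 * j), float(10 * j + 5), "loss")
        for j in range(n_regions)
    ]
    return assoc.RegionAberrationMatrix(
        case_ids=[f"c{i}" for i in range(n)],
        breeds=breeds,
        regions=regions,
        indicator=indicator,
    )


class TestPermutationFWER:
    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(0)
        m = _null_matrix(rng)
        with pytest.raises(ValueError):
            assoc.permutation_fwer(m, Config(n_permutations=0))

    def test_single_breed_rejected(self):
        rng = np.random.default_rng(0)
        m = _null_matrix(rng)
        m.breeds[:] = "BMD"
        with pytest.raises(ValueError, match="two breeds"):
            assoc.permutation_fwer(m, Config(n_permutations=1000))

    def test_cutoff_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        m = _null_matrix(rng)
        cfg5 = Config(n_permutations=2000, fwer_alpha=0.05, rng_seed=9)
        cfg1 = Config(n_permutations=2000, fwer_alpha=0.01, rng_seed=9)
        c5 = assoc.permutation_fwer(m, cfg5)
        c1 = assoc.permutation_fwer(m, cfg1)
        assert c1.cutoff <= c5.cutoff

    def test_cutoff_within_alpha(self):
        rng = np.random.default_rng(2)
        m = _null_matrix(rng)
        cut = assoc.permutation_fwer(m, Config(n_permutations=2000, rng_seed=3))
        assert 0 < cut.cutoff <= 0.05 + 1e-12

    def test_fwer_controlled_on_null_cohorts(self):
        """<= alpha + 2 binomial SE of 200 null cohorts show any flagged region."""
        rng = np.random.default_rng(2024)
        cfg = Config(n_permutations=2000, rng_seed=0)
        n_reps, any_sig = 200, 0
        for _ in range(n_reps):
            m = _null_matrix(rng)
            cut = assoc.permutation_fwer(m, cfg, rng=rng)
            res = assoc.associate_regions(m, cut)
            any_sig += any(r.significant for r in res)
        bound = 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_reps)
        assert any_sig / n_reps <= bound

    def test_cutoff_near_sidak_for_independent_regions(self):
        """For m independent balanced regions, cutoff ~ 1 - (1-alpha)^(1/m).

        Fisher p-values are discrete, so only order-of-magnitude agreement is
        asserted.
        """
        rng = np.random.default_rng(7)
        m = _null_matrix(rng, n_per_breed=50, n_regions=12)
        cut = assoc.permutation_fwer(m, Config(n_permutations=5000, rng_seed=5))
        sidak = 1 - (1 - 0.05) ** (1 / 12)
        assert 0.2 * sidak <= cut.cutoff <= 2.5 * sidak

    def test_label_swap_leaves_pvalues_unchanged(self):
        rng = np.random.default_rng(4)
        m = _null_matrix(rng)
        cfg = Config(n_permutations=1000, rng_seed=6)
        cut = assoc.permutation_fwer(m, cfg)
        res1 = assoc.associate_regions(m, cut)
        swapped = assoc.RegionAberrationMatrix(
            case_ids=m.case_ids,
            breeds=np.where(m.breeds == "BMD", "FCR", "BMD"),
            regions=m.regions,
            indicator=m.indicator,
        )
        res2 = assoc.associate_regions(swapped, cut)
        for r1, r2 in zip(res1, res2):
            assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)


class TestBuildRegionMatrix:
    def _meta(self):
        return [CaseMeta("c1", "BMD", "USA"), CaseMeta("c2", "FCR", "USA")]

    def test_overlap_indicator(self, result_factory):
        r1 = result_factory("c1", [("CFA1", 47, 50, "loss")])
        r2 = result_factory("c2", [("CFA1", 47, 48, "loss")])
        m = assoc.build_region_matrix(
            [r1, r2], [("CFA1", 48.0, 52.0, "loss")], self._meta()
        )
        assert m.indicator[:, 0].tolist() == [1, 0]  # half-open: [47,48) misses

    def test_state_must_match(self, result_factory):
        r1 = result_factory("c1", [("CFA1", 47, 50, "gain")])
        m = assoc.build_region_matrix(
            [r1], [("CFA1", 47.0, 50.0, "loss")], self._meta()
        )
        assert m.indicator[0, 0] == 0

    def test_flat_cases_excluded(self, result_factory):
        from cghcohort.cna_calling import CaseCallResult

        r1 = result_factory("c1", [("CFA1", 47, 50, "loss")])
        flat = CaseCallResult("c2", [])
        m = assoc.build_region_matrix(
            [r1, flat], [("CFA1", 47.0, 50.0, "loss")], self._meta()
        )
        assert m.case_ids == ["c1"]

    def test_region_off_genome(self, result_factory):
        r1 = result_factory("c1", [("CFA1", 47, 50, "loss")])
        with pytest.raises(ValueError, match="off chromosome"):
            assoc.build_region_matrix(
                [r1],
                [("CFA1", 120.0, 130.0, "loss")],
                self._meta(),
                chrom_lengths={"CFA1": 125.0},
            )

    def test_direct_fisher_on_strong_contrast(self):
        p = assoc.fisher_exact_2x2(24, 4, 6, 26)
        assert p < 1e-6


class TestEpidemiology:
    def test_f1_age_direction(self, f1_cohort):
        report = assoc.compare_epidemiology(f1_cohort.meta)
        assert report.age_stats["FCR"][1] > report.age_stats["BMD"][1]
        assert report.internal_frac["BMD"] > report.internal_frac["FCR"]

    def test_balanced_locations_give_p_one(self):
        meta = []
        for i, breed in enumerate(["BMD"] * 4 + ["FCR"] * 4):
            loc = "one_internal_organ" if i % 2 == 0 else "limb_only"
            meta.append(CaseMeta(f"c{i}", breed, "USA", tumor_location=loc, age_years=5.0))
        report = assoc.compare_epidemiology(meta)
        assert report.location_p == pytest.approx(1.0)

    def test_missing_breed_errors(self):
        meta = [CaseMeta("c1", "BMD", "USA", age_years=5.0)]
        with pytest.raises(ValueError):
            assoc.compare_epidemiology(meta)
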