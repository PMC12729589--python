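import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cernapipe import diffexpr
from cernapipe.models import ValidationError


def enumeration_oracle(counts_a, counts_b, phi):
    """Brute-force conditional NB exact test via hand-written log-pmf."""
    na, nb = len(counts_a), len(counts_b)
    sa = int(round(sum(counts_a)))
    total = sa + int(round(sum(counts_b)))
    if total == 0:
        return 1.0
    mu = total / (na + nb)

    def log_nb(x, size, mean):
        p = size / (size + mean)
        return (
            math.lgamma(x + size) - math.lgamma(size) - math.lgamma(x + 1)
            + size * math.log(p) + x * math.log1p(-p)
        )

    weights = [
        math.exp(log_nb(s, na / phi, na * mu)) * math.exp(log_nb(total - s, nb / phi, nb * mu))
        for s in range(total + 1)
    ]
    z = sum(weights)
    weights = [w / z for w in weights]
    obs = weights[sa]
    p = sum(w for w in weights if w <= obs * (1 + 1e-12))
    return min(1.0, max(p, obs))


class TestNBExactTest:
    def test_identical_groups_give_p_one(self):
        assert diffexpr.nb_exact_test([5, 5, 5], [5, 5, 5], 0.01) == 1.0

    def test_all_zero_gene_convention(self):
        assert diffexpr.nb_exact_test([0, 0], [0, 0], 0.01) == 1.0

    @pytest.mark.parametrize(
        "a, b",
        [
            ([3, 7, 5], [12, 18, 20]),
            ([0, 1, 0], [9, 4, 7]),
            ([30, 25], [22, 28, 31]),  # unequal group sizes
            ([1], [60]),
            ([14, 16, 15], [15, 14, 16]),
        ],
    )
    @pytest.mark.parametrize("phi", [0.01, 0.1, 1.0])
    def test_matches_enumeration_oracle(self, a, b, phi):
        assert sum(a) + sum(b) <= 200
        p = diffexpr.nb_exact_test(a, b, phi)
        assert p == pytest.approx(enumeration_oracle(a, b, phi), abs=1e-10)
        assert 0 < p <= 1

    def test_group_swap_symmetry(self):
        a, b = [3, 9, 4], [15, 11, 19]
        assert diffexpr.nb_exact_test(a, b, 0.01) == pytest.approx(
            diffexpr.nb_exact_test(b, a, 0.01), abs=1e-14
        )

    def test_increasing_dispersion_never_decreases_p(self):
        """Over-dispersion widens the null: p is monotone in phi on a grid."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.poisson(20, 3)
            b = rng.poisson(40, 3)
            ps = [diffexpr.nb_exact_test(a, b, phi)
                  for phi in (0.001, 0.01, 0.1, 0.5, 1.0)]
            assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_size_factor_scaling(self):
        """Dividing counts by size factors before testing equals passing them."""
        a, b = np.array([10, 20, 30]), np.array([15, 25, 35])
        fa, fb = np.array([1.0, 2.0, 3.0]), np.array([1.5, 2.5, 3.5])
        direct = diffexpr.nb_exact_test(a, b, 0.01, fa, fb)
        manual = diffexpr.nb_exact_test(np.rint(a / fa), np.rint(b / fb), 0.01)
        assert direct == pytest.approx(manual, abs=1e-14)

    def test_rejects_invalid_input(self):
        with pytest.raises(ValidationError):
            diffexpr.nb_exact_test([], [1, 2], 0.01)
        with pytest.raises(ValidationError):
            diffexpr.nb_exact_test([1, -2], [1, 2], 0.01)
        with pytest.raises(ValidationError):
            diffexpr.nb_exact_test([1, 2], [1, 2], 0.0)


def bh_oracle(p):
    """Brute-force min-over-tail BH definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {idx: r + 1 for r, idx in enumerate(order)}
    out = []
    for i in range(m):
        candidates = [p[j] * m / rank[j] for j in range(m) if p[j] >= p[i]]
        out.append(min(1.0, min(candidates)))
    return out


class TestBH:
    def test_all_equal(self):
        assert np.allclose(diffexpr.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_hand_computed_example(self):
        # ranks 1..4 give 0.04, 0.04, 0.04, 0.04 after step-up
        assert np.allclose(diffexpr.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_order_equivariance(self):
        p = np.array([0.3, 0.01, 0.2, 0.05, 0.9])
        perm = np.array([4, 2, 0, 1, 3])
        assert np.allclose(diffexpr.bh_fdr(p)[perm], diffexpr.bh_fdr(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            diffexpr.bh_fdr([0.5, 1.2])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                 min_size=1, max_size=50)
    )
    def test_matches_brute_force_oracle(self, p):
        got = diffexpr.bh_fdr(p)
        expected = bh_oracle(p)
        assert np.allclose(got, expected, atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(diffexpr.bh_fdr(p), adj)


class TestCallDE:
    @pytest.fixture(scope="class")
    def fixture_data(self):
        rng = np.random.default_rng(8)
        stages = ["A", "B", "C", "D"]
        samples = [f"{st}_{r}" for st in stages for r in (1, 2, 3)]
        sheet = pd.DataFrame(
            {"sample_id": samples,
             "stage": [s.split("_")[0] for s in samples],
             "replicate": [int(s.split("_")[1]) for s in samples]}
        )
        r = 1 / 0.01
        flat = rng.negative_binomial(r, r / (r + 50.0), size=(30, 12))
        # one strongly staged feature: 8-fold ramp
        mus = np.repeat([20, 50, 90, 160], 3)
        staged = rng.negative_binomial(r, r / (r + mus), size=(1, 12))
        counts = pd.DataFrame(
            np.vstack([flat, staged, np.full((1, 12), 77)]),
            index=[f"g{i}" for i in range(31)] + ["const"],
            columns=samples,
        )
        return counts, sheet

    def test_six_comparisons_and_statuses(self, fixture_data):
        counts, sheet = fixture_data
        tables = diffexpr.call_de(counts, sheet)
        assert len(tables) == 6
        assert set(tables) == {
            "A_vs_B", "A_vs_C", "A_vs_D", "B_vs_C", "B_vs_D", "C_vs_D"
        }
        # the planted staged feature is significant at the extremes
        extreme = tables["A_vs_D"].set_index("feature_id")
        assert extreme.loc["g30", "status"] == "up"
        assert extreme.loc["g30", "log2FC"] > 1

    def test_constant_feature_ns_everywhere(self, fixture_data):
        counts, sheet = fixture_data
        tables = diffexpr.call_de(counts, sheet)
        for df in tables.values():
            assert df.set_index("feature_id").loc["const", "status"] == "ns"

    def test_deterministic(self, fixture_data):
        counts, sheet = fixture_data
        t1 = diffexpr.call_de(counts, sheet)
        t2 = diffexpr.call_de(counts, sheet)
        for comp in t1:
            pd.testing.assert_frame_equal(t1[comp], t2[comp])

    def test_status_rule(self, fixture_data):
        counts, sheet = fixture_data
        for df in diffexpr.call_de(counts, sheet).values():
            up = df["status"] == "up"
            assert ((df.loc[up, "fdr"] < 0.05) & (df.loc[up, "log2FC"] > 1)).all()
            ns = df["status"] == "ns"
            assert (~((df.loc[ns, "fdr"] < 0.05) & (df.loc[ns, "log2FC"].abs() > 1))).all()


class TestSetOps:
    def make_tables(self, membership: dict[str, set[str]], universe):
        tables = {}
        for comp, sig in membership.items():
            tables[comp] = pd.DataFrame(
                {
                    "feature_id": list(universe),
                    "comparison": comp,
                    "log2FC": [2.0 if f in sig else 0.0 for f in universe],
                    "pvalue": [0.001 if f in sig else 0.9 for f in universe],
                    "fdr": [0.001 if f in sig else 0.9 for f in universe],
                    "status": ["up" if f in sig else "ns" for f in universe],
                }
            )
        return tables

    def test_disjoint_sets_empty_intersection(self):
        tables = self.make_tables(
            {"c1": {"a"}, "c2": {"b"}}, universe=["a", "b", "c"]
        )
        mm = diffexpr.de_set_ops(tables)
        assert set(mm.index) == {"a", "b"}
        assert not (mm["c1"] & mm["c2"]).any()

    def test_region_counts_match_hand_enumeration(self):
        universe = list("abcdefg")
        tables = self.make_tables(
            {"c1": {"a", "b", "d"}, "c2": {"b", "c", "d"}, "c3": {"d", "e"}},
            universe,
        )
        mm = diffexpr.de_set_ops(tables)
        regions = diffexpr.venn_region_counts(mm)
        assert regions[(True, False, False)] == 1   # a
        assert regions[(True, True, False)] == 1    # b
        assert regions[(False, True, False)] == 1   # c
        assert regions[(True, True, True)] == 1     # d
        assert regions[(False, False, True)] == 1   # e
        assert sum(regions.values()) == len(mm)     # partition of the union
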