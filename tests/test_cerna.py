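import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, spearmanr

from cernapipe import cerna
from cernapipe.models import CeRNAEdge, ValidationError


def target_df(rows):
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "target_id", "targetscan_score", "miranda_energy",
                 "source"],
    )


class TestFilterTargets:
    @pytest.mark.parametrize(
        "score, energy, source, kept",
        [
            (55, -12, "both", True),
            (45, -20, "both", False),      # fails the score threshold
            (80, -5, "both", False),       # fails the energy threshold
            (80, -20, "targetscan", False),  # present in only one predictor
            (50, -10, "both", True),       # boundary: thresholds inclusive
        ],
    )
    def test_threshold_and_intersection_rules(self, score, energy, source, kept):
        records = target_df([("m1", "t1", score, energy, source)])
        out = cerna.filter_targets(records)
        assert (("m1" in out.mirna_to_targets) and
                ("t1" in out.mirna_to_targets.get("m1", set()))) == kept

    def test_two_single_source_records_intersect(self):
        records = target_df(
            [("m1", "t1", 80, -20, "targetscan"),
             ("m1", "t1", 80, -20, "miranda")]
        )
        out = cerna.filter_targets(records)
        assert out.mirna_to_targets == {"m1": {"t1"}}

    def test_empty_records(self):
        assert cerna.filter_targets(target_df([])).mirna_to_targets == {}


class TestSpearmanEdges:
    def test_anti_monotone_kept_monotone_dropped(self):
        n = 8
        up = np.arange(1.0, n + 1)
        mirna = pd.DataFrame([up], index=["m1"],
                             columns=[f"s{j}" for j in range(n)])
        cernas = pd.DataFrame([up[::-1], up * 2], index=["anti", "mono"],
                              columns=[f"s{j}" for j in range(n)])
        targets = cerna.FilteredTargetSet({"m1": {"anti", "mono"}})
        edges = cerna.spearman_edges(mirna, cernas, targets)
        assert [(e.mirna_id, e.cerna_id) for e in edges] == [("m1", "anti")]
        assert edges[0].spearman_rho == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.integers(0, 5, size=12).astype(float)
            y = rng.integers(0, 5, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert cerna.spearman_rho(x, y) == pytest.approx(
                spearmanr(x, y).statistic, abs=1e-12
            )

    def test_constant_vector_skipped_with_warning(self, caplog):
        mirna = pd.DataFrame([[5, 5, 5, 5]], index=["m1"],
                             columns=list("abcd"))
        cernas = pd.DataFrame([[1, 2, 3, 4]], index=["t1"],
                              columns=list("abcd"))
        targets = cerna.FilteredTargetSet({"m1": {"t1"}})
        with caplog.at_level("WARNING"):
            edges = cerna.spearman_edges(mirna, cernas, targets)
        assert edges == [] and "constant" in caplog.text

    def test_mismatched_samples_rejected(self):
        mirna = pd.DataFrame([[1, 2]], index=["m"], columns=["a", "b"])
        cernas = pd.DataFrame([[1, 2]], index=["t"], columns=["a", "c"])
        with pytest.raises(ValidationError):
            cerna.spearman_edges(mirna, cernas, cerna.FilteredTargetSet({}))


class TestHypergeomShared:
    def test_trivial_values(self):
        assert cerna.hypergeom_shared(0, 4, 5, 10) == 1.0
        assert cerna.hypergeom_shared(3, 3, 3, 3) == pytest.approx(1.0)

    def test_exact_enumeration_value(self):
        assert cerna.hypergeom_shared(3, 4, 5, 10) == pytest.approx(
            66 / 252, abs=1e-12
        )

    def test_inconsistent_arguments_rejected(self):
        for bad in [(5, 4, 5, 10), (1, 11, 5, 10), (-1, 4, 5, 10)]:
            with pytest.raises(ValidationError):
                cerna.hypergeom_shared(*bad)

    def test_log_space_agrees_with_scipy_large_N(self):
        rng = np.random.default_rng(0)
        for N in (50, 200, 500):
            for _ in range(20):
                K = int(rng.integers(1, N))
                n = int(rng.integers(1, N))
                k = int(rng.integers(0, min(K, n) + 1))
                assert cerna.hypergeom_shared(k, K, n, N) == pytest.approx(
                    float(hypergeom.sf(k - 1, N, K, n)), abs=1e-10
                )


def build_zero_noise_screen():
    """Tiny hand-built screen: one planted triplet plus an uncorrelated decoy."""
    cols = [f"s{j}" for j in range(8)]
    up = np.arange(1.0, 9.0)
    mirna = pd.DataFrame([up, [3, 1, 4, 1, 5, 9, 2, 6]], index=["m1", "m2"],
                         columns=cols)
    cernas = pd.DataFrame(
        [up[::-1], up[::-1] * 3, [2, 7, 1, 8, 2, 8, 1, 8]],
        index=["L1", "G1", "G2"], columns=cols,
    )
    targets = cerna.FilteredTargetSet({"m1": {"L1", "G1"}, "m2": {"L1", "G2"}})
    types = {"L1": "lncRNA", "G1": "mRNA", "G2": "mRNA", "m1": "miRNA",
             "m2": "miRNA"}
    edges = cerna.spearman_edges(mirna, cernas, targets)
    return edges, cernas, targets, types


class TestScreenPairs:
    def test_planted_triplet_survives_correlation_filters(self):
        # the miRNA universe here is a single retained miRNA, so the
        # hypergeometric p is degenerate (1); disable that cut to isolate
        # the correlation filters
        edges, cernas, targets, types = build_zero_noise_screen()
        pairs = cerna.screen_pairs(edges, cernas, targets, types, p_max=1.1)
        assert len(pairs) == 1
        p = pairs[0]
        assert {p.rna_a, p.rna_b} == {"L1", "G1"}
        assert p.pearson_r == pytest.approx(1.0)
        assert p.shared_mirnas == frozenset({"m1"})
        assert (p.k, p.K, p.n, p.N) == (1, 1, 1, 1)

    def test_shared_mirnas_significant_in_realistic_universe(self):
        """A pair sharing both its miRNAs beats p<0.05 once the universe is
        populated with other retained miRNAs."""
        cols = [f"s{j}" for j in range(8)]
        up = np.arange(1.0, 9.0)
        mir_ids = ["p1", "p2"] + [f"f{i}" for i in range(10)]
        mirna = pd.DataFrame([up] * 12, index=mir_ids, columns=cols)
        cerna_ids = ["L1", "G1"] + [f"D{i}" for i in range(10)]
        cernas = pd.DataFrame([up[::-1]] * 12, index=cerna_ids, columns=cols)
        mapping = {"p1": {"L1", "G1"}, "p2": {"L1", "G1"}}
        mapping.update({f"f{i}": {f"D{i}"} for i in range(10)})
        targets = cerna.FilteredTargetSet(mapping)
        types = {"L1": "lncRNA", "G1": "mRNA"}
        types.update({f"D{i}": "mRNA" for i in range(10)})
        edges = cerna.spearman_edges(mirna, cernas, targets)
        pairs = cerna.screen_pairs(edges, cernas, targets, types)
        planted = [p for p in pairs if {p.rna_a, p.rna_b} == {"L1", "G1"}]
        assert len(planted) == 1
        p = planted[0]
        assert (p.k, p.K, p.n, p.N) == (2, 2, 2, 12)
        assert p.hyper_p == pytest.approx(1 / 66, abs=1e-12)  # C(2,2)/C(12,2)
        assert p.hyper_p < 0.05

    def test_pearson_threshold_is_strict_filter(self):
        edges, cernas, targets, types = build_zero_noise_screen()
        assert cerna.screen_pairs(edges, cernas, targets, types,
                                  r_min=1.0 + 1e-9) == []

    def test_pair_type_restriction(self):
        edges, cernas, targets, types = build_zero_noise_screen()
        types_all_mrna = dict(types, L1="mRNA")
        assert cerna.screen_pairs(edges, cernas, targets, types_all_mrna,
                                  p_max=1.1) == []
        both = cerna.screen_pairs(
            edges, cernas, targets, types_all_mrna, p_max=1.1,
            pair_types=frozenset({frozenset({"mRNA"})}),
        )
        assert len(both) == 1

    def test_universe_modes(self):
        edges, cernas, targets, types = build_zero_noise_screen()
        for mode, expected_N in [("filtered", 1), ("all_expressed", 2),
                                 ("all_predicted", 2)]:
            pairs = cerna.screen_pairs(edges, cernas, targets, types,
                                       universe_mode=mode, p_max=1.1)
            assert pairs and pairs[0].N == expected_N, mode

    def test_input_row_order_invariance(self):
        edges, cernas, targets, types = build_zero_noise_screen()
        pairs1 = cerna.screen_pairs(edges, cernas, targets, types, p_max=1.1)
        pairs2 = cerna.screen_pairs(list(reversed(edges)),
                                    cernas.iloc[::-1], targets, types,
                                    p_max=1.1)
        assert pairs1 == pairs2


class TestNetwork:
    def test_connectivity_counts_distinct_mirnas(self):
        edges = [
            CeRNAEdge("m1", "L1", -0.8),
            CeRNAEdge("m2", "L1", -0.9),
            CeRNAEdge("m3", "L1", -0.95),
            CeRNAEdge("m3", "G1", -0.85),
        ]
        pairs = cerna.screen_pairs(
            edges,
            pd.DataFrame([[1, 2, 3], [2, 4, 6]], index=["L1", "G1"],
                         columns=list("abc")),
            cerna.FilteredTargetSet(
                {"m1": {"L1"}, "m2": {"L1"}, "m3": {"L1", "G1"}}
            ),
            {"L1": "lncRNA", "G1": "mRNA"},
            p_max=1.1, r_min=0.5,
        )
        net = cerna.build_network(pairs, edges, {"L1": "lncRNA", "G1": "mRNA"})
        assert net.connectivity["L1"] == 3
        assert net.connectivity["G1"] == 1
        assert net.node_types["m3"] == "miRNA"

    def test_removing_an_edge_never_increases_connectivity(self):
        edges, cernas, targets, types = build_zero_noise_screen()
        pairs = cerna.screen_pairs(edges, cernas, targets, types, p_max=1.1)
        full = cerna.build_network(pairs, edges, types)
        for drop in range(len(edges)):
            reduced = cerna.build_network(pairs, edges[:drop] + edges[drop + 1:],
                                          types)
            for node, c in reduced.connectivity.items():
                assert c <= full.connectivity.get(node, 0)

    def test_connectivity_ranking_and_sankey(self):
        edges, cernas, targets, types = build_zero_noise_screen()
        pairs = cerna.screen_pairs(edges, cernas, targets, types, p_max=1.1)
        net = cerna.build_network(pairs, edges, types)
        lnc_rank, mrna_rank, sankey = cerna.connectivity_ranking(net)
        assert list(lnc_rank["node_id"]) == ["L1"]
        assert list(mrna_rank["node_id"]) == ["G1"]
        assert sankey.to_dict("records") == [
            {"lncRNA": "L1", "miRNA": "m1", "mRNA": "G1"}
        ]

    def test_empty_network(self):
        net = cerna.build_network([], [], {})
        assert net.node_types == {} and net.connectivity == {}
        lnc_rank, mrna_rank, sankey = cerna.connectivity_ranking(net)
        assert len(lnc_rank) == 0 and len(mrna_rank) == 0 and len(sankey) == 0
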