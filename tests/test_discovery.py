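"""Loss ranking, Venn intersection, activator identification, marker enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from h33course.discovery import (
    functional_targets,
    identify_activators,
    marker_enrichment,
    rank_h33_loss,
    read_gmt,
    write_gmt,
)
from h33course.genome_io import ValidationError
from h33course.onset import classify_onsets
from h33course.quantify import call_enrichment, normalize_library


class TestRankLoss:
    MATRIX = pd.DataFrame(
        {
            "A": [10, 2, 2, 2, 2, 2, 2],
            "B": [5, 5, 4, 1, 1, 1, 1],
            "C": [3, 3, 3, 3, 3, 3, 3],
        },
        index=[f"t{i}" for i in range(7)],
    ).T

    def test_max_consecutive_drop_ranking(self):
        # brute-force the per-row maximum consecutive decrease
        for gid, row in self.MATRIX.iterrows():
            v = row.tolist()
            brute = max(max(v[i] - v[i + 1], 0.0) for i in range(len(v) - 1))
            got = rank_h33_loss(self.MATRIX, n=3).loc[gid, "loss_score"]
            assert got == pytest.approx(brute)
        top2 = rank_h33_loss(self.MATRIX, n=2)
        assert list(top2.index) == ["A", "B"]
        assert top2.loc["A", "loss_score"] == 8 and top2.loc["B", "loss_score"] == 3

    def test_constant_matrix_ties_break_by_gene_id(self):
        m = pd.DataFrame(np.ones((3, 4)), index=["z", "x", "y"])
        assert list(rank_h33_loss(m, n=3).index) == ["x", "y", "z"]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(size=(30, 7)), index=[f"g{i}" for i in range(30)])
        base = rank_h33_loss(m, n=10)
        perm = rank_h33_loss(m.sample(frac=1, random_state=4), n=10)
        pd.testing.assert_frame_equal(base, perm)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValidationError):
            rank_h33_loss(self.MATRIX, n=0)


class TestFunctionalTargets:
    def test_intersection_and_venn(self):
        both, venn = functional_targets({"A", "B", "C"}, {"B", "C", "D"})
        assert both == {"B", "C"}
        assert venn == {"only_knockdown": 1, "only_loss": 1, "both": 2}

    def test_disjoint_and_identical(self):
        assert functional_targets({"A"}, {"B"})[0] == set()
        both, venn = functional_targets({"A", "B"}, {"A", "B"})
        assert both == {"A", "B"}
        assert venn["only_knockdown"] == venn["only_loss"] == 0

    def test_venn_regions_sum_to_union(self):
        a, b = {"A", "B", "C", "E"}, {"B", "C", "D"}
        _, venn = functional_targets(a, b)
        assert sum(venn.values()) == len(a | b)


class TestIdentifyActivators:
    def _setup(self, sheet7, succ_presence, unsucc_presence, succ_rising, unsucc_flat):
        chip = sheet7.successful_route("chip_ip") + sheet7.unsuccessful_route("chip_ip")
        presence = pd.DataFrame(
            [succ_presence + unsucc_presence], index=["g"], columns=chip
        ).astype(bool)
        calls = classify_onsets(presence, sheet7)
        rna = sheet7.labels("rna")
        expr_row = {l: 1.0 for l in rna}
        if succ_rising:
            expr_row.update({"D0": 0.5, "iPSC": 10.0})
        else:
            expr_row.update({"D0": 0.5, "iPSC": 0.5})
        expr_row["D16S-"] = 0.5 if unsucc_flat else 10.0
        expr = pd.DataFrame([expr_row], index=["g"])[rna]
        return calls, expr

    def test_qualifying_gene_is_activator(self, sheet7):
        calls, expr = self._setup(
            sheet7, [0, 0, 1, 1, 1, 1, 1], [0, 0, 0, 0], succ_rising=True, unsucc_flat=True
        )
        assert identify_activators(calls, expr, sheet7) == {"g"}

    def test_unsuccessful_enrichment_disqualifies(self, sheet7):
        calls, expr = self._setup(
            sheet7, [0, 0, 1, 1, 1, 1, 1], [0, 1, 0, 0], succ_rising=True, unsucc_flat=True
        )
        assert identify_activators(calls, expr, sheet7) == set()

    def test_onset_before_window_disqualifies(self, sheet7):
        calls, expr = self._setup(
            sheet7, [0, 1, 1, 1, 1, 1, 1], [0, 0, 0, 0], succ_rising=True, unsucc_flat=True
        )
        assert identify_activators(calls, expr, sheet7) == set()

    def test_route_shared_expression_disqualifies(self, sheet7):
        calls, expr = self._setup(
            sheet7, [0, 0, 1, 1, 1, 1, 1], [0, 0, 0, 0], succ_rising=True, unsucc_flat=False
        )
        assert identify_activators(calls, expr, sheet7) == set()

    def test_recovers_planted_activators_exactly(self, clean_bundle):
        b = clean_bundle
        ip = normalize_library(b.h33_ip_counts, b.library_sizes)
        inp = normalize_library(b.h33_input_counts, b.library_sizes)
        presence = call_enrichment(ip, inp, b.catalog.lengths())
        calls = classify_onsets(presence, b.sheet)
        found = identify_activators(calls, b.fpkm, b.sheet)
        planted = set(b.truth.index[b.truth["is_activator"]])
        assert len(planted) >= 10
        assert found == planted  # precision = recall = 1 at zero noise


class TestMarkerEnrichment:
    def test_perfect_overlap_matches_enumeration(self):
        universe = [f"u{i}" for i in range(20)]
        marker = set(universe[:5])
        res = marker_enrichment(universe[:5], {"mESC": marker}, universe)
        p = res.loc["mESC", "p"]
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
        # exhaustive enumeration over all C(20,5) draws of the query
        hits = sum(
            1 for draw in itertools.combinations(universe, 5) if set(draw) == marker
        )
        assert p == pytest.approx(hits / math.comb(20, 5), rel=1e-12)
        assert res.loc["mESC", "score"] == pytest.approx(-math.log10(p))
        assert bool(res.loc["mESC", "significant"])

    def test_hypergeom_tail_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = int(rng.integers(5, 15))
            universe = [f"u{i}" for i in range(m)]
            k_set = int(rng.integers(1, m))
            n_query = int(rng.integers(1, m))
            marker = set(rng.choice(universe, size=k_set, replace=False))
            query = list(rng.choice(universe, size=n_query, replace=False))
            res = marker_enrichment(query, {"s": marker}, universe)
            overlap = len(set(query) & marker)
            hits = sum(
                1
                for draw in itertools.combinations(universe, n_query)
                if len(set(draw) & marker) >= overlap
            )
            assert res.loc["s", "p"] == pytest.approx(hits / math.comb(m, n_query), rel=1e-9)

    def test_zero_overlap_not_significant(self):
        universe = [f"u{i}" for i in range(10)]
        res = marker_enrichment(universe[5:], {"s": set(universe[:5])}, universe)
        assert res.loc["s", "p"] == pytest.approx(1.0)
        assert res.loc["s", "score"] == pytest.approx(0.0)
        assert not bool(res.loc["s", "significant"])

    def test_bh_matches_reference_step_up(self):
        """BH-adjusted p-values agree with a hand-written step-up procedure
        on random p-vectors across marker sets."""

        def bh_reference(ps):
            m = len(ps)
            order = np.argsort(ps)
            adj = np.empty(m)
            prev = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                prev = min(prev, ps[idx] * m / rank)
                adj[idx] = prev
            return adj

        rng = np.random.default_rng(2)
        for _ in range(100):
            n_sets = int(rng.integers(2, 50))
            universe = [f"u{i}" for i in range(200)]
            sets = {
                f"s{j:02d}": set(rng.choice(universe, size=int(rng.integers(1, 40)), replace=False))
                for j in range(n_sets)
            }
            query = list(rng.choice(universe, size=30, replace=False))
            res = marker_enrichment(query, sets, universe)
            np.testing.assert_allclose(
                res["adjusted_p"].to_numpy(),
                bh_reference(res["p"].to_numpy()),
                rtol=1e-10,
            )

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            marker_enrichment(["alien"], {"s": {"u1"}}, ["u1", "u2"])


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = {"fib": {"a", "b"}, "plur": {"c"}}
        path = tmp_path / "m.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets
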