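"""Gene orders: linearization, LNCRs, conserved blocks, breakpoint distance."""

import numpy as np
import pytest

from _oracles import ref_common_blocks, ref_unannotated_gaps
from mitochar.generearrange import (
    GeneOrder,
    breakpoint_distance,
    common_blocks,
    find_lncrs,
    linearize,
    trna_block_string,
)
from mitochar.records_io import GeneFeature, GenomeRecord
from mitochar.synthetic_data import apply_rearrangements


def _order(names_signs, taxon="t", circular=True):
    return GeneOrder(taxon, list(names_signs), circular)


class TestLinearize:
    def test_published_order_head(self, jd_record):
        order = linearize(jd_record, anchor="COIII", include="all")
        assert order.names()[:7] == ["COIII", "trnK", "trnA", "trnR", "trnN", "trnI", "ND3"]

    def test_single_gene_record(self):
        rec = GenomeRecord(id="x", length=100,
                           features=[GeneFeature("COIII", "PCG", 1, 99, "H")])
        assert linearize(rec).names() == ["COIII"]

    def test_rotation_invariance(self, jd_record):
        a = linearize(jd_record, anchor="COIII")
        b = linearize(jd_record, anchor="ND5")
        assert a == b  # circular orders compare equal under rotation

    def test_strand_signs(self, jd_record):
        order = linearize(jd_record, include="pcg_rrna")
        signs = dict(order.symbols)
        assert signs["COIII"] == -1 and signs["ND5"] == 1

    def test_missing_anchor(self, jd_record):
        with pytest.raises(ValueError):
            linearize(jd_record, anchor="FOO")


class TestTrnaBlocks:
    def test_karni_between_coiii_and_nd3(self, jd_record):
        order = linearize(jd_record)
        assert trna_block_string(order, "COIII", "ND3") == "KARNI"

    def test_mcywqg_adjacent_to_12s(self, jd_record):
        order = linearize(jd_record)
        assert trna_block_string(order, "12S", "trnE") == "MCYWQG"
        assert trna_block_string(order, "trnM", "trnE") == "CYWQG"

    def test_window_without_trnas(self, jd_record):
        order = linearize(jd_record, include="pcg_rrna")
        assert trna_block_string(order, "COIII", "ND5") == ""


class TestLNCR:
    def test_published_two_lncrs(self, ap_record):
        gaps = find_lncrs(ap_record, min_len=500)
        assert len(gaps) == 2
        between = {(g.upstream, g.downstream): g.length for g in gaps}
        assert between[("trnE", "ND4")] == 1109
        assert between[("trnG", "COIII")] == 1053

    def test_fully_annotated_toy(self):
        rec = GenomeRecord(
            id="x", length=20,
            features=[GeneFeature("trnA", "tRNA", 1, 10), GeneFeature("trnB", "tRNA", 11, 20)],
        )
        assert find_lncrs(rec) == []

    def test_gap_lengths_match_coverage_bitmap(self, ap_record, jd_record):
        for rec in (ap_record, jd_record):
            for min_len in (1, 50, 500):
                got = sorted(g.length for g in find_lncrs(rec, min_len))
                assert got == ref_unannotated_gaps(rec, min_len)

    def test_coverage_plus_gaps_tile_genome(self, ap_record):
        from mitochar.generearrange import lncr_coverage_check

        total_gaps = sum(g.length for g in find_lncrs(ap_record, min_len=1))
        assert total_gaps == lncr_coverage_check(ap_record)


class TestCommonBlocks:
    def test_identical_orders_single_full_block(self):
        o = _order([("a", 1), ("b", -1), ("c", 1)])
        blocks = common_blocks([o, _order(o.symbols, taxon="u")])
        assert len(blocks) == 1 and blocks[0].names() == ["a", "b", "c"]

    def test_published_nd4_nd4l_block(self, jd_record, ap_record):
        o1 = linearize(jd_record, include="pcg_rrna")
        o2 = linearize(ap_record, include="pcg_rrna")
        blocks = common_blocks([o1, o2], min_len=2)
        assert any(
            ("ND4", "ND4L") in tuple(zip(b.names(), b.names()[1:])) for b in blocks
        )

    def test_matches_exhaustive_oracle_on_random_orders(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 8
            base = [(f"g{i}", int(rng.choice([-1, 1]))) for i in range(n)]
            orders = [_order(base, taxon="ref")]
            for t in range(2):
                perm = list(base)
                i, j = sorted(rng.choice(n, 2, replace=False))
                seg = [(s, -sg) for s, sg in reversed(perm[i:j + 1])]
                perm[i:j + 1] = seg
                orders.append(_order(perm, taxon=f"t{t}"))
            got = {tuple(b.names()) for b in common_blocks(orders)}
            assert got == ref_common_blocks(orders)


class TestBreakpointDistance:
    def test_identical_orders(self):
        o = _order([("a", 1), ("b", 1), ("c", -1)])
        assert breakpoint_distance(o, _order(o.symbols, taxon="u")) == 0

    def test_two_gene_reversal_in_circular_order(self):
        a = _order([(f"g{i}", 1) for i in range(6)])
        syms = list(a.symbols)
        syms[2:4] = [(s, -sg) for s, sg in reversed(syms[2:4])]
        b = _order(syms, taxon="u")
        assert breakpoint_distance(a, b) == 2

    def test_pseudo_metric_properties(self):
        rng = np.random.default_rng(9)
        names = [f"g{i}" for i in range(8)]
        def rand_order(t):
            perm = rng.permutation(8)
            return _order([(names[i], int(rng.choice([-1, 1]))) for i in perm], taxon=t)
        for _ in range(15):
            x, y, z = rand_order("x"), rand_order("y"), rand_order("z")
            assert breakpoint_distance(x, x.rotated(3)) == 0  # rotation invariant
            dxy = breakpoint_distance(x, y)
            assert dxy == breakpoint_distance(y, x)
            assert dxy <= breakpoint_distance(x, z) + breakpoint_distance(z, y)

    def test_distance_grows_with_rearrangement_count(self):
        base = _order([(f"g{i}", 1) for i in range(12)])
        rng = np.random.default_rng(2)
        means = []
        for k in (1, 3, 6):
            dists = []
            for rep in range(20):
                moved, _ = apply_rearrangements(
                    base, ["translocation"] * k, seed=int(rng.integers(2**31))
                )
                dists.append(breakpoint_distance(base, moved))
            means.append(np.mean(dists))
        assert means[0] <= means[1] <= means[2]


class TestRearrangementSimulator:
    def test_empty_event_list_is_identity(self):
        o = _order([("a", 1), ("b", -1), ("c", 1)])
        new, log = apply_rearrangements(o, [], seed=0)
        assert new == o and log == []

    def test_known_translocation_breakpoints(self):
        o = _order([(f"g{i}", 1) for i in range(6)])
        new, log = apply_rearrangements(
            o, [{"type": "translocation", "segment": (1, 2), "dest": 3}], seed=0
        )
        # g1-g2 moved between g4 and g5: adjacencies g0-g1, g2-g3, g3-g4(sic) change
        assert breakpoint_distance(o, new) == 3
        assert log[0]["segment"] == (1, 2)

    def test_duplication_loss_keeps_single_copies(self):
        o = _order([(f"g{i}", 1) for i in range(6)])
        new, _ = apply_rearrangements(o, [{"type": "duplication_loss",
                                           "segment": (1, 3)}], seed=4)
        assert sorted(new.names()) == sorted(o.names())

    def test_seeded_runs_reproducible(self):
        o = _order([(f"g{i}", 1) for i in range(10)])
        events = ["translocation", "inversion", "duplication_loss"]
        a, la = apply_rearrangements(o, events, seed=33)
        b, lb = apply_rearrangements(o, events, seed=33)
        assert a.symbols == b.symbols and la == lb
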