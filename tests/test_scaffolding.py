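"""Chimera calling, bridging, megascaffold construction and emission."""

import pytest

from omscaffold.align import MapAlignment
from omscaffold.digest import RestrictionMap
from omscaffold.scaffolding import (
    Bridge,
    Placement,
    assign_unique_map,
    build_bridges,
    call_chimeras,
    emit_agp,
    emit_fasta,
    extend_megascaffolds,
    filter_end_anchored,
    reverse_complement,
)


def make_alignment(
    sid,
    mid,
    score=20.0,
    q_range=(0, 10),
    m=10,
    t_range=(5, 15),
    n=100,
    orientation="forward",
    opt_bp=(50_000, 150_000),
    overhangs=(0, 0),
    end_anchored=True,
):
    return MapAlignment(
        scaffold_map_id=sid,
        optical_map_id=mid,
        orientation=orientation,
        blocks=[((q_range[0], q_range[1]), (t_range[0], t_range[1]))],
        score=score,
        scaffold_overhang_left=overhangs[0],
        scaffold_overhang_right=overhangs[1],
        optical_offset_start=t_range[0],
        optical_offset_end=t_range[1],
        optical_start_bp=opt_bp[0],
        optical_end_bp=opt_bp[1],
        n_scaffold_fragments=m,
        n_optical_fragments=n,
        end_anchored=end_anchored,
    )


class TestCallChimeras:
    def test_single_map_not_chimeric(self):
        calls = call_chimeras([make_alignment("s1", "m1")])
        assert len(calls) == 1 and not calls[0].is_chimeric

    def test_two_disjoint_parts_chimeric(self):
        alns = [
            make_alignment("s1", "m1", score=20, q_range=(0, 6), m=12),
            make_alignment("s1", "m2", score=15, q_range=(6, 12), m=12),
        ]
        calls = call_chimeras(alns)
        assert calls[0].is_chimeric
        assert calls[0].optical_maps_hit == {"m1", "m2"}

    def test_redundant_secondary_hit_not_chimeric(self):
        alns = [
            make_alignment("s1", "m1", score=20, q_range=(0, 11), m=12),
            make_alignment("s1", "m2", score=10, q_range=(2, 9), m=12),
        ]
        assert not call_chimeras(alns)[0].is_chimeric

    def test_no_confident_anchor_no_call(self):
        alns = [
            make_alignment("s1", "m1", score=7.0, q_range=(0, 4), m=8),
            make_alignment("s1", "m2", score=6.5, q_range=(4, 8), m=8),
        ]
        assert call_chimeras(alns) == []


class TestFilterAndAssign:
    def test_end_anchored_subset(self):
        alns = [
            make_alignment("s1", "m1", end_anchored=True),
            make_alignment("s2", "m1", end_anchored=False),
        ]
        assert [a.scaffold_map_id for a in filter_end_anchored(alns)] == ["s1"]

    def test_all_interior_empty(self):
        assert filter_end_anchored(
            [make_alignment("s1", "m1", end_anchored=False)]
        ) == []

    def test_largest_map_chosen(self):
        maps = [
            RestrictionMap("m30", "optical", [30_000_000]),
            RestrictionMap("m50", "optical", [50_000_000]),
        ]
        alns = [
            make_alignment("s1", "m30", score=15.0),
            make_alignment("s1", "m50", score=14.0),
        ]
        kept = assign_unique_map(alns, maps)
        assert {a.optical_map_id for a in kept} == {"m50"}

    def test_margin_protects_decisively_better_alignment(self):
        maps = [
            RestrictionMap("m30", "optical", [30_000_000]),
            RestrictionMap("m50", "optical", [50_000_000]),
        ]
        alns = [
            make_alignment("s1", "m30", score=20.0),
            make_alignment("s1", "m50", score=9.5),
        ]
        kept = assign_unique_map(alns, maps)
        assert {a.optical_map_id for a in kept} == {"m30"}

    def test_span_tie_breaks_lexicographically(self):
        maps = [
            RestrictionMap("mB", "optical", [40_000_000]),
            RestrictionMap("mA", "optical", [40_000_000]),
        ]
        alns = [make_alignment("s1", "mB"), make_alignment("s1", "mA")]
        assert {a.optical_map_id for a in assign_unique_map(alns, maps)} == {"mA"}

    def test_single_map_scaffold_unchanged(self):
        maps = [RestrictionMap("m1", "optical", [10_000_000])]
        alns = [make_alignment("s1", "m1")]
        assert assign_unique_map(alns, maps) == alns


class TestBuildBridges:
    def test_two_placements_gap_arithmetic(self):
        alns = [
            make_alignment("s1", "m1", opt_bp=(0, 10_000_000)),
            make_alignment("s2", "m1", opt_bp=(10_050_000, 22_000_000)),
        ]
        bridges = build_bridges(alns)
        assert len(bridges) == 1
        assert bridges[0].gaps == [50_000]
        assert [p.scaffold_id for p in bridges[0].placements] == ["s1", "s2"]

    def test_single_placement_no_bridge(self):
        assert build_bridges([make_alignment("s1", "m1")]) == []

    def test_deep_overlap_flagged(self):
        alns = [
            make_alignment("s1", "m1", opt_bp=(0, 10_000_000)),
            make_alignment("s2", "m1", opt_bp=(9_900_000, 22_000_000)),
        ]
        assert build_bridges(alns)[0].flagged == [True]


def simple_bridge(gap, overhangs_prev=(0, 0), overhangs_next=(0, 0)):
    p1 = Placement("s1", "forward", 0, 10_000_000, *overhangs_prev, 20.0)
    p2 = Placement(
        "s2", "forward", 10_000_000 + gap, 22_000_000 + gap, *overhangs_next, 20.0
    )
    return Bridge("m1", [p1, p2], [gap], [gap < -50_000])


LENGTHS = {"s1": 10_000_000, "s2": 12_000_000}


class TestExtendMegascaffolds:
    def test_clean_pair_joined(self):
        bridge = simple_bridge(50_000, (0, 10_000), (10_000, 0))
        megas, acc = extend_megascaffolds([bridge], LENGTHS)
        assert len(megas) == 1
        assert megas[0].components == [
            ("s1", "forward", 0),
            ("s2", "forward", 50_000),
        ]
        assert megas[0].total_span == 22_050_000
        assert acc.n_scaffolds_before == 2 and acc.n_scaffolds_after == 1

    def test_gap_cap_refuses_join(self):
        megas, acc = extend_megascaffolds([simple_bridge(2_500_000)], LENGTHS)
        assert megas == []
        assert acc.n_scaffolds_after == 2

    def test_overhang_cap_refuses_join(self):
        bridge = simple_bridge(1_900_000, (0, 1_500_000), (800_000, 0))
        megas, _ = extend_megascaffolds([bridge], LENGTHS)
        assert megas == []

    def test_tails_larger_than_gap_refuse_join(self):
        # 80 kb of unaligned tail cannot hide inside a 20 kb gap
        bridge = simple_bridge(20_000, (0, 60_000), (20_000, 0))
        megas, _ = extend_megascaffolds([bridge], LENGTHS)
        assert megas == []

    def test_negative_gap_gets_sentinel(self):
        megas, _ = extend_megascaffolds([simple_bridge(-20_000)], LENGTHS)
        assert megas[0].components[1][2] == 100

    def test_accounting_monotone(self):
        megas, acc = extend_megascaffolds([simple_bridge(50_000)], LENGTHS)
        assert acc.n_scaffolds_after <= acc.n_scaffolds_before
        assert acc.n50_after >= acc.n50_before


class TestEmission:
    def test_single_component_agp(self):
        megas, _ = extend_megascaffolds([simple_bridge(2_500_000)], LENGTHS)
        # force a single-component object through the writer
        from omscaffold.scaffolding import Megascaffold

        mega = Megascaffold("mega_x_0", [("s1", "forward", 0)], "m1", 10_000_000)
        rows = emit_agp([mega], LENGTHS)
        assert rows[0].startswith("##agp-version")
        assert rows[1].split("\t") == [
            "mega_x_0", "1", "10000000", "1", "W", "s1", "1", "10000000", "+",
        ]

    def test_two_components_and_gap(self):
        megas, _ = extend_megascaffolds([simple_bridge(50_000)], LENGTHS)
        rows = emit_agp(megas, LENGTHS)
        assert len(rows) == 4  # header + W + N + W
        gap_row = rows[2].split("\t")
        assert gap_row[4:9] == ["N", "50000", "map", "no", "na"]
        last = rows[3].split("\t")
        assert int(last[2]) == 10_000_000 + 50_000 + 12_000_000

    def test_unknown_component_rejected(self):
        from omscaffold.scaffolding import Megascaffold

        mega = Megascaffold("mega_x_0", [("nope", "forward", 0)], "m1", 1)
        with pytest.raises(KeyError):
            emit_agp([mega], LENGTHS)

    def test_fasta_single_forward_identity(self):
        from omscaffold.scaffolding import Megascaffold

        seqs = {"s1": "ACGTACGTAA"}
        mega = Megascaffold("m", [("s1", "forward", 0)], "m1", 10)
        assert emit_fasta([mega], seqs) == [("m", "ACGTACGTAA")]

    def test_fasta_single_reverse_is_revcomp(self):
        from omscaffold.scaffolding import Megascaffold

        seqs = {"s1": "ACGTACGTAA"}
        mega = Megascaffold("m", [("s1", "reverse", 0)], "m1", 10)
        assert emit_fasta([mega], seqs) == [("m", reverse_complement("ACGTACGTAA"))]

    def test_agp_fasta_round_trip(self):
        seqs = {"s1": "ACGT" * 2_500, "s2": "GGCC" * 3_000}
        lengths = {k: len(v) for k, v in seqs.items()}
        from omscaffold.scaffolding import Megascaffold

        mega = Megascaffold(
            "mega_m1_0",
            [("s1", "reverse", 0), ("s2", "forward", 120)],
            "m1",
            lengths["s1"] + 120 + lengths["s2"],
        )
        (name, fasta_seq), = emit_fasta([mega], seqs)
        rebuilt = {}
        for row in emit_agp([mega], lengths):
            if row.startswith("##"):
                continue
            cols = row.split("\t")
            obj, beg, end = cols[0], int(cols[1]), int(cols[2])
            if cols[4] == "W":
                comp = seqs[cols[5]][int(cols[6]) - 1 : int(cols[7])]
                if cols[8] == "-":
                    comp = reverse_complement(comp)
            else:
                comp = "N" * int(cols[5])
            rebuilt.setdefault(obj, []).append((beg, comp))
        reconstructed = "".join(c for _, c in sorted(rebuilt[name]))
        assert reconstructed == fasta_seq


class TestPipelineProperties:
    def test_partition_no_loss_no_duplication(self, noise_dataset, noise_result):
        all_ids = {rec.id for rec in noise_dataset.scaffolds}
        joined = [sid for m in noise_result.megascaffolds for sid in m.scaffold_ids]
        assert len(joined) == len(set(joined))  # each scaffold at most once
        assert set(joined) <= all_ids

    def test_accounting_monotone_on_simulation(self, noise_result):
        acc = noise_result.accounting
        assert acc.n_scaffolds_after <= acc.n_scaffolds_before
        assert acc.n50_after >= acc.n50_before

    def test_every_emitted_join_respects_caps(self, noise_result):
        placements = {}
        for bridge in noise_result.bridges:
            for p in bridge.placements:
                placements[p.scaffold_id] = p
        for mega in noise_result.megascaffolds:
            comps = mega.components
            for (a, _, _), (b, _, gap_before) in zip(comps, comps[1:]):
                assert 0 < gap_before < 2_000_000
                facing = placements[a].overhang_right + placements[b].overhang_left
                assert facing <= 2_000_000
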