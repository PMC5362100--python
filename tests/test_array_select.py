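"""Window selection: tiling argmax, fill-in, seeding, capacity, probes."""

import numpy as np
import pytest

from snparray import array_select
from snparray.array_select import (
    ArrayDesign,
    SelectionConfig,
    assemble_design,
    expected_snp_count,
    fillin_scan,
    primary_window_scan,
    probe_sequences,
)
from snparray.effect_annot import EffectClass, PrioritizedSNP, priority_level

from conftest import make_snp


def psnp(pos, priority=1, maf=0.25, scaffold="s1", must=False, ref="A", alt="G"):
    effect = {
        1: EffectClass.INTERGENIC,
        2: EffectClass.INTRON,
        3: EffectClass.SYNONYMOUS,
        4: EffectClass.MISSENSE,
    }[priority]
    return PrioritizedSNP(
        variant=make_snp(scaffold=scaffold, pos=pos, ref=ref, alt=alt, gts=[0, 1, 2]),
        effect=effect,
        priority=priority,
        maf=maf,
        must_include=must,
    )


class TestExpectedCount:
    @pytest.mark.parametrize(
        "length,expected",
        [(560_000_000, 200_000), (2800, 1), (7000, 2), (1, 1), (2799, 1)],
    )
    def test_floor_with_minimum_one(self, length, expected):
        assert expected_snp_count(length) == expected


class TestPrimaryScan:
    def test_single_candidate_selected(self):
        sel = primary_window_scan([psnp(1500)])
        assert [s.pos for s in sel] == [1500]

    def test_highest_priority_wins(self):
        sel = primary_window_scan([psnp(100, priority=3), psnp(200, priority=4)])
        assert [s.pos for s in sel] == [200]

    def test_maf_breaks_priority_ties(self):
        sel = primary_window_scan(
            [psnp(100, priority=4, maf=0.10), psnp(200, priority=4, maf=0.30)]
        )
        assert [s.pos for s in sel] == [200]

    def test_position_breaks_full_ties(self):
        sel = primary_window_scan(
            [psnp(200, priority=4, maf=0.3), psnp(100, priority=4, maf=0.3)]
        )
        assert [s.pos for s in sel] == [100]

    def test_windows_are_anchored_at_position_one(self):
        # 3000 and 3001 fall in different tiles
        sel = primary_window_scan([psnp(3000), psnp(3001)])
        assert [s.pos for s in sel] == [3000, 3001]

    def test_equivalence_with_exhaustive_argmax_oracle(self):
        """Random scaffolds <= 50 kb: per-window argmax by brute force."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(1, 200))
            cands = [
                psnp(
                    int(rng.integers(1, 50_001)),
                    priority=int(rng.integers(1, 5)),
                    maf=float(rng.choice([0.05, 0.1, 0.25, 0.4])),
                )
                for _ in range(n)
            ]
            got = primary_window_scan(cands, 3000)
            # oracle: for each tile enumerate members, take max directly
            windows = sorted({(c.pos - 1) // 3000 for c in cands})
            want = []
            for w in windows:
                members = [c for c in cands if (c.pos - 1) // 3000 == w]
                want.append(
                    max(members, key=lambda c: (c.priority, c.maf, -c.pos))
                )
            assert [(s.pos, s.priority) for s in got] == [
                (s.pos, s.priority) for s in want
            ]
            # invariant: one selected marker per tile, maximal priority in tile
            tiles = [(s.pos - 1) // 3000 for s in got]
            assert len(set(tiles)) == len(tiles)
            for s in got:
                tile = (s.pos - 1) // 3000
                assert s.priority == max(
                    c.priority for c in cands if (c.pos - 1) // 3000 == tile
                )


class TestFillin:
    def test_no_deficit_no_addition(self):
        sel = [psnp(1000), psnp(4000)]
        assert fillin_scan([psnp(1500)], sel, 5600) == []

    def test_deficit_two_takes_two_best(self):
        selected = [psnp(100, priority=4)]
        cands = [
            psnp(1500, priority=2, maf=0.4),
            psnp(2500, priority=3, maf=0.1),
            psnp(3500, priority=1, maf=0.2),
        ]
        added = fillin_scan(cands, selected, 8400, expected=3)
        # deficit 2: best-ranked are the priority-3 then priority-2 candidates
        assert sorted(s.pos for s in added) == [1500, 2500]
        # oracle: brute-force best pair under the one-per-window constraint
        assert {s.pos for s in added} == {2500, 1500}

    def test_candidates_in_occupied_windows_excluded(self):
        selected = [psnp(150)]
        added = fillin_scan([psnp(900)], selected, 2900, expected=2)
        assert added == []  # window 0 already holds a marker

    def test_deficit_larger_than_supply(self):
        added = fillin_scan([psnp(1500)], [psnp(100)], 28_000, expected=6)
        assert [s.pos for s in added] == [1500]

    def test_left_to_right_order_option(self):
        selected = []
        cands = [psnp(2500, priority=4), psnp(500, priority=1)]
        added = fillin_scan(cands, selected, 3000, expected=1, by_quality=False)
        assert [s.pos for s in added] == [500]


class TestAssemble:
    def test_must_include_beats_better_rival_in_window(self):
        rival = psnp(200, priority=4, maf=0.4)
        wanted = psnp(100, priority=1, maf=0.05)
        design = assemble_design([rival, wanted], [wanted.marker_id])
        assert wanted.marker_id in design.marker_ids
        assert rival.marker_id in design.marker_ids  # rival still best of its tile

    def test_unknown_must_include_id_fails_listing_it(self):
        with pytest.raises(ValueError, match="s1:999"):
            assemble_design([psnp(100)], ["s1:999"])

    def test_capacity_trim_drops_worst_non_must(self):
        cands = [
            psnp(1 + 3000 * i, priority=(i % 4) + 1, maf=0.1 + 0.02 * i)
            for i in range(12)
        ]
        must_ids = [cands[0].marker_id, cands[4].marker_id]
        cfg = SelectionConfig(capacity=10)
        design = assemble_design(cands, must_ids, cfg)
        assert len(design) == 10
        assert set(must_ids) <= set(design.marker_ids)
        # the two worst non-must markers (lowest priority, then MAF) are gone
        droppable = sorted(
            (c for c in cands if c.marker_id not in must_ids),
            key=lambda c: (c.priority, c.maf),
        )
        dropped = {droppable[0].marker_id, droppable[1].marker_id}
        assert dropped.isdisjoint(design.marker_ids)

    def test_duplicate_site_submitted_twice_kept_once(self):
        a, b = psnp(100, priority=2), psnp(100, priority=4)
        design = assemble_design([a, b], [])
        assert len(design) == 1
        assert design.markers[0].priority == 4

    def test_large_effect_snps_are_seeded(self):
        large = PrioritizedSNP(
            variant=make_snp(pos=200, gts=[0, 1, 2]),
            effect=EffectClass.STOP_GAINED,
            priority=4,
            maf=0.06,
        )
        rival = psnp(300, priority=4, maf=0.5)
        design = assemble_design([large, rival], [])
        assert large.marker_id in design.marker_ids

    def test_determinism_byte_identical(self, small_world):
        genome, genes, variants, _ = small_world
        from snparray import effect_annot, site_filter

        passing, stats = site_filter.apply_site_filters(variants)
        snps = [v for v in variants if v.vclass.value == "SNP"]
        maf = {v.marker_id: st.maf for v, st in zip(snps, stats)}
        pri = effect_annot.prioritize(
            passing, [maf[v.marker_id] for v in passing], genes, genome
        )
        lengths = {k: len(v) for k, v in genome.items()}
        d1 = assemble_design(pri, [], SelectionConfig(), lengths)
        d2 = assemble_design(list(pri), [], SelectionConfig(), lengths)
        probe_sequences(d1, genome)
        probe_sequences(d2, genome)
        assert d1.to_frame().to_csv() == d2.to_frame().to_csv()

    def test_primary_tile_uniqueness_invariant(self, small_world):
        genome, genes, variants, _ = small_world
        from snparray import effect_annot, site_filter

        passing, stats = site_filter.apply_site_filters(variants)
        snps = [v for v in variants if v.vclass.value == "SNP"]
        maf = {v.marker_id: st.maf for v, st in zip(snps, stats)}
        pri = effect_annot.prioritize(
            passing, [maf[v.marker_id] for v in passing], genes, genome
        )
        sel = primary_window_scan(
            sorted((p for p in pri if p.scaffold_id == "scaffold_1"),
                   key=lambda s: s.pos)
        )
        tiles = [(s.pos - 1) // 3000 for s in sel]
        assert len(tiles) == len(set(tiles))


class TestDesignObject:
    def test_requires_sorted_unique_markers(self):
        with pytest.raises(ValueError, match="sorted"):
            ArrayDesign([psnp(200), psnp(100)])
        with pytest.raises(ValueError, match="duplicate"):
            ArrayDesign([psnp(100), psnp(100, priority=2)])


class TestProbes:
    def test_interior_snp_71_char_template(self, small_world):
        genome, _, _, _ = small_world
        m = psnp(5000, scaffold="scaffold_1",
                 ref=genome["scaffold_1"][4999],
                 alt="A" if genome["scaffold_1"][4999] != "A" else "C")
        design = ArrayDesign([m])
        probes = probe_sequences(design, genome)
        probe = probes[m.marker_id]
        assert len(probe) == 71 + 4  # 70 flank bases + "[X/Y]"
        assert probe[35:40] == f"[{m.variant.ref_allele}/{m.variant.alt_allele}]"

    def test_edge_snp_truncated_flank(self, small_world):
        genome, _, _, _ = small_world
        ref = genome["scaffold_1"][9]
        m = psnp(10, scaffold="scaffold_1", ref=ref,
                 alt="A" if ref != "A" else "C")
        probes = probe_sequences(ArrayDesign([m]), genome)
        left = probes[m.marker_id].split("[")[0]
        assert len(left) == 9

    def test_probe_center_matches_genome_ref(self, small_world):
        genome, _, _, _ = small_world
        rng = np.random.default_rng(4)
        markers = []
        for pos in sorted(rng.choice(np.arange(100, 50_000), 30, replace=False)):
            ref = genome["scaffold_2"][pos - 1]
            alt = "A" if ref != "A" else "C"
            markers.append(psnp(int(pos), scaffold="scaffold_2", ref=ref, alt=alt))
        probes = probe_sequences(ArrayDesign(markers), genome)
        for m in markers:
            left, rest = probes[m.marker_id].split("[")
            assert rest.split("/")[0] == genome["scaffold_2"][m.pos - 1]
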