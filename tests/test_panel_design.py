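"""Panel tiling, candidate screening, oligo grammar, and codebook tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromtrace.panel_design import (
    DEFAULT_REGION,
    CandidateTarget,
    GenomicInterval,
    KmerIndex,
    PanelDesignError,
    assemble_template_oligo,
    build_codebook,
    design_adapter_oligo,
    design_probes,
    extract_candidate_targets,
    filter_repetitive,
    generate_oligo_pool,
    parse_template_oligo,
    partition_region,
    reverse_complement,
    select_probes,
)
from conftest import random_sequence


class TestPartition:
    def test_traced_region_yields_42_segments(self):
        panel = partition_region(DEFAULT_REGION, 50_000)
        assert panel.n_segments == 42
        assert panel.remainder_bp == 0
        assert panel.segments[0].interval.start == 23_500_000
        assert panel.segments[-1].interval.end == 25_600_000

    def test_single_tile(self):
        panel = partition_region(GenomicInterval("chrT", 0, 50_000), 50_000)
        assert panel.n_segments == 1

    def test_remainder_dropped_and_reported(self):
        with pytest.warns(UserWarning, match="25000-bp remainder"):
            panel = partition_region(GenomicInterval("chrT", 0, 125_000), 50_000)
        assert panel.n_segments == 2
        assert panel.remainder_bp == 25_000

    def test_region_shorter_than_segment_is_error(self):
        with pytest.raises(PanelDesignError):
            partition_region(GenomicInterval("chrT", 0, 10_000), 50_000)

    @pytest.mark.filterwarnings("ignore:dropped")
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(span=st.integers(50_000, 5_000_000), start=st.integers(0, 10_000_000))
    def test_count_law_and_tiling(self, span, start):
        panel = partition_region(GenomicInterval("chrT", start, start + span), 50_000)
        assert panel.n_segments == span // 50_000
        # exact tiling: consecutive, disjoint, gap-free from region start
        for i, seg in enumerate(panel.segments):
            assert seg.interval.start == start + i * 50_000
            assert len(seg.interval) == 50_000


class TestCandidates:
    def test_nonoverlapping_enumeration_count(self):
        # brute-force expectation: floor(50000 / 30) windows at 30-nt stride
        seq = random_sequence(50_000, seed=11)
        cands = extract_candidate_targets(seq, min_gap=30, gc_range=None, max_homopolymer=None)
        assert len(cands) == 50_000 // 30 == 1666
        offsets = np.array([c.offset for c in cands])
        assert (np.diff(offsets) >= 30).all()

    def test_too_short_sequence(self):
        with pytest.warns(UserWarning):
            assert extract_candidate_targets("A" * 29) == []

    def test_homopolymer_filter_rejects_all_a(self):
        assert extract_candidate_targets("A" * 2000, max_homopolymer=10, gc_range=None) == []

    def test_non_acgt_windows_skipped(self):
        seq = random_sequence(60, seed=3) + "N" + random_sequence(60, seed=4)
        cands = extract_candidate_targets(seq, gc_range=None, max_homopolymer=None)
        assert all("N" not in c.sequence for c in cands)

    def test_gc_recorded(self):
        cands = extract_candidate_targets("ACGT" * 30, gc_range=None, max_homopolymer=None)
        assert cands and all(c.gc_fraction == 0.5 for c in cands)


def brute_force_max_hits(target: str, genome: str, k: int) -> int:
    """Independent oracle: count occurrences of each window by string scan."""
    best = 0
    for i in range(len(target) - k + 1):
        sub = target[i : i + k]
        count = start = 0
        while True:
            j = genome.find(sub, start)
            if j < 0:
                break
            count += 1
            start = j + 1
        best = max(best, count)
    return best


class TestRepeatFilter:
    def test_unique_genome_retains_all(self):
        seq = random_sequence(50_000, seed=5)
        idx = KmerIndex({"chrT": seq}, k=17)
        cands = extract_candidate_targets(seq, gc_range=None, max_homopolymer=None)
        kept = filter_repetitive(cands, idx, max_hits=1)
        assert len(kept) == len(cands)
        assert all(c.max_subkmer_hits == 1 for c in kept)

    def test_duplicated_block_removed_matches_brute_force(self):
        rng = np.random.default_rng(7)
        base = random_sequence(20_000, seed=8)
        block = random_sequence(1_000, seed=9)
        genome = base[:5_000] + block + base[5_000:10_000] + 4 * block + base[10_000:]
        idx = KmerIndex({"chrT": genome}, k=17)
        cands = extract_candidate_targets(genome[:12_000], gc_range=None, max_homopolymer=None)
        kept = filter_repetitive(cands, idx, max_hits=1)
        kept_offsets = {c.offset for c in kept}
        for c in cands:
            expected = brute_force_max_hits(c.sequence, genome, 17) <= 1
            assert (c.offset in kept_offsets) == expected

    def test_absent_kmer_scores_zero(self):
        idx = KmerIndex({"chrT": random_sequence(1_000, seed=1)}, k=17)
        foreign = CandidateTarget(0, 0, "TTTTTTTTTTTTTTTTTTTTTTTTTTTTTT")
        kept = filter_repetitive([foreign], idx, max_hits=1)
        assert kept[0].max_subkmer_hits == 0

    def test_empty_genome_is_error(self):
        with pytest.raises(PanelDesignError):
            KmerIndex({"chrT": "NNNN"}, k=17)


class TestSelection:
    def _candidates(self, n, seed=0):
        rng = np.random.default_rng(seed)
        offsets = np.sort(rng.choice(49_970, size=n, replace=False))
        return [CandidateTarget(0, int(o), "A" * 30) for o in offsets]

    def test_exact_count_when_plenty(self):
        sel = select_probes(self._candidates(1666), n_per_segment=500)
        assert len(sel) == 500

    def test_all_selected_with_warning_when_scarce(self):
        with pytest.warns(UserWarning):
            sel = select_probes(self._candidates(100), n_per_segment=500)
        assert len(sel) == 100

    def test_deterministic(self):
        a = select_probes(self._candidates(1200, seed=3), 500)
        b = select_probes(self._candidates(1200, seed=3), 500)
        assert [c.offset for c in a] == [c.offset for c in b]

    def test_selection_spans_segment(self):
        sel = select_probes(self._candidates(1666), 500)
        offs = [c.offset for c in sel]
        assert offs[0] == min(offs) and offs[-1] == max(offs)
        assert len(set(offs)) == 500


class TestOligoGrammar:
    def _parts(self, seed=0):
        pool = generate_oligo_pool(5, seed=seed)
        return pool[0], pool[1], pool[2:5]

    def test_template_length_and_roundtrip(self):
        fwd, rev, sites = self._parts()
        target = CandidateTarget(0, 0, random_sequence(30, seed=2))
        oligo = assemble_template_oligo(target, fwd, rev, sites)
        assert len(oligo.full_sequence) == sum((20, 20, 30, 20, 20, 20)) == 130
        assert parse_template_oligo(oligo.full_sequence) == oligo.parts
        assert oligo.parts[5] == reverse_complement(rev)

    def test_wrong_component_length_names_component(self):
        fwd, rev, sites = self._parts()
        target = CandidateTarget(0, 0, random_sequence(30, seed=2))
        with pytest.raises(PanelDesignError, match="fwd_primer"):
            assemble_template_oligo(target, "ACGT", rev, sites)
        with pytest.raises(PanelDesignError, match="target"):
            assemble_template_oligo(CandidateTarget(0, 0, "ACGT"), fwd, rev, sites)

    def test_segment_oligos_share_readout_sites(self):
        fwd, rev, sites = self._parts()
        t1 = assemble_template_oligo(CandidateTarget(3, 0, random_sequence(30, 5)), fwd, rev, sites)
        t2 = assemble_template_oligo(CandidateTarget(3, 90, random_sequence(30, 6)), fwd, rev, sites)
        assert (t1.parts[1], t1.parts[3], t1.parts[4]) == (t2.parts[1], t2.parts[3], t2.parts[4])

    def test_adapter_structure(self):
        pool = generate_oligo_pool(2, seed=4)
        ad = design_adapter_oligo(pool[0], pool[1], segment_index=7)
        assert len(ad.full_sequence) == 60
        assert ad.full_sequence[20:40] == ad.full_sequence[40:60]
        assert ad.primary_binding == reverse_complement(pool[0])


class TestCodebook:
    def test_42_segments_two_channels_21_rounds(self, full_panel):
        assert full_panel.n_rounds == 21
        assert full_panel.n_channels == 2

    def test_single_segment(self):
        panel = build_codebook(partition_region(GenomicInterval("chrT", 0, 50_000), 50_000))
        assert panel.n_rounds == 1
        assert panel.locus_for(0, "647") == 0
        assert panel.locus_for(0, "560") is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(n_segments=st.integers(1, 64), n_channels=st.integers(1, 4))
    def test_codebook_bijection(self, n_segments, n_channels):
        panel = partition_region(GenomicInterval("chrT", 0, n_segments * 50_000), 50_000)
        panel = build_codebook(panel, n_channels, [f"c{i}" for i in range(n_channels)])
        slots = {(s.hyb_round, s.channel) for s in panel.segments}
        assert len(slots) == n_segments  # injective
        assert panel.n_rounds == -(-n_segments // n_channels)
        assert all(s.hyb_round == s.index // n_channels for s in panel.segments)


class TestOligoPool:
    def test_pairwise_distance_constraints(self):
        pool = generate_oligo_pool(12, seed=1, min_hamming=8)
        for i, a in enumerate(pool):
            for b in pool[i + 1 :]:
                assert sum(x != y for x, y in zip(a, b)) >= 8
                rc = reverse_complement(a)
                assert sum(x != y for x, y in zip(rc, b)) >= 8


class TestFullDesign:
    def test_design_probes_on_toy_genome(self, toy_panel):
        genome = {"chrT": random_sequence(500_000, seed=21)}
        probes = design_probes(genome, toy_panel, n_per_segment=40, seed=0)
        assert len(probes.template_oligos) == 40 * toy_panel.n_segments
        assert len(probes.adapter_oligos) == toy_panel.n_segments
        # adapter routes the segment's first readout site to its channel readout
        for seg in toy_panel.segments:
            ad = probes.adapter_oligos[seg.index]
            site = probes.readout_sites[seg.index][0]
            assert ad.primary_binding == reverse_complement(site)
            assert ad.readout_binding == probes.channel_readouts[seg.channel]
        # two segments of one round, different channels: distinct readouts
        r0 = [a for a, s in zip(probes.adapter_oligos, toy_panel.segments) if s.hyb_round == 0]
        assert r0[0].readout_binding != r0[1].readout_binding
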