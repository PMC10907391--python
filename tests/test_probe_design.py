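"""Probe-design rules: site enumeration, off-target screening, probe-set
selection, readout generation, and oligo assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fishcoder as fc
from fishcoder.probe_design import (
    DEFAULT_FWD_PRIMER,
    DEFAULT_REV_PRIMER,
    ReadoutCapacityError,
    parse_full_sequence,
)
from oracles import site_survives_bruteforce

CFG = fc.DesignConfig(rng_seed=0)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.mark.parametrize(
    "length,expected",
    [(100, 73), (28, 1), (27, 0)],
)
def test_site_enumeration_window_count(length, expected):
    rng = np.random.default_rng(0)
    t = fc.TranscriptRecord("t", random_seq(rng, length))
    sites, warnings = fc.enumerate_targeting_sites(t, CFG)
    assert len(sites) == expected
    if expected == 0:
        assert warnings  # degenerate transcript is flagged, not dropped
    else:
        assert not warnings
        assert sites[0].start == 0
        assert all(
            s.target_seq == t.sequence[s.start : s.start + 28] for s in sites
        )


def test_site_28nt_transcript_yields_itself():
    rng = np.random.default_rng(1)
    seq = random_seq(rng, 28)
    sites, _ = fc.enumerate_targeting_sites(fc.TranscriptRecord("t", seq), CFG)
    assert sites[0].target_seq == seq


class TestOffTargetScreen:
    def test_planted_17mer_removed_16mer_retained(self):
        rng = np.random.default_rng(2)
        target = random_seq(rng, 28)
        decoy_17 = fc.TranscriptRecord("d17", random_seq(rng, 50) + target[:17] + random_seq(rng, 50))
        decoy_16 = fc.TranscriptRecord("d16", random_seq(rng, 50) + target[:16] + random_seq(rng, 50))
        site = fc.CandidateSite("g", 0, target)
        kept, _ = fc.screen_off_targets([site], [decoy_17], CFG)
        assert kept == [] or not site_survives_bruteforce(target, [decoy_17.sequence], 17)
        assert kept == []
        kept, _ = fc.screen_off_targets([site], [decoy_16], CFG)
        # a 16-nt shared substring is strictly below the 17-nt threshold
        if site_survives_bruteforce(target, [decoy_16.sequence], 17):
            assert kept == [site]

    def test_revcomp_segment_removed(self):
        rng = np.random.default_rng(3)
        target = random_seq(rng, 28)
        decoy = fc.TranscriptRecord("d", fc.revcomp(target))
        kept, _ = fc.screen_off_targets([fc.CandidateSite("g", 0, target)], [decoy], CFG)
        assert kept == []

    def test_empty_background_passes_with_warning(self):
        site = fc.CandidateSite("g", 0, "A" * 28)
        kept, warnings = fc.screen_off_targets([site], [], CFG)
        assert kept == [site]
        assert any("unscreened" in w or "empty" in w for w in warnings)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            transcripts = [
                fc.TranscriptRecord(f"g{i}", random_seq(rng, 120)) for i in range(8)
            ]
            decoys = [
                fc.TranscriptRecord(f"d{i}", random_seq(rng, 300)) for i in range(4)
            ]
            # plant partial homology so both outcomes occur
            frag = transcripts[0].sequence[10:30]
            decoys.append(fc.TranscriptRecord("dplant", random_seq(rng, 40) + frag))
            bg = [d.sequence for d in decoys]
            for t in transcripts:
                sites, _ = fc.enumerate_targeting_sites(t, CFG)
                kept, _ = fc.screen_off_targets(sites, decoys, CFG)
                expected = [
                    s
                    for s in sites
                    if site_survives_bruteforce(s.target_seq, bg, CFG.offtarget_k)
                ]
                assert kept == expected

    def test_raising_k_never_removes_survivors(self):
        rng = np.random.default_rng(5)
        t = fc.TranscriptRecord("g", random_seq(rng, 200))
        decoys = [fc.TranscriptRecord("d", t.sequence[40:90] + random_seq(rng, 100))]
        sites, _ = fc.enumerate_targeting_sites(t, CFG)
        counts = []
        for k in (15, 17, 19, 22, 28):
            cfg = fc.DesignConfig(offtarget_k=k)
            counts.append(len(fc.screen_off_targets(sites, decoys, cfg)[0]))
        assert counts == sorted(counts)


class TestSelectProbeSet:
    def _clean_sites(self, length, seed=0):
        rng = np.random.default_rng(seed)
        t = fc.TranscriptRecord("g", random_seq(rng, length))
        sites, _ = fc.enumerate_targeting_sites(t, CFG)
        return sites

    def test_long_clean_transcript_capped_at_32(self):
        selected, flag = fc.select_probe_set(self._clean_sites(5000), CFG)
        assert len(selected) == 32 and not flag
        starts = sorted(s.start for s in selected)
        assert all(b - a >= 28 for a, b in zip(starts, starts[1:]))

    def test_600nt_transcript_above_minimum(self):
        # maximal non-overlapping packing of 28-mers in 600 nt is 21
        selected, flag = fc.select_probe_set(self._clean_sites(600), CFG)
        assert 17 <= len(selected) <= 21 and not flag

    def test_short_transcript_flagged(self):
        selected, flag = fc.select_probe_set(self._clean_sites(100), CFG)
        assert len(selected) <= 3 and flag


class TestReadouts:
    def test_gc_and_length_recount(self):
        ros = fc.generate_readout_oligos(8, [], CFG)
        for ro in ros:
            assert len(ro.sequence) == 18
            gc = sum(c in "GC" for c in ro.sequence) / 18
            assert 0.40 <= gc <= 0.60
        assert len({ro.sequence for ro in ros}) == 8

    def test_pairwise_kmer_independence(self):
        ros = fc.generate_readout_oligos(12, [], CFG)
        from oracles import shares_kmer_bruteforce, revcomp as rc

        for i, a in enumerate(ros):
            for b in ros[i + 1 :]:
                assert not shares_kmer_bruteforce(a.sequence, b.sequence, 10)
                assert not shares_kmer_bruteforce(a.sequence, rc(b.sequence), 10)

    def test_planted_10mer_rejected_9mer_tolerated(self):
        ros = fc.generate_readout_oligos(5, [], CFG)
        bg10 = [fc.TranscriptRecord("b", "AAAC" * 20 + ros[0].sequence[:10] + "GGTT" * 20)]
        again = fc.generate_readout_oligos(5, bg10, CFG)
        from oracles import shares_kmer_bruteforce, revcomp as rc

        for ro in again:
            assert not shares_kmer_bruteforce(ro.sequence, bg10[0].sequence, 10)
            assert not shares_kmer_bruteforce(ro.sequence, rc(bg10[0].sequence), 10)

    def test_deterministic_given_seed(self):
        a = fc.generate_readout_oligos(6, [], fc.DesignConfig(rng_seed=42))
        b = fc.generate_readout_oligos(6, [], fc.DesignConfig(rng_seed=42))
        assert [r.sequence for r in a] == [r.sequence for r in b]
        c = fc.generate_readout_oligos(6, [], fc.DesignConfig(rng_seed=43))
        assert [r.sequence for r in a] != [r.sequence for r in c]

    def test_capacity_error_names_dominant_constraint(self):
        # an impossible GC window cannot be satisfied
        cfg = fc.DesignConfig(gc_min=0.98, gc_max=0.99, rng_seed=0)
        with pytest.raises(ReadoutCapacityError, match="gc"):
            fc.generate_readout_oligos(2, [], cfg, max_tries_per_oligo=500)


class TestAssembly:
    def _parts(self):
        rng = np.random.default_rng(6)
        site = fc.CandidateSite("g", 5, random_seq(rng, 28))
        ros = fc.generate_readout_oligos(4, [], CFG)
        return site, ros

    def test_layout_length_and_roundtrip(self):
        site, ros = self._parts()
        fwd, rev = DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER
        (probe,) = fc.assemble_probes([site], ros, (fwd, rev), CFG)
        assert len(probe.full_sequence) == 20 + 18 * 2 + 28 + 18 * 2 + 20
        assert probe.full_sequence.startswith(fwd + ros[0].sequence + ros[1].sequence)
        assert probe.full_sequence.endswith(ros[2].sequence + ros[3].sequence + rev)
        assert len(probe.targeting_region) == 28
        # parsing the oligo recovers the transcript window
        assert parse_full_sequence(probe.full_sequence, (20, 20), CFG) == site.target_seq

    def test_targeting_region_base_pairs_with_transcript(self):
        site, ros = self._parts()
        (probe,) = fc.assemble_probes([site], ros, ("AAAA", "TTTT"), CFG)
        assert fc.revcomp(probe.targeting_region) == site.target_seq

    def test_wrong_readout_count_is_hard_error(self):
        site, ros = self._parts()
        with pytest.raises(ValueError, match="readouts"):
            fc.assemble_probes([site], ros[:3], ("AAAA", "TTTT"), CFG)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_screen_soundness_property(seed):
    """k-mer index screen agrees exactly with all-substring brute force."""
    rng = np.random.default_rng(seed)
    t = fc.TranscriptRecord("g", random_seq(rng, 80))
    decoys = [fc.TranscriptRecord(f"d{i}", random_seq(rng, 60)) for i in range(2)]
    # half the time plant an overlap to exercise removals
    if seed % 2:
        decoys.append(
            fc.TranscriptRecord("dp", t.sequence[20:40] + random_seq(rng, 20))
        )
    sites, _ = fc.enumerate_targeting_sites(t, CFG)
    kept, _ = fc.screen_off_targets(sites, decoys, CFG)
    bg = [d.sequence for d in decoys]
    expected = [
        s for s in sites if site_survives_bruteforce(s.target_seq, bg, 17)
    ]
    assert kept == expected


def test_design_probe_library_end_to_end():
    transcripts = fc.synthetic_transcripts([f"g{i}" for i in range(5)], 1500, rng_seed=0)
    decoys = fc.synthetic_transcripts([f"d{i}" for i in range(3)], 1500, rng_seed=1)
    designs = fc.design_probe_library(transcripts, decoys, CFG)
    assert len(designs) == 5
    for d in designs:
        assert 17 <= len(d.probes) <= 32
        assert not d.below_minimum
        ids = {p.readout_ids for p in d.probes}
        assert len(ids) == 1  # all probes of a gene share the same 4 readouts
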