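"""Encoding-probe design for combinatorial single-molecule FISH.

Each encoding probe carries a 28-nt region complementary to its target
mRNA, four 18-nt readout-binding sequences (two on each side of the
targeting region), and two PCR primer flanks.  Targeting regions are
screened against a background transcriptome by exact shared-substring
homology (k-mer sharing on both strands); readout sequences are generated
by seeded rejection sampling under GC and cross-homology constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases in ``seq``."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class TranscriptRecord:
    """One target transcript (mRNA sense strand, ACGT alphabet)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.gene_id}: empty sequence")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"{self.gene_id}: non-ACGT characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DesignConfig:
    """Probe-design rule set.

    Defaults encode the standard design: 28-nt targets, four 18-nt
    readouts per probe, 17-32 probes per gene, readout GC in [0.40,
    0.60], 17-nt off-target homology threshold for targeting regions and
    a 10-nt threshold for readout sequences.
    """

    target_len: int = 28
    readout_len: int = 18
    readouts_per_probe: int = 4
    min_probes: int = 17
    max_probes: int = 32
    gc_min: float = 0.40
    gc_max: float = 0.60
    offtarget_k: int = 17
    readout_k: int = 10
    rng_seed: int = 0
    # optional GC window on targeting regions; off by default
    target_gc_min: float | None = None
    target_gc_max: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_min < self.gc_max < 1.0):
            raise ValueError("require 0 < gc_min < gc_max < 1")
        if self.min_probes > self.max_probes:
            raise ValueError("min_probes must not exceed max_probes")
        if self.offtarget_k > self.target_len:
            raise ValueError("offtarget_k must not exceed target_len")
        if self.readout_k > self.readout_len:
            raise ValueError("readout_k must not exceed readout_len")


@dataclass(frozen=True)
class CandidateSite:
    """One candidate probe-binding window on a transcript."""

    gene_id: str
    start: int
    target_seq: str


@dataclass(frozen=True)
class ReadoutOligo:
    """A readout sequence and the (round, channel) pseudocolor it reports."""

    readout_id: int
    sequence: str
    pseudocolor: tuple[int, int]


@dataclass(frozen=True)
class EncodingProbe:
    """Assembled encoding oligo.

    Layout: fwd_primer | readout0 | readout1 | revcomp(target) |
    readout2 | readout3 | rev_primer.  The targeting region is the
    reverse complement of the transcript window so the probe hybridizes
    to the mRNA.
    """

    gene_id: str
    site: CandidateSite
    readout_ids: tuple[int, ...]
    fwd_primer: str
    rev_primer: str
    full_sequence: str

    @property
    def targeting_region(self) -> str:
        """The probe's mRNA-complementary segment."""
        return revcomp(self.site.target_seq)


# Arbitrary screened 20-mer amplification flanks used when the caller
# supplies none (the layout, not the primer identity, matters here).
DEFAULT_FWD_PRIMER = "CGGCTCGCAGCGTGTAAACG"
DEFAULT_REV_PRIMER = "CGATGCGCCAATTCCGGTTC"


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]


def build_kmer_index(records: Sequence[TranscriptRecord], k: int) -> set[str]:
    """Hash index of all k-mers on both strands of ``records``."""
    index: set[str] = set()
    for rec in records:
        index.update(_kmers(rec.sequence, k))
        index.update(_kmers(revcomp(rec.sequence), k))
    return index


def enumerate_targeting_sites(
    transcript: TranscriptRecord, cfg: DesignConfig
) -> tuple[list[CandidateSite], list[str]]:
    """All sliding windows of length ``cfg.target_len`` in 5'->3' order.

    Returns (sites, warnings); a transcript shorter than the target
    length yields no sites and a warning record instead of an error.
    """
    L, t = len(transcript), cfg.target_len
    if L < t:
        return [], [f"{transcript.gene_id}: length {L} < target_len {t}; no sites"]
    sites = [
        CandidateSite(transcript.gene_id, i, transcript.sequence[i : i + t])
        for i in range(L - t + 1)
    ]
    return sites, []


def screen_off_targets(
    sites: Sequence[CandidateSite],
    background: Sequence[TranscriptRecord],
    cfg: DesignConfig,
    index: set[str] | None = None,
) -> tuple[list[CandidateSite], list[str]]:
    """Remove sites sharing an exact substring of length >= ``offtarget_k``
    with any background sequence or its reverse complement.

    A shared substring of length >= k exists iff a k-mer is shared, so a
    both-strand k-mer hash index decides the screen exactly.  An empty
    background passes everything and is logged as unscreened.
    """
    warnings: list[str] = []
    if not background and index is None:
        warnings.append("off-target screen skipped: empty background")
        return list(sites), warnings
    if index is None:
        index = build_kmer_index(background, cfg.offtarget_k)
    survivors = [
        s
        for s in sites
        if not any(km in index for km in _kmers(s.target_seq, cfg.offtarget_k))
    ]
    return survivors, warnings


def select_probe_set(
    surviving_sites: Sequence[CandidateSite], cfg: DesignConfig
) -> tuple[list[CandidateSite], bool]:
    """Pick up to ``max_probes`` non-overlapping sites, evenly spaced.

    Greedy left-to-right packing yields the maximal non-overlapping set;
    if it exceeds ``max_probes``, an evenly spaced subset is kept.
    Returns (selected, below_minimum_flag).  Genes with fewer than
    ``min_probes`` selectable sites are flagged, never dropped.
    """
    sites = sorted(surviving_sites, key=lambda s: s.start)
    packed: list[CandidateSite] = []
    next_free = -1
    for s in sites:
        if s.start >= next_free:
            packed.append(s)
            next_free = s.start + cfg.target_len
    if len(packed) > cfg.max_probes:
        idx = np.linspace(0, len(packed) - 1, cfg.max_probes).round().astype(int)
        packed = [packed[i] for i in sorted(set(idx.tolist()))]
    if cfg.target_gc_min is not None or cfg.target_gc_max is not None:
        lo = cfg.target_gc_min if cfg.target_gc_min is not None else 0.0
        hi = cfg.target_gc_max if cfg.target_gc_max is not None else 1.0
        packed = [s for s in packed if lo <= gc_fraction(s.target_seq) <= hi]
    return packed, len(packed) < cfg.min_probes


class ReadoutCapacityError(RuntimeError):
    """Raised when rejection sampling cannot find enough readouts."""


def generate_readout_oligos(
    n: int,
    background: Sequence[TranscriptRecord],
    cfg: DesignConfig,
    pseudocolors: Sequence[tuple[int, int]] | None = None,
    max_tries_per_oligo: int = 20_000,
) -> list[ReadoutOligo]:
    """Rejection-sample ``n`` distinct readout sequences.

    Acceptance requires GC within [gc_min, gc_max] and no shared
    substring of length >= ``readout_k`` with the background (both
    strands) or with any previously accepted readout (both strands).
    Deterministic given ``cfg.rng_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.rng_seed)
    forbidden = build_kmer_index(background, cfg.readout_k)
    rejections = {"gc": 0, "background_kmer": 0, "cross_readout_kmer": 0}
    accepted: list[ReadoutOligo] = []
    accepted_kmers: set[str] = set()
    bases = np.array(list("ACGT"))
    budget = n * max_tries_per_oligo
    tries = 0
    while len(accepted) < n:
        if tries >= budget:
            dominant = max(rejections, key=rejections.get)  # type: ignore[arg-type]
            raise ReadoutCapacityError(
                f"found {len(accepted)}/{n} readouts in {tries} tries; "
                f"dominant rejection cause: {dominant} ({rejections})"
            )
        tries += 1
        seq = "".join(bases[rng.integers(0, 4, cfg.readout_len)])
        if not (cfg.gc_min <= gc_fraction(seq) <= cfg.gc_max):
            rejections["gc"] += 1
            continue
        kms = list(_kmers(seq, cfg.readout_k))
        if any(km in forbidden for km in kms):
            rejections["background_kmer"] += 1
            continue
        if any(km in accepted_kmers for km in kms):
            rejections["cross_readout_kmer"] += 1
            continue
        pc = pseudocolors[len(accepted)] if pseudocolors is not None else (len(accepted), 0)
        accepted.append(ReadoutOligo(len(accepted), seq, pc))
        accepted_kmers.update(_kmers(seq, cfg.readout_k))
        accepted_kmers.update(_kmers(revcomp(seq), cfg.readout_k))
    return accepted


def assemble_probes(
    sites: Sequence[CandidateSite],
    readouts: Sequence[ReadoutOligo],
    primers: tuple[str, str],
    cfg: DesignConfig,
) -> list[EncodingProbe]:
    """Assemble one encoding probe per site.

    ``readouts`` are the gene's four readout oligos; all probes of the
    gene carry the same four, split two per side of the targeting
    region.
    """
    if len(readouts) != cfg.readouts_per_probe:
        raise ValueError(
            f"expected {cfg.readouts_per_probe} readouts, got {len(readouts)}"
        )
    fwd, rev = primers
    if not fwd or not rev:
        raise ValueError("primers must be non-empty")
    ro = [r.sequence for r in readouts]
    ids = tuple(r.readout_id for r in readouts)
    probes = []
    for site in sites:
        full = fwd + ro[0] + ro[1] + revcomp(site.target_seq) + ro[2] + ro[3] + rev
        probes.append(
            EncodingProbe(site.gene_id, site, ids, fwd, rev, full)
        )
    return probes


def parse_full_sequence(
    full: str, primer_lens: tuple[int, int], cfg: DesignConfig
) -> str:
    """Recover the transcript target window from an assembled oligo."""
    a = primer_lens[0] + 2 * cfg.readout_len
    return revcomp(full[a : a + cfg.target_len])


@dataclass
class GeneDesign:
    """Per-gene design outcome."""

    gene_id: str
    probes: list[EncodingProbe]
    below_minimum: bool
    n_candidate_sites: int
    n_surviving_sites: int
    warnings: list[str] = field(default_factory=list)


def design_probe_library(
    transcripts: Sequence[TranscriptRecord],
    background: Sequence[TranscriptRecord],
    cfg: DesignConfig,
    gene_readouts: dict[str, Sequence[ReadoutOligo]] | None = None,
    primers: tuple[str, str] = (DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER),
) -> list[GeneDesign]:
    """Design probes for every transcript against a shared background.

    Background records whose gene_id matches the gene under design are
    excluded from that gene's screen, so a whole-transcriptome FASTA can
    be passed directly.  When ``gene_readouts`` is None, four readouts
    per gene are generated from ``cfg.rng_seed`` and screened against
    the background.
    """
    ids = {t.gene_id for t in transcripts}
    if len(ids) != len(transcripts):
        raise ValueError("gene_id values must be unique within a library")
    decoys = [b for b in background if b.gene_id not in ids]
    shared_index = build_kmer_index(decoys, cfg.offtarget_k) if decoys else None
    if gene_readouts is None:
        flat = generate_readout_oligos(4 * len(transcripts), decoys, cfg)
        gene_readouts = {
            t.gene_id: flat[4 * i : 4 * i + 4] for i, t in enumerate(transcripts)
        }
    designs: list[GeneDesign] = []
    for t in transcripts:
        sites, warn = enumerate_targeting_sites(t, cfg)
        survivors, warn2 = screen_off_targets(sites, decoys, cfg, index=shared_index)
        selected, flag = select_probe_set(survivors, cfg)
        probes = assemble_probes(selected, gene_readouts[t.gene_id], primers, cfg)
        designs.append(
            GeneDesign(
                t.gene_id, probes, flag, len(sites), len(survivors), warn + warn2
            )
        )
    return designs


def synthetic_transcripts(
    gene_ids: Sequence[str],
    length: int = 1200,
    rng_seed: int = 0,
    gc: float = 0.5,
) -> list[TranscriptRecord]:
    """Random i.i.d. transcripts for simulation-backed runs and tests."""
    rng = np.random.default_rng(rng_seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return [
        TranscriptRecord(g, "".join(rng.choice(bases, size=length, p=p)))
        for g in gene_ids
    ]


# ----------------------------------------------------------------------
# I/O

def read_fasta(path) -> list[TranscriptRecord]:
    """Read a multi-record FASTA into TranscriptRecords."""
    from Bio import SeqIO

    return [
        TranscriptRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_probe_tsv(designs: Sequence[GeneDesign], path) -> None:
    """Write the probe library as TSV."""
    import pandas as pd

    rows = [
        {
            "gene_id": p.gene_id,
            "start": p.site.start,
            "target_seq": p.site.target_seq,
            "readout_ids": ",".join(map(str, p.readout_ids)),
            "full_sequence": p.full_sequence,
        }
        for d in designs
        for p in d.probes
    ]
    pd.DataFrame(rows, columns=["gene_id", "start", "target_seq", "readout_ids", "full_sequence"]).to_csv(
        path, sep="\t", index=False
    )


def write_probe_fasta(designs: Sequence[GeneDesign], path) -> None:
    with open(path, "w") as fh:
        for d in designs:
            for i, p in enumerate(d.probes):
                fh.write(f">{p.gene_id}_probe{i:03d}\n{p.full_sequence}\n")


def write_design_report(designs: Sequence[GeneDesign], path, cfg: DesignConfig) -> None:
    report = {
        "config": asdict(cfg),
        "genes": {
            d.gene_id: {
                "n_probes": len(d.probes),
                "n_candidate_sites": d.n_candidate_sites,
                "n_surviving_sites": d.n_surviving_sites,
                "below_minimum": d.below_minimum,
                "warnings": d.warnings,
            }
            for d in designs
        },
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
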