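"""Probe-panel design for sequential-hybridization chromatin tracing.

A target genomic region is tiled into consecutive fixed-length segments
(50 kb by default).  Each segment receives a set of 30-nt genome-targeting
sequences, screened for repetitive sub-k-mers against the supplied genome,
which are then assembled into 130-nt template oligos (forward primer,
readout site, target, two readout sites, reverse-primer site).  Segments
are scheduled into sequential hybridization rounds over a small number of
dye channels (the codebook), and per-segment adapter oligos route each
segment's readout site to the channel's common dye-labeled readout.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Segment",
    "SegmentPanel",
    "CandidateTarget",
    "TemplateOligo",
    "AdapterOligo",
    "PanelDesignError",
    "DEFAULT_REGION",
    "partition_region",
    "extract_candidate_targets",
    "KmerIndex",
    "filter_repetitive",
    "select_probes",
    "assemble_template_oligo",
    "parse_template_oligo",
    "build_codebook",
    "design_adapter_oligo",
    "generate_oligo_pool",
    "reverse_complement",
    "design_probes",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Traced imprinting-domain region: chr15 15q11.2-q13, hg38. The end
#: coordinate is chosen so that the region tiles into exactly 42 segments
#: of 50 kb (2.1 Mb); see docs/methods.md for the coordinate discussion.
DEFAULT_REGION_START = 23_500_000
DEFAULT_REGION_END = 25_600_000


class PanelDesignError(ValueError):
    """Raised when panel-design inputs violate a documented precondition."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    assembly: str = "hg38"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise PanelDesignError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise PanelDesignError(
                f"end ({self.end}) must exceed start ({self.start})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


DEFAULT_REGION = GenomicInterval("chr15", DEFAULT_REGION_START, DEFAULT_REGION_END)


@dataclass(frozen=True)
class Segment:
    """One tiled target segment; round/channel unset until codebook build."""

    index: int
    interval: GenomicInterval
    hyb_round: int | None = None
    channel: str | None = None


@dataclass
class SegmentPanel:
    """Ordered tiling of a region plus the round/channel readout codebook."""

    region: GenomicInterval
    segment_length: int
    segments: list[Segment]
    n_channels: int | None = None
    channel_names: tuple[str, ...] | None = None
    remainder_bp: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_rounds(self) -> int | None:
        if self.n_channels is None:
            return None
        return -(-self.n_segments // self.n_channels)  # ceil

    @property
    def has_codebook(self) -> bool:
        return self.n_channels is not None

    def locus_for(self, hyb_round: int, channel: str) -> int | None:
        """Segment index read out in (round, channel), or None if empty slot."""
        for seg in self.segments:
            if seg.hyb_round == hyb_round and seg.channel == channel:
                return seg.index
        return None

    def bins(self):
        """Bin table (chrom, start, end) in panel order, as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [s.interval.chrom for s in self.segments],
                "start": [s.interval.start for s in self.segments],
                "end": [s.interval.end for s in self.segments],
            }
        )


@dataclass(frozen=True)
class CandidateTarget:
    """A 30-nt genome-targeting sequence candidate within one segment."""

    segment_index: int
    offset: int
    sequence: str
    strand: str = "+"
    gc_fraction: float = 0.0
    max_subkmer_hits: int | None = None


@dataclass(frozen=True)
class TemplateOligo:
    """130-nt primary probe: primers, readout sites, and targeting sequence.

    ``parts`` is the 5'->3' six-tuple (fwd_primer, readout_site_1, target,
    readout_site_2, readout_site_3, rev_primer_site); lengths (20, 20, 30,
    20, 20, 20), 130 nt in total.
    """

    segment_index: int
    parts: tuple[str, str, str, str, str, str]
    full_sequence: str
    offset: int = 0


#: (start, end) slices of the six template-oligo parts within the 130-mer.
TEMPLATE_GRAMMAR = ((0, 20), (20, 40), (40, 70), (70, 90), (90, 110), (110, 130))
TEMPLATE_PART_LENGTHS = (20, 20, 30, 20, 20, 20)
TEMPLATE_LENGTH = 130
TEMPLATE_PART_NAMES = (
    "fwd_primer",
    "readout_site_1",
    "target",
    "readout_site_2",
    "readout_site_3",
    "rev_primer_site",
)


@dataclass(frozen=True)
class AdapterOligo:
    """60-nt adapter: primary-probe binding site + two identical readout-binding copies."""

    segment_index: int
    primary_binding: str
    readout_binding: str
    full_sequence: str


# ---------------------------------------------------------------------------
# region partitioning and codebook


def partition_region(region: GenomicInterval, segment_length: int) -> SegmentPanel:
    """Tile ``region`` into consecutive ``segment_length`` segments.

    A trailing remainder shorter than one segment is dropped and recorded in
    ``SegmentPanel.remainder_bp``.
    """
    if segment_length <= 0:
        raise PanelDesignError("segment_length must be positive")
    span = len(region)
    if span < segment_length:
        raise PanelDesignError(
            f"region {region.label} ({span} bp) is shorter than one "
            f"{segment_length}-bp segment"
        )
    n = span // segment_length
    remainder = span - n * segment_length
    segments = [
        Segment(
            index=i,
            interval=GenomicInterval(
                region.chrom,
                region.start + i * segment_length,
                region.start + (i + 1) * segment_length,
                region.assembly,
            ),
        )
        for i in range(n)
    ]
    if remainder:
        warnings.warn(
            f"dropped {remainder}-bp remainder at the end of {region.label}",
            stacklevel=2,
        )
    return SegmentPanel(
        region=region,
        segment_length=segment_length,
        segments=segments,
        remainder_bp=remainder,
    )


def build_codebook(
    panel: SegmentPanel,
    n_channels: int = 2,
    channel_names: Sequence[str] = ("647", "560"),
) -> SegmentPanel:
    """Assign segment i to round ``i // n_channels``, channel ``i % n_channels``.

    Rounds therefore follow genomic order; with the default two dye channels
    a 42-segment panel is read out in 21 sequential rounds.
    """
    if n_channels < 1:
        raise PanelDesignError("n_channels must be >= 1")
    names = tuple(channel_names)[:n_channels]
    if len(names) != n_channels:
        raise PanelDesignError("need one name per channel")
    segments = [
        replace(seg, hyb_round=seg.index // n_channels, channel=names[seg.index % n_channels])
        for seg in panel.segments
    ]
    return SegmentPanel(
        region=panel.region,
        segment_length=panel.segment_length,
        segments=segments,
        n_channels=n_channels,
        channel_names=names,
        remainder_bp=panel.remainder_bp,
    )


# ---------------------------------------------------------------------------
# candidate extraction and screening


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def extract_candidate_targets(
    segment_sequence: str,
    k: int = 30,
    min_gap: int = 30,
    gc_range: tuple[float, float] | None = (0.30, 0.70),
    max_homopolymer: int | None = 6,
    segment_index: int = 0,
) -> list[CandidateTarget]:
    """Enumerate k-mer targeting-sequence candidates along one segment.

    Scans left to right; after accepting a candidate the scan jumps ahead by
    ``min_gap`` so successive offsets differ by at least that much (with
    ``min_gap == k`` candidates are non-overlapping).  Windows containing
    non-ACGT characters are skipped.  Composition filters (GC fraction and
    maximum homopolymer run) are applied when not None.
    """
    seq = segment_sequence.upper()
    if len(seq) < k:
        warnings.warn(f"sequence of {len(seq)} nt is shorter than k={k}", stacklevel=2)
        return []
    out: list[CandidateTarget] = []
    valid = set("ACGT")
    offset = 0
    while offset + k <= len(seq):
        window = seq[offset : offset + k]
        if set(window) <= valid:
            gc = _gc_fraction(window)
            ok = True
            if gc_range is not None and not (gc_range[0] <= gc <= gc_range[1]):
                ok = False
            if ok and max_homopolymer is not None and _max_homopolymer(window) > max_homopolymer:
                ok = False
            if ok:
                out.append(
                    CandidateTarget(
                        segment_index=segment_index,
                        offset=offset,
                        sequence=window,
                        gc_fraction=gc,
                    )
                )
                offset += max(min_gap, 1)
                continue
        offset += 1
    return out


class KmerIndex:
    """Exact occurrence counts of all length-k substrings of a genome.

    Stands in for a repetitive-sequence BLAST screen: a targeting sequence is
    considered repetitive when any of its sub-k-mers occurs more than
    ``max_hits`` times genome-wide on the forward strand.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 17):
        if k < 1:
            raise PanelDesignError("k must be positive")
        self.k = k
        counts: Counter[str] = Counter()
        valid = set("ACGT")
        for seq in genome.values():
            s = str(seq).upper()
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if set(kmer) <= valid:
                    counts[kmer] += 1
        if not counts:
            raise PanelDesignError("empty k-mer index: genome has no valid k-mers")
        self._counts = counts

    def count(self, kmer: str) -> int:
        return self._counts.get(kmer.upper(), 0)

    def max_window_hits(self, seq: str) -> int:
        """Worst-case occurrence count over all length-k windows of ``seq``."""
        s = seq.upper()
        if len(s) < self.k:
            return 0
        return max(self.count(s[i : i + self.k]) for i in range(len(s) - self.k + 1))


def filter_repetitive(
    candidates: Iterable[CandidateTarget],
    genome_index: KmerIndex,
    max_hits: int = 1,
) -> list[CandidateTarget]:
    """Retain candidates whose every sub-k-mer occurs <= max_hits genome-wide."""
    out = []
    for cand in candidates:
        hits = genome_index.max_window_hits(cand.sequence)
        if hits <= max_hits:
            out.append(replace(cand, max_subkmer_hits=hits))
    return out


def select_probes(
    candidates: Sequence[CandidateTarget],
    n_per_segment: int = 500,
    strategy: str = "even_spacing",
) -> list[CandidateTarget]:
    """Deterministically pick ``n_per_segment`` candidates spread along the segment.

    Even spacing takes candidates at evenly spaced ranks over the
    offset-sorted list (leftmost candidate wins rank ties), which spreads
    probes across the full segment.  With fewer candidates than requested,
    all are returned with a warning.
    """
    if strategy != "even_spacing":
        raise PanelDesignError(f"unknown selection strategy: {strategy!r}")
    if n_per_segment < 1:
        raise PanelDesignError("n_per_segment must be >= 1")
    ordered = sorted(candidates, key=lambda c: c.offset)
    m = len(ordered)
    if m <= n_per_segment:
        if m < n_per_segment:
            warnings.warn(
                f"only {m} candidates available for {n_per_segment} requested probes",
                stacklevel=2,
            )
        return ordered
    if n_per_segment == 1:
        return [ordered[0]]
    step = (m - 1) / (n_per_segment - 1)
    return [ordered[int(i * step)] for i in range(n_per_segment)]


# ---------------------------------------------------------------------------
# oligo assembly


def _require_length(seq: str, n: int, name: str) -> str:
    if len(seq) != n:
        raise PanelDesignError(f"{name} must be {n} nt, got {len(seq)} nt")
    return seq.upper()


def assemble_template_oligo(
    target: CandidateTarget,
    fwd_primer: str,
    rev_primer: str,
    readout_sites: Sequence[str],
) -> TemplateOligo:
    """Concatenate the 130-nt template oligo 5'->3'.

    Order: forward primer, readout site 1, 30-nt targeting sequence, readout
    sites 2 and 3, reverse-primer site.  The reverse-primer site is stored as
    the reverse complement of the reverse primer so that the primer anneals to
    the emitted strand.
    """
    if len(readout_sites) != 3:
        raise PanelDesignError("exactly three readout sites are required")
    fwd = _require_length(fwd_primer, 20, "fwd_primer")
    rev = _require_length(rev_primer, 20, "rev_primer")
    r1, r2, r3 = (_require_length(s, 20, f"readout_site_{i+1}") for i, s in enumerate(readout_sites))
    tgt = _require_length(target.sequence, 30, "target")
    parts = (fwd, r1, tgt, r2, r3, reverse_complement(rev))
    return TemplateOligo(
        segment_index=target.segment_index,
        parts=parts,
        full_sequence="".join(parts),
        offset=target.offset,
    )


def parse_template_oligo(full_sequence: str) -> tuple[str, ...]:
    """Slice a 130-mer under the (20,20,30,20,20,20) grammar; error otherwise."""
    if len(full_sequence) != TEMPLATE_LENGTH:
        raise PanelDesignError(
            f"template oligo must be {TEMPLATE_LENGTH} nt, got {len(full_sequence)}"
        )
    return tuple(full_sequence[a:b] for a, b in TEMPLATE_GRAMMAR)


def design_adapter_oligo(
    segment_readout_site: str,
    readout_binding: str,
    segment_index: int = 0,
) -> AdapterOligo:
    """Build the 60-nt adapter routing a segment to a channel's common readout.

    The primary-binding half is the reverse complement of the segment's
    designated template readout site; the common readout-binding 20-mer is
    duplicated to carry two dye-labeled readout oligos.
    """
    site = _require_length(segment_readout_site, 20, "segment_readout_site")
    bind = _require_length(readout_binding, 20, "readout_binding")
    primary = reverse_complement(site)
    return AdapterOligo(
        segment_index=segment_index,
        primary_binding=primary,
        readout_binding=bind,
        full_sequence=primary + bind + bind,
    )


# ---------------------------------------------------------------------------
# primer / readout sequence pool


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_oligo_pool(
    n: int,
    length: int = 20,
    seed: int = 0,
    min_hamming: int = 8,
    max_tries: int = 200_000,
) -> list[str]:
    """Seeded pool of 20-mers with pairwise (and reverse-complement) Hamming >= min_hamming."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    pool: list[str] = []
    tries = 0
    while len(pool) < n:
        tries += 1
        if tries > max_tries:
            raise PanelDesignError("could not build oligo pool under the distance constraints")
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        rc = reverse_complement(cand)
        if _hamming(cand, rc) < min_hamming:
            continue
        ok = all(
            _hamming(cand, p) >= min_hamming and _hamming(rc, p) >= min_hamming
            for p in pool
        )
        if ok:
            pool.append(cand)
    return pool


# ---------------------------------------------------------------------------
# full design


@dataclass
class ProbeSet:
    """Design output for one panel: oligos plus the sequence bookkeeping."""

    panel: SegmentPanel
    template_oligos: list[TemplateOligo]
    adapter_oligos: list[AdapterOligo]
    fwd_primer: str
    rev_primer: str
    readout_sites: dict[int, tuple[str, str, str]]  # segment -> three sites
    channel_readouts: dict[str, str]  # channel -> common readout-binding seq

    def oligos_for_segment(self, segment_index: int) -> list[TemplateOligo]:
        return [o for o in self.template_oligos if o.segment_index == segment_index]


def design_probes(
    genome: Mapping[str, str],
    panel: SegmentPanel,
    n_per_segment: int = 500,
    k: int = 30,
    min_gap: int = 30,
    gc_range: tuple[float, float] | None = (0.30, 0.70),
    max_homopolymer: int | None = 6,
    sub_k: int = 17,
    max_hits: int = 1,
    seed: int = 0,
) -> ProbeSet:
    """Run the full per-segment design: extract, screen, select, assemble.

    ``genome`` maps record names to sequences; segment sequences are sliced
    from the record named by the panel's chromosome (falling back to the sole
    record of a single-record genome).
    """
    if not panel.has_codebook:
        raise PanelDesignError("panel codebook must be built before probe design")
    index = KmerIndex(genome, k=sub_k)
    pool = generate_oligo_pool(2 + 3 * panel.n_segments + panel.n_channels, seed=seed)
    fwd_primer, rev_primer = pool[0], pool[1]
    channel_readouts = {
        name: pool[2 + i] for i, name in enumerate(panel.channel_names)
    }
    site_pool = pool[2 + panel.n_channels :]

    chrom = panel.region.chrom
    if chrom not in genome and len(genome) == 1:
        chrom = next(iter(genome))
    if chrom not in genome:
        raise PanelDesignError(f"genome has no record named {panel.region.chrom!r}")
    ref = str(genome[chrom]).upper()

    templates: list[TemplateOligo] = []
    adapters: list[AdapterOligo] = []
    readout_sites: dict[int, tuple[str, str, str]] = {}
    for seg in panel.segments:
        lo = seg.interval.start - panel.region.start if len(ref) < seg.interval.end else seg.interval.start
        # toy genomes often hold only the region itself; full references hold the chromosome
        seq = ref[lo : lo + panel.segment_length]
        cands = extract_candidate_targets(
            seq,
            k=k,
            min_gap=min_gap,
            gc_range=gc_range,
            max_homopolymer=max_homopolymer,
            segment_index=seg.index,
        )
        kept = filter_repetitive(cands, index, max_hits=max_hits)
        chosen = select_probes(kept, n_per_segment=n_per_segment)
        sites = tuple(site_pool[3 * seg.index : 3 * seg.index + 3])
        readout_sites[seg.index] = sites  # type: ignore[assignment]
        for cand in chosen:
            templates.append(assemble_template_oligo(cand, fwd_primer, rev_primer, sites))
        adapters.append(
            design_adapter_oligo(sites[0], channel_readouts[seg.channel], seg.index)
        )
    return ProbeSet(
        panel=panel,
        template_oligos=templates,
        adapter_oligos=adapters,
        fwd_primer=fwd_primer,
        rev_primer=rev_primer,
        readout_sites=readout_sites,
        channel_readouts=channel_readouts,
    )
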