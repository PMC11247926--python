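"""Plain-text readers/writers for panel, oligo, foci, and trace artifacts."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .panel_design import AdapterOligo, SegmentPanel, TemplateOligo

__all__ = [
    "load_genome",
    "write_genome_fasta",
    "write_segments_bed",
    "write_codebook",
    "read_codebook",
    "write_oligos_fasta",
    "write_tsv",
    "read_tsv",
]


def load_genome(path) -> dict[str, str]:
    """Multi-record FASTA into {name: uppercase sequence} (pyfaidx-backed)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True, rebuild=False)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome_fasta(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_segments_bed(panel: SegmentPanel, path) -> None:
    """Segments as BED6; name encodes round/channel/segment index."""
    with open(path, "w") as fh:
        for seg in panel.segments:
            name = f"Hyb_{seg.hyb_round}_{seg.channel}_seg{seg.index}"
            fh.write(
                f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}"
                f"\t{name}\t0\t+\n"
            )


def write_codebook(panel: SegmentPanel, path) -> None:
    rows = [
        dict(
            segment_index=seg.index,
            chrom=seg.interval.chrom,
            start=seg.interval.start,
            end=seg.interval.end,
            round=seg.hyb_round,
            channel=seg.channel,
            readout_id=f"R{seg.index}",
        )
        for seg in panel.segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_codebook(path) -> SegmentPanel:
    """Rebuild a SegmentPanel (with codebook) from a codebook TSV."""
    from .panel_design import GenomicInterval, Segment

    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("segment_index")
    segments = [
        Segment(
            index=int(r.segment_index),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            hyb_round=int(r.round),
            channel=str(r.channel),
        )
        for r in df.itertuples()
    ]
    seg_len = int(df["end"].iloc[0] - df["start"].iloc[0])
    channels = tuple(pd.unique(df.sort_values(["round", "channel"])["channel"]).astype(str))
    region = GenomicInterval(
        str(df["chrom"].iloc[0]), int(df["start"].min()), int(df["end"].max())
    )
    return SegmentPanel(
        region=region,
        segment_length=seg_len,
        segments=segments,
        n_channels=len(channels),
        channel_names=channels,
    )


def write_oligos_fasta(
    oligos: Sequence[TemplateOligo | AdapterOligo], panel: SegmentPanel, path
) -> None:
    """Oligos as FASTA with structured headers ``segIdx|offset|round|channel``."""
    by_index = {seg.index: seg for seg in panel.segments}
    records = []
    for i, o in enumerate(oligos):
        seg = by_index[o.segment_index]
        offset = getattr(o, "offset", 0)
        header = f"{o.segment_index}|{offset}|{seg.hyb_round}|{seg.channel}"
        records.append(SeqRecord(Seq(o.full_sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
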