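"""Conserved intronic region (CIR) construction from annotation and tracks.

The search space for long-range complementary regions is built in three
steps: (1) per protein-coding gene, take the maximal segments that do not
overlap any annotated exon of any gene, extended by up to 10 nts into the
flanking exons so that duplexes overlapping splice sites remain visible;
(2) subtract exclusion tracks (repeats, small RNAs, conserved TFBS, ...);
(3) intersect with the conserved-element track.  Each resulting CIR keeps
the identity of the gene whose intronic region produced it, so a genomic
interval may yield CIRs for several overlapping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd

from .intervals import (
    GenomicInterval,
    complement_within,
    intersect_intervals,
    merge_intervals,
    subtract_intervals,
)

__all__ = [
    "Gene",
    "CIR",
    "read_gtf",
    "read_bed",
    "write_bed6",
    "extract_intronic_regions",
    "apply_exclusions",
    "intersect_conserved",
    "build_cirs",
]

EXON_EXTENSION = 10  # nts of flanking exon included in each intronic region


@dataclass(frozen=True)
class Gene:
    id: str
    interval: GenomicInterval
    exons: Tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class CIR:
    """A conserved intronic fragment attributed to one gene."""

    interval: GenomicInterval
    gene_id: str
    parent: GenomicInterval  # the (extended) intronic region it came from

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def __len__(self) -> int:
        return len(self.interval)


def read_gtf(path: str, biotypes: Sequence[str] = ("protein_coding",)) -> List[Gene]:
    """Parse genes and exons from a GTF/GFF file (gffutils, in-memory)."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: Dict[str, List[GenomicInterval]] = {}
    for exon in db.features_of_type("exon"):
        gid = exon.attributes.get("gene_id", ["?"])[0]
        exons_by_gene.setdefault(gid, []).append(
            GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        )
    genes: List[Gene] = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", ["?"])[0]
        biotype = (
            feat.attributes.get("gene_biotype", [])
            or feat.attributes.get("gene_type", ["?"])
        )[0]
        if biotypes and biotype not in biotypes:
            continue
        genes.append(
            Gene(
                id=gid,
                interval=GenomicInterval(
                    feat.seqid, feat.start - 1, feat.end, feat.strand, name=gid
                ),
                exons=tuple(sorted(exons_by_gene.get(gid, ()))),
                biotype=biotype,
            )
        )
    genes.sort(key=lambda g: g.interval)
    return genes


def read_bed(path: str) -> List[GenomicInterval]:
    df = pd.read_csv(
        str(path), sep="\t", header=None, comment="#", dtype={0: str}
    )
    out = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else ""
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "+"
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand, name))
    return sorted(out)


def write_bed6(intervals: Iterable[GenomicInterval], path: str) -> None:
    with open(str(path), "w") as fh:
        for iv in sorted(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def extract_intronic_regions(genes: Sequence[Gene]) -> List[GenomicInterval]:
    """Maximal intra-gene segments free of any exon, with 10-nt exon flanks.

    Exons are unioned across ALL genes (so a segment overlapped by another
    gene's exon is split).  Each segment is then extended by up to 10 nts
    into its flanking exon blocks, clipped to the exon block and the gene
    bounds.  The returned intervals carry the gene id in ``name``.
    """
    exon_union: Dict[str, List[Tuple[int, int]]] = {}
    for gene in genes:
        exon_union.setdefault(gene.chrom, []).extend(
            (e.start, e.end) for e in gene.exons
        )
    exon_union = {c: merge_intervals(v) for c, v in exon_union.items()}
    regions: List[GenomicInterval] = []
    for gene in genes:
        blocks = exon_union.get(gene.chrom, [])
        window = (gene.interval.start, gene.interval.end)
        for s, e in complement_within(window, blocks):
            ext_s, ext_e = s, e
            for bs, be in blocks:
                if be == s:  # exon block flanking on the left
                    ext_s = max(s - EXON_EXTENSION, bs, gene.interval.start)
                if bs == e:  # exon block flanking on the right
                    ext_e = min(e + EXON_EXTENSION, be, gene.interval.end)
            regions.append(
                GenomicInterval(gene.chrom, ext_s, ext_e, gene.strand, name=gene.id)
            )
    return sorted(regions)


def apply_exclusions(
    regions: Sequence[GenomicInterval],
    exclusion_tracks: Sequence[Sequence[GenomicInterval]],
) -> List[GenomicInterval]:
    """Subtract every exclusion track; fragments keep gene attribution."""
    cut_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for track in exclusion_tracks:
        for iv in track:
            cut_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: List[GenomicInterval] = []
    for region in regions:
        cuts = cut_by_chrom.get(region.chrom, [])
        for s, e in subtract_intervals([(region.start, region.end)], cuts):
            out.append(
                GenomicInterval(region.chrom, s, e, region.strand, name=region.name)
            )
    return sorted(out)


def intersect_conserved(
    regions: Sequence[GenomicInterval],
    conserved: Sequence[GenomicInterval],
) -> List[CIR]:
    """Intersect intronic regions with conserved elements, yielding CIRs."""
    cons_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in conserved:
        cons_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    cirs: List[CIR] = []
    for region in regions:
        spans = cons_by_chrom.get(region.chrom, [])
        for s, e in intersect_intervals([(region.start, region.end)], spans):
            cirs.append(
                CIR(
                    interval=GenomicInterval(
                        region.chrom, s, e, region.strand, name=region.name
                    ),
                    gene_id=region.name,
                    parent=region,
                )
            )
    cirs.sort(key=lambda c: (c.interval, c.gene_id))
    return cirs


def build_cirs(
    genes: Sequence[Gene],
    conserved: Sequence[GenomicInterval],
    exclusion_tracks: Sequence[Sequence[GenomicInterval]] = (),
) -> List[CIR]:
    """Full CIR construction: introns -> exclusions -> conserved intersect."""
    regions = extract_intronic_regions(genes)
    if exclusion_tracks:
        regions = apply_exclusions(regions, exclusion_tracks)
    return intersect_conserved(regions, conserved)
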