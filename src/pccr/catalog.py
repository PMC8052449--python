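"""Genome-wide search over CIR pairs and annotation of the resulting catalog.

Every pair of conserved intronic regions of the same gene lying within a
distance limit L (default 10,000 nts, including a region with itself) is
scanned with the duplex search on sense-strand sequence; hits are lifted
back to genomic coordinates and annotated with the spread between the two
regions, an energy group, the relative position within the gene,
conservation scores, and the GC content of the paired nucleotides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .annotation import CIR, Gene
from .duplex import SearchParams, find_duplexes, select_nonintersecting
from .energies import KmerEnergyTable, build_kmer_table
from .intervals import GenomicInterval
from .tracks import Genome, ScoreTrack

__all__ = [
    "PCCR",
    "CatalogParams",
    "enumerate_cir_pairs",
    "scan_gene",
    "build_catalog",
    "relative_position",
    "conservation_scores",
    "assign_energy_group",
    "write_catalog",
    "read_catalog",
]


@dataclass(frozen=True)
class PCCR:
    """A pair of conserved complementary regions within one gene."""

    ccr1: GenomicInterval  # transcriptionally upstream arm
    ccr2: GenomicInterval
    gene_id: str
    dG: float
    structure: Tuple[Tuple[int, int], ...]  # genomic (pos in ccr1, pos in ccr2)
    spread: int
    energy_group: str
    rel_pos: float
    gc: float
    length_avg: float
    cons_scores: Optional[Tuple[float, float, float]] = None
    evalue: Optional[float] = None
    pccr_id: Optional[int] = None

    @property
    def chrom(self) -> str:
        return self.ccr1.chrom

    @property
    def span(self) -> Tuple[int, int]:
        """Genomic footprint from the leftmost to the rightmost nucleotide."""
        return (
            min(self.ccr1.start, self.ccr2.start),
            max(self.ccr1.end, self.ccr2.end),
        )

    @property
    def inner_gap(self) -> Tuple[int, int]:
        """The genomic interval strictly between the two arms."""
        left = min((self.ccr1, self.ccr2), key=lambda c: c.start)
        right = max((self.ccr1, self.ccr2), key=lambda c: c.start)
        return (left.end, max(right.start, left.end))


@dataclass(frozen=True)
class CatalogParams:
    L: int = 10_000
    search: SearchParams = field(default_factory=SearchParams)

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError("L must be positive")


ENERGY_GROUPS = (("I", -20.0), ("II", -25.0), ("III", -30.0))


def assign_energy_group(dG: float) -> str:
    """Energy group I (-20,-15], II (-25,-20], III (-30,-25], IV <= -30."""
    if dG > -15.0:
        raise ValueError(f"dG={dG} above the -15 kcal/mol catalog threshold")
    for label, lower in ENERGY_GROUPS:
        if dG > lower:
            return label
    return "IV"


def relative_position(interval: GenomicInterval, gene: Gene) -> float:
    """Relative position p of an interval within its gene: 0 at the 5' end,
    1 at the 3' end (strand-aware), clamped to [0, 1]."""
    a, b = gene.interval.start, gene.interval.end
    x, y = interval.start, interval.end
    if x < a or y > b:
        raise ValueError("interval outside gene")
    denom = (b - a) - (y - x) + 1
    p = (x - a) / denom if denom > 0 else 0.0
    p = min(max(p, 0.0), 1.0)
    return 1.0 - p if gene.strand == "-" else p


def conservation_scores(
    ccr: GenomicInterval,
    cir: GenomicInterval,
    score_track: ScoreTrack,
    flank: int = 300,
) -> Tuple[float, float, float]:
    """(s1, s2, s3) conservation scores of one arm.

    s1: mean score within the arm minus the mean over the two flanking
    windows of ``flank`` nts (larger = locally elevated conservation).
    s2: mean score over the arm plus ``flank`` nts on both sides
    (smaller = more isolated).  s3: arm length relative to its parent
    conserved region.  Uncovered positions score 0.
    """
    import numpy as np

    inside = score_track.values(ccr.chrom, ccr.start, ccr.end)
    flanks = np.concatenate(
        [
            score_track.values(ccr.chrom, max(ccr.start - flank, 0), ccr.start),
            score_track.values(ccr.chrom, ccr.end, ccr.end + flank),
        ]
    )
    s1 = float(inside.mean() - (flanks.mean() if len(flanks) else 0.0))
    s2 = score_track.mean(ccr.chrom, max(ccr.start - flank, 0), ccr.end + flank)
    s3 = len(ccr) / len(cir)
    return (s1, s2, s3)


def enumerate_cir_pairs(
    cirs: Sequence[CIR], L: int = 10_000
) -> List[Tuple[CIR, CIR]]:
    """All unordered same-gene CIR pairs (self-pairs included) with genomic
    gap at most L nucleotides."""
    cirs = sorted(cirs, key=lambda c: c.interval)
    pairs: List[Tuple[CIR, CIR]] = []
    for idx, c1 in enumerate(cirs):
        for c2 in cirs[idx:]:
            gap = max(0, c2.interval.start - c1.interval.end)
            if c2.interval.start - c1.interval.end > L:
                break
            pairs.append((c1, c2))
    return pairs


def _sense_to_genomic(cir: CIR, offset: int) -> int:
    """Map a sense-sequence index within a CIR to a genomic position."""
    if cir.strand == "-":
        return cir.interval.end - 1 - offset
    return cir.interval.start + offset


def _lift_region(cir: CIR, region: Tuple[int, int]) -> GenomicInterval:
    g1 = _sense_to_genomic(cir, region[0])
    g2 = _sense_to_genomic(cir, region[1] - 1)
    lo, hi = min(g1, g2), max(g1, g2)
    return GenomicInterval(cir.chrom, lo, hi + 1, cir.strand, name=cir.gene_id)


def scan_gene(
    gene: Gene,
    cirs: Sequence[CIR],
    genome: Genome,
    table: KmerEnergyTable,
    params: CatalogParams = CatalogParams(),
    score_track: Optional[ScoreTrack] = None,
) -> List[PCCR]:
    """Duplex search over all distance-eligible CIR pairs of one gene."""
    gene_cirs = [c for c in cirs if c.gene_id == gene.id]
    sense_cache: Dict[Tuple[int, int], str] = {}

    def sense(cir: CIR) -> str:
        key = (cir.interval.start, cir.interval.end)
        if key not in sense_cache:
            sense_cache[key] = genome.sense(cir.interval)
        return sense_cache[key]

    pccrs: List[PCCR] = []
    for c1, c2 in enumerate_cir_pairs(gene_cirs, params.L):
        # transcription order: for minus-strand genes the genomically
        # downstream CIR is transcribed first
        up, down = (c1, c2) if gene.strand == "+" else (c2, c1)
        self_pair = c1.interval == c2.interval
        hits = find_duplexes(sense(up), sense(down), table, params.search)
        hits = select_nonintersecting(hits)
        for hit in hits:
            r1 = _lift_region(up, hit.region1)
            r2 = _lift_region(down, hit.region2)
            if r1.overlaps(r2):
                continue  # self-pair duplex folding back onto itself
            if self_pair and r1.start > r2.start:
                continue  # mirror duplicate of a hit already reported
            structure = tuple(
                (_sense_to_genomic(up, i), _sense_to_genomic(down, j))
                for i, j in hit.structure.base_pairs
            )
            paired = "".join(
                genome.fetch(r1.chrom, g1, g1 + 1) + genome.fetch(r2.chrom, g2, g2 + 1)
                for g1, g2 in structure
            )
            gc = sum(1 for b in paired if b in "GC") / len(paired)
            left, right = (r1, r2) if r1.start <= r2.start else (r2, r1)
            spread = max(0, right.start - left.end)
            span = GenomicInterval(
                r1.chrom,
                min(r1.start, r2.start),
                max(r1.end, r2.end),
                gene.strand,
            )
            cons = None
            if score_track is not None:
                s1a = conservation_scores(r1, up.interval, score_track)
                s2a = conservation_scores(r2, down.interval, score_track)
                cons = tuple(round((x + y) / 2, 6) for x, y in zip(s1a, s2a))
            pccrs.append(
                PCCR(
                    ccr1=r1,
                    ccr2=r2,
                    gene_id=gene.id,
                    dG=round(hit.dG, 6),
                    structure=structure,
                    spread=spread,
                    energy_group=assign_energy_group(hit.dG),
                    rel_pos=round(relative_position(span, gene), 6),
                    gc=round(gc, 6),
                    length_avg=(len(r1) + len(r2)) / 2,
                    cons_scores=cons,
                )
            )
    pccrs.sort(key=lambda p: (p.span, p.dG))
    return pccrs


def build_catalog(
    genes: Sequence[Gene],
    cirs: Sequence[CIR],
    genome: Genome,
    params: CatalogParams = CatalogParams(),
    table: Optional[KmerEnergyTable] = None,
    score_track: Optional[ScoreTrack] = None,
) -> List[PCCR]:
    """Scan every gene and return the numbered catalog."""
    if table is None:
        table = build_kmer_table(params.search.k, params.search.max_gu)
    catalog: List[PCCR] = []
    for gene in genes:
        try:
            catalog.extend(
                scan_gene(gene, cirs, genome, table, params, score_track)
            )
        except KeyError as exc:  # sequence fetch failure: skip gene, continue
            import warnings

            warnings.warn(f"gene {gene.id}: sequence fetch failed ({exc})")
    catalog = [replace(p, pccr_id=i + 1) for i, p in enumerate(catalog)]
    return catalog


_TSV_COLUMNS = [
    "pccr_id", "chrom", "strand", "gene_id",
    "ccr1_start", "ccr1_end", "ccr2_start", "ccr2_end",
    "dG", "length_avg", "spread", "energy_group", "rel_pos", "gc",
    "s1", "s2", "s3", "evalue", "structure",
]


def _structure_str(structure: Tuple[Tuple[int, int], ...]) -> str:
    return ",".join(f"{i}:{j}" for i, j in structure)


def write_catalog(pccrs: Sequence[PCCR], bed_path, tsv_path) -> None:
    """Write the catalog as paired-block BED12 plus a full-annotation TSV."""
    with open(str(bed_path), "w") as bed:
        for p in pccrs:
            left, right = sorted([p.ccr1, p.ccr2], key=lambda c: c.start)
            span_s, span_e = p.span
            sizes = f"{len(left)},{len(right)}"
            starts = f"{left.start - span_s},{right.start - span_s}"
            bed.write(
                "\t".join(
                    map(
                        str,
                        [
                            p.chrom, span_s, span_e, f"pccr_{p.pccr_id}",
                            0, p.ccr1.strand, span_s, span_e, "0,0,0",
                            2, sizes, starts,
                        ],
                    )
                )
                + "\n"
            )
    rows = []
    for p in pccrs:
        s1, s2, s3 = p.cons_scores if p.cons_scores else (float("nan"),) * 3
        rows.append(
            [
                p.pccr_id, p.chrom, p.ccr1.strand, p.gene_id,
                p.ccr1.start, p.ccr1.end, p.ccr2.start, p.ccr2.end,
                p.dG, p.length_avg, p.spread, p.energy_group, p.rel_pos, p.gc,
                s1, s2, s3,
                p.evalue if p.evalue is not None else float("nan"),
                _structure_str(p.structure),
            ]
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(
        str(tsv_path), sep="\t", index=False
    )


def read_catalog(tsv_path) -> List[PCCR]:
    df = pd.read_csv(str(tsv_path), sep="\t", dtype={"chrom": str})
    out: List[PCCR] = []
    for row in df.itertuples(index=False):
        structure = tuple(
            tuple(map(int, pair.split(":"))) for pair in row.structure.split(",")
        )
        cons = None
        if not pd.isna(row.s1):
            cons = (row.s1, row.s2, row.s3)
        out.append(
            PCCR(
                ccr1=GenomicInterval(
                    row.chrom, row.ccr1_start, row.ccr1_end, row.strand,
                    name=row.gene_id,
                ),
                ccr2=GenomicInterval(
                    row.chrom, row.ccr2_start, row.ccr2_end, row.strand,
                    name=row.gene_id,
                ),
                gene_id=row.gene_id,
                dG=row.dG,
                structure=structure,
                spread=int(row.spread),
                energy_group=row.energy_group,
                rel_pos=row.rel_pos,
                gc=row.gc,
                length_avg=row.length_avg,
                cons_scores=cons,
                evalue=None if pd.isna(row.evalue) else row.evalue,
                pccr_id=int(row.pccr_id),
            )
        )
    return out
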