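"""Resampling null models, enrichment statistics, and odds ratios.

Two placement controls are used throughout: *random shift* moves each
structure to a uniformly random offset within its own gene, preserving
the arm lengths and the spread; *random gene* re-creates the structure at
the same relative position in a randomly chosen length-matched gene.
False discovery is estimated by *re-wiring*: running the identical
search on chimeric pairs of conserved regions drawn from different genes
while matching length and nucleotide composition.  Association of binary
features with the two arms is summarized by odds ratios from 2x2 tables
with Woolf (log) confidence intervals and Fisher exact p values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .annotation import CIR, Gene
from .catalog import PCCR
from .duplex import SearchParams, find_duplexes, select_nonintersecting
from .energies import KmerEnergyTable, build_kmer_table
from .intervals import GenomicInterval
from .tracks import Genome

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "FDREstimate",
    "PseudoPCCR",
    "classify_overlap",
    "random_shift_control",
    "random_gene_control",
    "enrichment",
    "rewire_fdr",
    "odds_ratio",
    "forked_peak_or",
    "ccr_peak_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EnrichmentResult:
    observed: int
    control_counts: List[int]
    enrichment: float
    p_value: float
    ci95: Tuple[float, float]
    undefined: bool = False


@dataclass
class FDREstimate:
    n_real: int
    n_control: float
    fdr: float
    strata: Optional[Dict[str, float]] = None


@dataclass(frozen=True)
class PseudoPCCR:
    """Geometry-only stand-in for a structure in a control catalog."""

    gene_id: str
    chrom: str
    span: Tuple[int, int]
    inner_gap: Tuple[int, int]
    len1: int
    len2: int


def _geometry(p) -> Tuple[str, str, int, int, int, int]:
    """(gene_id, chrom, span_start, len1, gap, len2) of a PCCR-like object."""
    left = min((p.ccr1, p.ccr2), key=lambda c: c.start)
    right = max((p.ccr1, p.ccr2), key=lambda c: c.start)
    gap = max(right.start - left.end, 0)
    return (p.gene_id, p.ccr1.chrom, left.start, len(left), gap, len(right))


def _pseudo(gene_id, chrom, start, len1, gap, len2) -> PseudoPCCR:
    return PseudoPCCR(
        gene_id=gene_id,
        chrom=chrom,
        span=(start, start + len1 + gap + len2),
        inner_gap=(start + len1, start + len1 + gap),
        len1=len1,
        len2=len2,
    )


def classify_overlap(pccr, feature: GenomicInterval) -> str:
    """Relation of a structure's footprint to a feature interval.

    ``inside``: the whole footprint lies within the feature.  ``outside``:
    the feature is looped out, i.e. lies strictly between the two arms.
    ``crossing``: footprint and feature partially overlap.  ``disjoint``
    otherwise.  ``pccr`` needs ``chrom``, ``span`` and ``inner_gap``.
    """
    if pccr.chrom != feature.chrom:
        return "disjoint"
    s, e = pccr.span
    if feature.start <= s and e <= feature.end:
        return "inside"
    gs, ge = pccr.inner_gap
    if gs <= feature.start and feature.end <= ge:
        return "outside"
    if s < feature.end and feature.start < e:
        return "crossing"
    return "disjoint"


def random_shift_control(
    pccrs: Sequence, genes: Sequence[Gene], n: int = 40, seed: int = 0
) -> List[List[PseudoPCCR]]:
    """n control catalogs, each PCCR uniformly shifted within its gene,
    preserving arm lengths and spread."""
    rng = np.random.default_rng(seed)
    by_id = {g.id: g for g in genes}
    out: List[List[PseudoPCCR]] = []
    for _ in range(n):
        cat: List[PseudoPCCR] = []
        for p in pccrs:
            gene_id, chrom, start, len1, gap, len2 = _geometry(p)
            gene = by_id[gene_id]
            total = len1 + gap + len2
            lo, hi = gene.interval.start, gene.interval.end - total
            if hi < lo:
                warnings.warn(f"{gene_id}: structure longer than gene; kept")
                new_start = start
            else:
                new_start = int(rng.integers(lo, hi + 1))
            cat.append(_pseudo(gene_id, chrom, new_start, len1, gap, len2))
        out.append(cat)
    return out


def random_gene_control(
    pccrs: Sequence,
    genes: Sequence[Gene],
    n: int = 40,
    seed: int = 0,
    length_tol: float = 0.10,
) -> List[List[PseudoPCCR]]:
    """n control catalogs with each structure re-created at the same
    relative position in a random gene of matching length (±10%)."""
    rng = np.random.default_rng(seed)
    lengths = np.array([len(g) for g in genes])
    out: List[List[PseudoPCCR]] = []
    for _ in range(n):
        cat: List[PseudoPCCR] = []
        for p in pccrs:
            gene_id, chrom, start, len1, gap, len2 = _geometry(p)
            total = len1 + gap + len2
            src = next(g for g in genes if g.id == gene_id)
            ok = [
                g
                for g, L in zip(genes, lengths)
                if abs(L - len(src)) <= length_tol * len(src) and L >= total
            ]
            if not ok:
                warnings.warn(f"{gene_id}: no length-matched gene; nearest used")
                ok = [
                    min(
                        (g for g in genes if len(g) >= total),
                        key=lambda g: abs(len(g) - len(src)),
                    )
                ]
            tgt = ok[int(rng.integers(len(ok)))]
            # same relative position within the new gene
            rel = (start - src.interval.start) / max(len(src) - total + 1, 1)
            place = tgt.interval.start + int(
                round(rel * (len(tgt) - total))
            )
            cat.append(_pseudo(tgt.id, tgt.chrom, place, len1, gap, len2))
        out.append(cat)
    return out


def _signed_rank_p(controls: Sequence[int], observed: int) -> float:
    """Two-tailed Wilcoxon signed-rank p for control counts vs observed."""
    diffs = np.asarray(controls, dtype=float) - observed
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return 1.0
    return float(stats.wilcoxon(diffs).pvalue)


def _count_relation(catalog: Sequence, features: Sequence[GenomicInterval],
                    relation: str) -> int:
    """A structure is counted once per feature it stands in ``relation`` to."""
    count = 0
    for p in catalog:
        for f in features:
            if classify_overlap(p, f) == relation:
                count += 1
    return count


def enrichment(
    pccrs: Sequence,
    features: Sequence[GenomicInterval],
    control_catalogs: Sequence[Sequence],
    relation: str = "inside",
) -> EnrichmentResult:
    """Observed-to-control ratio of relation counts, with a two-tailed
    Wilcoxon signed-rank test of H0: enrichment = 1."""
    if relation not in ("inside", "outside", "crossing"):
        raise ValueError(f"unknown relation {relation!r}")
    observed = _count_relation(pccrs, features, relation)
    controls = [
        _count_relation(cat, features, relation) for cat in control_catalogs
    ]
    mean_ctrl = float(np.mean(controls)) if controls else float("nan")
    undefined = not controls or mean_ctrl == 0
    ratio = float("nan") if undefined else observed / mean_ctrl
    p_value = _signed_rank_p(controls, observed)
    lo, hi = (
        (float("nan"), float("nan"))
        if undefined
        else (
            observed / np.percentile(controls, 97.5)
            if np.percentile(controls, 97.5) > 0
            else float("inf"),
            observed / np.percentile(controls, 2.5)
            if np.percentile(controls, 2.5) > 0
            else float("inf"),
        )
    )
    return EnrichmentResult(
        observed=observed,
        control_counts=controls,
        enrichment=ratio,
        p_value=p_value,
        ci95=(lo, hi),
        undefined=undefined,
    )


def odds_ratio(
    t: ContingencyTable2x2,
) -> Tuple[float, Tuple[float, float], float, bool]:
    """(OR, 95% CI, Fisher exact p, haldane_corrected).

    OR = ad/bc with Woolf log CI; a Haldane correction of 0.5 per cell is
    applied (and flagged) when any off-diagonal cell is zero.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    corrected = b * c == 0 or a * d == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se))
    p = float(stats.fisher_exact([[t.a, t.b], [t.c, t.d]])[1])
    return float(or_), ci, p, corrected


def _near(iv: GenomicInterval, peaks: Sequence[GenomicInterval], window: int) -> bool:
    return any(
        p.chrom == iv.chrom
        and p.start < iv.end + window
        and iv.start - window < p.end
        for p in peaks
    )


def forked_peak_or(
    pccrs: Sequence,
    peaks_by_rbp: Dict[str, Sequence[GenomicInterval]],
    window: int = 50,
) -> Dict[str, Tuple[float, Tuple[float, float], float, bool]]:
    """Per-RBP odds ratio of a peak near both arms given a peak near one.

    A forked configuration (peaks flanking both arms of the duplex) is a
    signature of cross-linking next to double-stranded RNA.
    """
    out = {}
    for rbp, peaks in peaks_by_rbp.items():
        a = b = c = d = 0
        for p in pccrs:
            left = _near(p.ccr1, peaks, window)
            right = _near(p.ccr2, peaks, window)
            if left and right:
                a += 1
            elif left:
                b += 1
            elif right:
                c += 1
            else:
                d += 1
        if a + b + c == 0:
            continue  # no peaks near any arm: skip RBP
        out[rbp] = odds_ratio(ContingencyTable2x2(a, b, c, d))
    return out


def ccr_peak_enrichment(
    ccrs: Sequence[GenomicInterval],
    cirs: Sequence[CIR],
    peaks: Sequence[GenomicInterval],
    n: int = 40,
    seed: int = 0,
    min_cover: float = 0.5,
) -> EnrichmentResult:
    """CCRs covered >= 50% by peaks versus random shifts within parent CIRs."""
    rng = np.random.default_rng(seed)
    cir_of: List[GenomicInterval] = []
    for ccr in ccrs:
        host = next(
            (c.interval for c in cirs if c.interval.contains(ccr)), None
        )
        cir_of.append(host if host is not None else ccr)

    def covered(iv: GenomicInterval) -> bool:
        from .intervals import intersect_intervals

        spans = [
            (p.start, p.end) for p in peaks if p.chrom == iv.chrom
        ]
        inter = intersect_intervals([(iv.start, iv.end)], spans)
        total = sum(e - s for s, e in inter)
        return total >= min_cover * len(iv)

    observed = sum(covered(ccr) for ccr in ccrs)
    controls = []
    for _ in range(n):
        cnt = 0
        for ccr, host in zip(ccrs, cir_of):
            slack = len(host) - len(ccr)
            if slack <= 0:
                shifted = ccr
            else:
                start = host.start + int(rng.integers(0, slack + 1))
                shifted = GenomicInterval(
                    ccr.chrom, start, start + len(ccr), ccr.strand
                )
            cnt += covered(shifted)
        controls.append(cnt)
    mean_ctrl = float(np.mean(controls))
    undefined = mean_ctrl == 0
    p = _signed_rank_p(controls, observed)
    return EnrichmentResult(
        observed=observed,
        control_counts=controls,
        enrichment=float("nan") if undefined else observed / mean_ctrl,
        p_value=p,
        ci95=(float("nan"), float("nan")),
        undefined=undefined,
    )


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return sum(1 for b in seq if b in "GC") / max(len(seq), 1)


def rewire_fdr(
    cirs: Sequence[CIR],
    genes: Sequence[Gene],
    genome: Genome,
    params: SearchParams = SearchParams(),
    L: int = 10_000,
    n: int = 4,
    seed: int = 0,
    table: Optional[KmerEnergyTable] = None,
    length_tol: float = 0.10,
    gc_tol: float = 0.05,
) -> FDREstimate:
    """False discovery rate by re-wiring.

    The real pass searches every distance-eligible same-gene CIR pair.
    Each control pass replaces the second region of every real pair with
    a CIR from a DIFFERENT gene matched on length (±10%) and GC content
    (±5 points), then runs the identical search; FDR is the control
    prediction count relative to the real count (averaged over n runs).
    """
    from .catalog import enumerate_cir_pairs

    if table is None:
        table = build_kmer_table(params.k, params.max_gu)
    rng = np.random.default_rng(seed)
    by_gene: Dict[str, List[CIR]] = {}
    for c in cirs:
        by_gene.setdefault(c.gene_id, []).append(c)
    if len(by_gene) < 2:
        raise ValueError("re-wiring needs at least 2 genes")
    seqs = {id(c): genome.sense(c.interval) for c in cirs}
    gcs = {id(c): _gc_fraction(seqs[id(c)]) for c in cirs}

    real_pairs: List[Tuple[CIR, CIR]] = []
    for gene_cirs in by_gene.values():
        real_pairs.extend(enumerate_cir_pairs(gene_cirs, L))

    def n_hits(pairs: Iterable[Tuple[CIR, CIR]]) -> Tuple[int, Dict[str, int]]:
        from .catalog import assign_energy_group

        total = 0
        groups: Dict[str, int] = {}
        for c1, c2 in pairs:
            hits = find_duplexes(seqs[id(c1)], seqs[id(c2)], table, params)
            for hit in select_nonintersecting(hits):
                total += 1
                grp = assign_energy_group(hit.dG)
                groups[grp] = groups.get(grp, 0) + 1
        return total, groups

    n_real, real_groups = n_hits(real_pairs)
    control_counts = []
    control_groups: Dict[str, List[int]] = {}
    all_cirs = list(cirs)
    for _ in range(n):
        decoy_pairs = []
        for c1, c2 in real_pairs:
            want_len, want_gc = len(c2.interval), gcs[id(c2)]
            pool = [
                c
                for c in all_cirs
                if c.gene_id != c1.gene_id
                and abs(len(c.interval) - want_len) <= length_tol * want_len
                and abs(gcs[id(c)] - want_gc) <= gc_tol
            ]
            if not pool:  # relax matching rather than drop the pair
                pool = [c for c in all_cirs if c.gene_id != c1.gene_id]
                warnings.warn("re-wiring: matching bins relaxed for a pair")
            decoy_pairs.append((c1, pool[int(rng.integers(len(pool)))]))
        cnt, grp = n_hits(decoy_pairs)
        control_counts.append(cnt)
        for label, g in grp.items():
            control_groups.setdefault(label, []).append(g)
    n_control = float(np.mean(control_counts))
    fdr = n_control / n_real if n_real else float("nan")
    strata = {
        label: (np.sum(control_groups.get(label, [0])) / n) / real_groups[label]
        for label in real_groups
        if real_groups[label] > 0
    }
    return FDREstimate(
        n_real=n_real, n_control=n_control, fdr=fdr, strata=strata
    )
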