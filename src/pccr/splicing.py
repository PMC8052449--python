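"""Splicing-side statistics for long-range duplex catalogs.

Exon inclusion is quantified from split reads as Ψ = inc/(inc + 2·exc),
discarded when the denominator is below 10.  The module classifies
splice sites by pooled read support, filters candidate cryptic sites by
externally supplied strength scores, matches introns with and without
structures by length to compare transcript-end content, compares
inclusion of looped-out exons against free exons, scores catalog support
by experimental RNA-RNA contact data (precision / recall / partner
probability), detects RNA-bridge and exon-loop-out candidates from peak
geometry plus knockdown response, and computes the base-pair agreement
score used to benchmark duplex predictions against other tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CIR
from .intervals import GenomicInterval
from .nulls import ContingencyTable2x2, classify_overlap, odds_ratio
from .tracks import Genome, ScoreTrack

__all__ = [
    "psi",
    "classify_splice_sites",
    "cryptic_sites",
    "match_iwp_iwo",
    "loopout_psi_comparison",
    "structure_support",
    "StructureSupport",
    "detect_rna_bridges",
    "detect_loopouts",
    "BridgeCandidate",
    "LoopoutCandidate",
    "benchmark_score",
    "reactivity_delta",
    "editing_site_or",
]

PSI_MIN_DENOMINATOR = 10


def psi(inc: int, exc: int) -> Optional[float]:
    """Exon inclusion rate inc/(inc + 2·exc); None below denominator 10."""
    if inc < 0 or exc < 0:
        raise ValueError("negative read counts")
    denom = inc + 2 * exc
    if denom < PSI_MIN_DENOMINATOR:
        return None
    return inc / denom


@dataclass(frozen=True)
class SpliceSite:
    position: int
    side: str  # donor | acceptor
    support: int
    score: Optional[float] = None


def classify_splice_sites(
    sites: Sequence[SpliceSite],
    top_fraction: float = 0.02,
    min_support: int = 3,
) -> Dict[int, str]:
    """Label the top 2% of sites (by pooled support) active and the
    bottom 2% inactive, among sites supported by >= 3 split reads.
    Ties are broken by position so the labelling is deterministic."""
    eligible = sorted(
        (s for s in sites if s.support >= min_support),
        key=lambda s: (s.support, s.position),
    )
    n_tail = int(len(eligible) * top_fraction)
    labels: Dict[int, str] = {}
    for s in eligible[:n_tail]:
        labels[s.position] = "inactive"
    for s in eligible[len(eligible) - n_tail :]:
        labels[s.position] = "active"
    return labels


def cryptic_sites(
    candidates: Sequence[SpliceSite],
    expressed: Set[int],
    annotated: Set[int],
    donor_thr: float = 800.0,
    acceptor_thr: float = 950.0,
) -> List[SpliceSite]:
    """Strong unused splice-site motifs: externally scored candidates above
    the side-specific strength threshold that are neither expressed nor
    annotated."""
    out = []
    for s in candidates:
        if s.score is None:
            continue
        thr = donor_thr if s.side == "donor" else acceptor_thr
        if s.score > thr and s.position not in expressed and s.position not in annotated:
            out.append(s)
    return out


def _log_length_bin(length: int, width: float = 0.1) -> int:
    return int(math.log10(max(length, 1)) / width)


def match_iwp_iwo(
    introns: Sequence[GenomicInterval],
    with_pccr: Set[Tuple[str, int, int]],
    ends_3p: Sequence[GenomicInterval],
    ends_5p: Sequence[GenomicInterval],
    seed: int = 0,
) -> Dict[str, object]:
    """Length-matched comparison of introns with vs without structures.

    Introns are split into IWP (intron with PCCR) and IWO (without) by
    membership of their (chrom, start, end) in ``with_pccr``, sampled
    without replacement to equal counts per log10-length bin (width 0.1),
    and compared by whether they contain at least one annotated 3' (or
    5') transcript end; association is reported as an odds ratio.
    """
    rng = np.random.default_rng(seed)
    iwp = [iv for iv in introns if (iv.chrom, iv.start, iv.end) in with_pccr]
    iwo = [iv for iv in introns if (iv.chrom, iv.start, iv.end) not in with_pccr]
    bins_iwp: Dict[int, List[GenomicInterval]] = {}
    bins_iwo: Dict[int, List[GenomicInterval]] = {}
    for iv in iwp:
        bins_iwp.setdefault(_log_length_bin(len(iv)), []).append(iv)
    for iv in iwo:
        bins_iwo.setdefault(_log_length_bin(len(iv)), []).append(iv)
    sel_iwp: List[GenomicInterval] = []
    sel_iwo: List[GenomicInterval] = []
    for b in sorted(set(bins_iwp) & set(bins_iwo)):
        k = min(len(bins_iwp[b]), len(bins_iwo[b]))
        sel_iwp.extend(
            bins_iwp[b][i] for i in rng.choice(len(bins_iwp[b]), k, replace=False)
        )
        sel_iwo.extend(
            bins_iwo[b][i] for i in rng.choice(len(bins_iwo[b]), k, replace=False)
        )

    def contains_end(iv: GenomicInterval, ends: Sequence[GenomicInterval]) -> bool:
        return any(
            e.chrom == iv.chrom and iv.start <= e.start and e.end <= iv.end
            for e in ends
        )

    out: Dict[str, object] = {
        "n_matched": len(sel_iwp),
        "iwp": sel_iwp,
        "iwo": sel_iwo,
    }
    for label, ends in (("3p", ends_3p), ("5p", ends_5p)):
        a = sum(contains_end(iv, ends) for iv in sel_iwp)
        c = sum(contains_end(iv, ends) for iv in sel_iwo)
        table = ContingencyTable2x2(a, len(sel_iwp) - a, c, len(sel_iwo) - c)
        if len(ends) == 0:
            out[f"or_{label}"] = None
            continue
        out[f"or_{label}"] = odds_ratio(table)
        out[f"pct_iwp_{label}"] = 100.0 * a / len(sel_iwp) if sel_iwp else float("nan")
        out[f"pct_iwo_{label}"] = 100.0 * c / len(sel_iwo) if sel_iwo else float("nan")
    return out


def loopout_psi_comparison(
    exons: Sequence[GenomicInterval],
    pccrs: Sequence,
    quants: pd.DataFrame,
    by_group: bool = True,
) -> Dict[str, Dict[str, object]]:
    """Ψ of exons looped out by structures vs exons that are not.

    An exon is looped out when it lies strictly between the two arms.
    Returns, per energy group (and pooled under "all"), the two Ψ
    samples and the two-sample Kolmogorov-Smirnov test.
    """
    psis = {}
    for row in quants.itertuples(index=False):
        value = psi(int(row.inc), int(row.exc))
        if value is not None:
            psis[row.exon_id] = value
    looped_by_group: Dict[str, Set[str]] = {}
    looped_all: Set[str] = set()
    for p in pccrs:
        for exon in exons:
            if classify_overlap(p, exon) == "outside":
                looped_all.add(exon.name)
                looped_by_group.setdefault(p.energy_group, set()).add(exon.name)
    results: Dict[str, Dict[str, object]] = {}
    groups = {"all": looped_all}
    if by_group:
        groups.update(looped_by_group)
    for label, looped in groups.items():
        sample = [psis[e] for e in psis if e in looped]
        control = [psis[e] for e in psis if e not in looped_all]
        if len(sample) < 2 or len(control) < 2:
            continue
        ks = stats.ks_2samp(sample, control)
        results[label] = {
            "looped_psi": sample,
            "control_psi": control,
            "ks_stat": float(ks.statistic),
            "p_value": float(ks.pvalue),
        }
    if not results and (len(looped_all) == len(psis) or not psis):
        raise ValueError("no control exons available for comparison")
    return results


@dataclass(frozen=True)
class StructureSupport:
    P: float  # precision, %
    R: float  # recall, %
    pi: float  # correct-partner probability, %
    n_pccr: int
    n_experimental: int


def _arm_overlap(ccr: GenomicInterval, side: GenomicInterval) -> bool:
    return ccr.overlaps(side)


def structure_support(
    pccrs: Sequence,
    experimental_pairs: Sequence[Tuple[GenomicInterval, GenomicInterval]],
    L: int = 10_000,
) -> StructureSupport:
    """Agreement with experimentally determined RNA-RNA contacts.

    P: % of structures whose two arms both overlap (>= 1 nt) the two
    sides of some experimental pair.  R: % of experimental pairs so
    matched.  pi: among structures with at least one arm matching either
    side of some pair, the % whose partner arm is also correct.
    """
    if not experimental_pairs:
        raise ValueError("empty experimental set")
    matched_exp = [False] * len(experimental_pairs)
    n_true = 0
    n_partial = 0
    for p in pccrs:
        full = False
        partial = False
        for idx, (side1, side2) in enumerate(experimental_pairs):
            hit11 = _arm_overlap(p.ccr1, side1)
            hit12 = _arm_overlap(p.ccr1, side2)
            hit21 = _arm_overlap(p.ccr2, side1)
            hit22 = _arm_overlap(p.ccr2, side2)
            if (hit11 and hit22) or (hit12 and hit21):
                full = True
                matched_exp[idx] = True
            if hit11 or hit12 or hit21 or hit22:
                partial = True
        n_true += full
        n_partial += partial
    n = len(pccrs)
    return StructureSupport(
        P=100.0 * n_true / n if n else 0.0,
        R=100.0 * sum(matched_exp) / len(experimental_pairs),
        pi=100.0 * n_true / n_partial if n_partial else 0.0,
        n_pccr=n,
        n_experimental=len(experimental_pairs),
    )


@dataclass(frozen=True)
class BridgeCandidate:
    pccr_id: Optional[int]
    rbp: str
    exon_id: str
    delta_psi: float
    q_value: float


@dataclass(frozen=True)
class LoopoutCandidate:
    pccr_id: Optional[int]
    rbp: str
    exon_id: str
    delta_psi: float
    q_value: float


def _within(iv: GenomicInterval, other: GenomicInterval, window: int) -> bool:
    """Nearest-boundary distance between two intervals <= window."""
    if iv.chrom != other.chrom:
        return False
    if iv.overlaps(other):
        return True
    gap = max(other.start - iv.end, iv.start - other.end)
    return gap <= window


def detect_rna_bridges(
    pccrs: Sequence,
    peaks_by_rbp: Dict[str, Sequence[GenomicInterval]],
    exons: Sequence[GenomicInterval],
    kd_results: pd.DataFrame,
    window: int = 50,
    max_q: float = 0.01,
) -> List[BridgeCandidate]:
    """RNA bridges: a peak within ``window`` of one arm, a regulated exon
    within ``window`` of the mate arm, and a significant inclusion
    response of that exon to the factor's knockdown (q < 0.01)."""
    kd = {
        (row.exon_id, row.rbp): (row.delta_psi, row.q_value)
        for row in kd_results.itertuples(index=False)
    }
    out: List[BridgeCandidate] = []
    for p in pccrs:
        for rbp, peaks in peaks_by_rbp.items():
            near1 = any(_within(p.ccr1, pk, window) for pk in peaks)
            near2 = any(_within(p.ccr2, pk, window) for pk in peaks)
            for exon in exons:
                for peak_arm, exon_arm in ((p.ccr1, p.ccr2), (p.ccr2, p.ccr1)):
                    has_peak = near1 if peak_arm is p.ccr1 else near2
                    if not has_peak:
                        continue
                    if not _within(exon_arm, exon, window):
                        continue
                    resp = kd.get((exon.name, rbp))
                    if resp is None or resp[1] >= max_q:
                        continue
                    cand = BridgeCandidate(
                        pccr_id=getattr(p, "pccr_id", None),
                        rbp=rbp,
                        exon_id=exon.name,
                        delta_psi=resp[0],
                        q_value=resp[1],
                    )
                    if cand not in out:
                        out.append(cand)
    return out


def detect_loopouts(
    pccrs: Sequence,
    peaks_by_rbp: Dict[str, Sequence[GenomicInterval]],
    exons: Sequence[GenomicInterval],
    kd_results: pd.DataFrame,
    max_q: float = 0.01,
) -> List[LoopoutCandidate]:
    """Exon loop-outs: the structure surrounds an exon (strictly between
    the arms), a peak overlaps one of the arms, and the exon responds to
    that factor's knockdown (q < 0.01)."""
    kd = {
        (row.exon_id, row.rbp): (row.delta_psi, row.q_value)
        for row in kd_results.itertuples(index=False)
    }
    out: List[LoopoutCandidate] = []
    for p in pccrs:
        for rbp, peaks in peaks_by_rbp.items():
            on_arm = any(
                pk.overlaps(p.ccr1) or pk.overlaps(p.ccr2) for pk in peaks
            )
            if not on_arm:
                continue
            for exon in exons:
                if classify_overlap(p, exon) != "outside":
                    continue
                resp = kd.get((exon.name, rbp))
                if resp is None or resp[1] >= max_q:
                    continue
                cand = LoopoutCandidate(
                    pccr_id=getattr(p, "pccr_id", None),
                    rbp=rbp,
                    exon_id=exon.name,
                    delta_psi=resp[0],
                    q_value=resp[1],
                )
                if cand not in out:
                    out.append(cand)
    return out


def benchmark_score(S1: Set, S2: Set) -> float:
    """|S1 ∩ S2| / |S1|: fraction of predicted base pairs found in the
    other prediction."""
    if not S1:
        raise ValueError("S1 must be nonempty")
    return len(set(S1) & set(S2)) / len(S1)


def reactivity_delta(
    pccrs: Sequence,
    cirs: Sequence[CIR],
    reactivity: ScoreTrack,
    n_controls: int = 1,
    seed: int = 0,
) -> Dict[str, object]:
    """Per-arm reactivity drop and its regression on the energy group.

    For each arm: mean reactivity of its paired nucleotides minus the
    mean of equally many randomly chosen covered nucleotides in the same
    parent conserved region outside the arm.  The slope β1 of an OLS fit
    of Δreactivity on the energy-group index (I..IV -> 1..4) quantifies
    the stability dependence; a signed-rank test for Δ < 0 is included.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    group_index = {"I": 1, "II": 2, "III": 3, "IV": 4}
    deltas, groups = [], []
    for p in pccrs:
        for arm, paired_pos in (
            (p.ccr1, [g1 for g1, _ in p.structure]),
            (p.ccr2, [g2 for _, g2 in p.structure]),
        ):
            host = next(
                (c.interval for c in cirs if c.interval.contains(arm)), None
            )
            if host is None:
                continue
            vals = [reactivity.values(arm.chrom, g, g + 1)[0] for g in paired_pos]
            outside = [
                pos
                for pos in range(host.start, host.end)
                if not (arm.start <= pos < arm.end)
            ]
            if not outside or not vals:
                continue
            pick = rng.choice(len(outside), size=min(len(vals), len(outside)),
                              replace=False)
            ctrl = [
                reactivity.values(arm.chrom, outside[i], outside[i] + 1)[0]
                for i in pick
            ]
            deltas.append(float(np.mean(vals) - np.mean(ctrl)))
            groups.append(group_index[p.energy_group])
    if not deltas:
        return {"deltas": [], "beta1": float("nan"), "p_value": float("nan")}
    X = sm.add_constant(np.asarray(groups, dtype=float))
    fit = sm.OLS(np.asarray(deltas), X).fit()
    nonzero = [d for d in deltas if d != 0]
    wil = stats.wilcoxon(nonzero).pvalue if nonzero else 1.0
    return {
        "deltas": deltas,
        "groups": groups,
        "beta1": float(fit.params[1]) if len(fit.params) > 1 else float("nan"),
        "beta1_se": float(fit.bse[1]) if len(fit.bse) > 1 else float("nan"),
        "p_value": float(wil),
    }


def editing_site_or(
    ccrs: Sequence[GenomicInterval],
    cirs: Sequence[CIR],
    editing_sites: Sequence[GenomicInterval],
    genome: Genome,
) -> Tuple[float, Tuple[float, float], float, bool]:
    """Odds ratio of sense-strand adenosines being editing sites inside
    vs outside the arms, within the conserved search regions."""
    edited = {(e.chrom, e.start) for e in editing_sites}
    ccr_pos: Set[Tuple[str, int]] = set()
    for ccr in ccrs:
        for pos in range(ccr.start, ccr.end):
            ccr_pos.add((ccr.chrom, pos))
    a = b = c = d = 0
    seen: Set[Tuple[str, int]] = set()
    for cir in cirs:
        sense_a = "A" if cir.strand == "+" else "T"
        for pos in range(cir.interval.start, cir.interval.end):
            key = (cir.chrom, pos)
            if key in seen:
                continue
            seen.add(key)
            if genome.fetch(cir.chrom, pos, pos + 1) != sense_a:
                continue
            is_edit = key in edited
            inside = key in ccr_pos
            if inside and is_edit:
                a += 1
            elif inside:
                b += 1
            elif is_edit:
                c += 1
            else:
                d += 1
    if a + b + c + d == 0:
        raise ValueError("no adenosines in the conserved regions")
    if not editing_sites:
        raise ValueError("empty editing set")
    return odds_ratio(ContingencyTable2x2(a, b, c, d))
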