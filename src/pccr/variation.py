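"""Population polymorphism statistics and covariation aggregation.

Covers four analyses of how human variation interacts with long-range
duplexes: (1) SNP density inside the paired arms versus the surrounding
conserved background (one-tailed Poisson test for depletion); (2) the
free-energy impact of an observed SNP compared with the impact the same
substitution would have had elsewhere in the arm (fixed topology: a pair
broken by the mutation loses its adjacent stacking terms, no refolding);
(3) compensatory population polymorphisms — base pairs where common
variants on both sides restore an admissible pair — with a re-wiring
null that permutes pairing partners within groups of identical pair
type, chromosome and donor count; and (4) aggregation of per-base-pair
covariation E values into per-structure products with BH adjustment,
plus Stockholm export of paired alignment blocks for covariation tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .energies import ADMISSIBLE, to_rna
from .intervals import GenomicInterval, merge_intervals

__all__ = [
    "SNVRecord",
    "read_vcf",
    "snp_density_test",
    "snp_ddg",
    "fixed_topology_energy",
    "BasePairSNP",
    "compensatory_counts",
    "rewire_basepairs",
    "compensatory_rewiring_test",
    "aggregate_evalues",
    "export_stockholm",
]

#: admissible base pairs in DNA alphabet (WC + GT wobble)
DNA_ADMISSIBLE = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)


@dataclass(frozen=True)
class SNVRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    af: float  # carrier fraction

    def __post_init__(self):
        if not (0 < self.af <= 1):
            raise ValueError("carrier fraction must be in (0, 1]")


def read_vcf(path, min_af: float = 0.0) -> List[SNVRecord]:
    """Biallelic SNVs from a VCF; multi-allelic records are split."""
    import pysam

    out: List[SNVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index else vcf:
            if rec.alts is None:
                continue
            af_field = rec.info.get("AF")
            for idx, alt in enumerate(rec.alts):
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue
                if af_field is None:
                    af = 0.5
                elif isinstance(af_field, tuple):
                    af = float(af_field[idx])
                else:
                    af = float(af_field)
                if af >= min_af and af > 0:
                    out.append(
                        SNVRecord(rec.chrom, rec.pos - 1, rec.ref, alt, min(af, 1.0))
                    )
    return out


def snp_density_test(
    snvs: Sequence[SNVRecord],
    ccr_regions: Sequence[GenomicInterval],
    background_regions: Sequence[GenomicInterval],
) -> Tuple[float, float, float]:
    """(density_ccr, density_bg, p) with a one-tailed Poisson test for
    density_ccr < density_bg.  Regions are merged before measuring."""

    def merged_len_and_count(regions):
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in regions:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        total = 0
        spans = {}
        for chrom, lst in by_chrom.items():
            m = merge_intervals(lst)
            spans[chrom] = m
            total += sum(e - s for s, e in m)
        count = sum(
            1
            for v in snvs
            if any(s <= v.pos < e for s, e in spans.get(v.chrom, ()))
        )
        return total, count

    len_ccr, n_ccr = merged_len_and_count(ccr_regions)
    len_bg, n_bg = merged_len_and_count(background_regions)
    if len_ccr == 0 or len_bg == 0:
        raise ValueError("empty region set")
    d_ccr, d_bg = n_ccr / len_ccr, n_bg / len_bg
    mu = d_bg * len_ccr  # expected CCR count at the background rate
    p = float(stats.poisson.cdf(n_ccr, mu))
    return d_ccr, d_bg, p


def fixed_topology_energy(
    base_pairs: Sequence[Tuple[int, int]], seq1: str, seq2: str, m: int = 2
) -> float:
    """Duplex energy on a FIXED pair topology tolerating broken pairs.

    Pairs whose nucleotides are no longer admissible contribute no
    stacking (both adjacent stack terms are dropped); loop penalties of
    the original topology are kept.  Used to score mutated sequences
    against the structure predicted for the reference.
    """
    from .energies import loop_penalty, stack_energy

    s1, s2 = to_rna(seq1), to_rna(seq2)
    intact = [
        (i, j) for i, j in base_pairs if (s1[i], s2[j]) in ADMISSIBLE
    ]
    intact_set = set(intact)
    total = 0.0
    for (pi, pj), (i, j) in zip(base_pairs, base_pairs[1:]):
        if i == pi + 1 and j == pj - 1:
            if (pi, pj) in intact_set and (i, j) in intact_set:
                total += stack_energy((s1[pi], s2[pj]), (s1[i], s2[j]))
        else:
            total += loop_penalty(i - pi - 1, pj - j - 1, m=m)
    return total


def snp_ddg(
    base_pairs: Sequence[Tuple[int, int]],
    seq1: str,
    seq2: str,
    snv_offset: int,
    alt: str,
    arm: int = 1,
    rng: Optional[np.random.Generator] = None,
    max_positions: Optional[int] = None,
) -> Tuple[float, np.ndarray]:
    """ΔΔG of an observed substitution vs the same substitution elsewhere.

    ``snv_offset`` indexes the mutated arm's sense sequence (``arm`` 1 or
    2); ``alt`` is the alternative base (RNA or DNA alphabet).  Returns
    the actual ΔΔG and the null distribution over every alternative
    position in the same arm that carries the reference allele.  Raises
    if the SNV does not fall in a paired position.
    """
    s1, s2 = to_rna(seq1), to_rna(seq2)
    alt = to_rna(alt)
    paired = {i for i, _ in base_pairs} if arm == 1 else {j for _, j in base_pairs}
    if snv_offset not in paired:
        raise ValueError("SNV outside paired positions")
    seq = s1 if arm == 1 else s2
    ref = seq[snv_offset]
    e_ref = fixed_topology_energy(base_pairs, s1, s2)

    def mutated_energy(offset: int) -> float:
        mut = seq[:offset] + alt + seq[offset + 1 :]
        if arm == 1:
            return fixed_topology_energy(base_pairs, mut, s2)
        return fixed_topology_energy(base_pairs, s1, mut)

    ddg_actual = mutated_energy(snv_offset) - e_ref
    alt_positions = [
        pos for pos in sorted(paired) if pos != snv_offset and seq[pos] == ref
    ]
    if max_positions is not None and len(alt_positions) > max_positions:
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.choice(len(alt_positions), size=max_positions, replace=False)
        alt_positions = [alt_positions[i] for i in sorted(idx)]
    null = np.array([mutated_energy(pos) - e_ref for pos in alt_positions])
    return ddg_actual, null


@dataclass(frozen=True)
class BasePairSNP:
    """One base pair of a catalog structure with the variants touching it.

    ``left``/``right`` are genomic (chrom, pos, ref) in DNA alphabet;
    ``left_snvs``/``right_snvs`` are the qualifying variants at the two
    positions.  ``pair_type`` is e.g. "AT", "GC", "TG" on the genome.
    """

    chrom: str
    left_pos: int
    right_pos: int
    left_ref: str
    right_ref: str
    left_snvs: Tuple[SNVRecord, ...] = ()
    right_snvs: Tuple[SNVRecord, ...] = ()

    @property
    def pair_type(self) -> str:
        return self.left_ref + self.right_ref

    def donor_count(self, cohort_size: int = 2504) -> int:
        """Number of individuals carrying any variant at this pair,
        reconstructed from carrier fractions for a cohort of the given
        size (assuming distinct carriers across variants)."""
        total = sum(v.af for v in self.left_snvs + self.right_snvs)
        return int(round(min(total, 1.0) * cohort_size))


def _is_compensatory(bp: BasePairSNP) -> bool:
    return any(
        (l.alt, r.alt) in DNA_ADMISSIBLE
        for l in bp.left_snvs
        for r in bp.right_snvs
    )


def compensatory_counts(
    base_pairs: Sequence[BasePairSNP],
    min_af: float = 0.01,
) -> Tuple[int, int]:
    """(pairs touched by >=1 qualifying SNV, pairs with a compensatory
    change): both sides carry a qualifying variant and the two
    alternative alleles form an admissible (WC or wobble) pair."""
    touched = compensatory = 0
    for bp in base_pairs:
        filt = BasePairSNP(
            chrom=bp.chrom,
            left_pos=bp.left_pos,
            right_pos=bp.right_pos,
            left_ref=bp.left_ref,
            right_ref=bp.right_ref,
            left_snvs=tuple(v for v in bp.left_snvs if v.af >= min_af),
            right_snvs=tuple(v for v in bp.right_snvs if v.af >= min_af),
        )
        if filt.left_snvs or filt.right_snvs:
            touched += 1
        if _is_compensatory(filt):
            compensatory += 1
    return touched, compensatory


def rewire_basepairs(
    base_pairs: Sequence[BasePairSNP],
    rng: np.random.Generator,
    cohort_size: int = 2504,
) -> List[BasePairSNP]:
    """Randomly interchange pairing partners within groups of base pairs
    of the same pair type, chromosome, and SNP donor count.

    Within a group (A1·T1, A2·T2, ...) the right partners are permuted
    uniformly, e.g. giving A1·T2 and A2·T1; the pair-type multiset and
    group sizes are preserved exactly.  The donor count is the carrier
    count reconstructed from allele frequencies (see
    :meth:`BasePairSNP.donor_count`).
    """
    groups: Dict[Tuple[str, str, int], List[int]] = {}
    for idx, bp in enumerate(base_pairs):
        key = (bp.pair_type, bp.chrom, bp.donor_count(cohort_size))
        groups.setdefault(key, []).append(idx)
    out: List[Optional[BasePairSNP]] = [None] * len(base_pairs)
    for indices in groups.values():
        perm = rng.permutation(len(indices))
        for slot, src in zip(indices, (indices[p] for p in perm)):
            left = base_pairs[slot]
            right = base_pairs[src]
            out[slot] = BasePairSNP(
                chrom=left.chrom,
                left_pos=left.left_pos,
                right_pos=right.right_pos,
                left_ref=left.left_ref,
                right_ref=right.right_ref,
                left_snvs=left.left_snvs,
                right_snvs=right.right_snvs,
            )
    return [bp for bp in out if bp is not None]


def compensatory_rewiring_test(
    base_pairs: Sequence[BasePairSNP],
    n: int = 100,
    seed: int = 0,
    min_af: float = 0.01,
) -> Dict[str, float]:
    """Observed vs re-wired compensatory counts with a one-tailed Poisson p."""
    touched, observed = compensatory_counts(base_pairs, min_af=min_af)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n):
        rewired = rewire_basepairs(base_pairs, rng)
        _, c = compensatory_counts(rewired, min_af=min_af)
        null.append(c)
    mean_null = float(np.mean(null))
    p = float(stats.poisson.sf(observed - 1, max(mean_null, 1e-12)))
    return {
        "n_touched": touched,
        "observed": observed,
        "null_mean": mean_null,
        "density_pct": 100.0 * observed / touched if touched else float("nan"),
        "null_density_pct": 100.0 * mean_null / touched if touched else float("nan"),
        "p_value": p,
    }


def aggregate_evalues(
    per_pccr: Sequence[Tuple[Sequence[float], Sequence[bool]]],
) -> pd.DataFrame:
    """Per-structure covariation E value and BH adjustment.

    Each element is (per-base-pair E values, significance flags from the
    covariation software).  The structure's E value is the product over
    flagged pairs (empty product = 1).  Benjamini-Hochberg adjustment is
    applied across the structures with E value < 1, as elsewhere values
    of exactly 1 carry no covariation information.
    """
    from statsmodels.stats.multitest import multipletests

    evalues = []
    for values, flags in per_pccr:
        values = list(values)
        if any(v < 0 for v in values):
            raise ValueError("negative E value")
        prod = 1.0
        for v, f in zip(values, flags):
            if f:
                prod *= v
        evalues.append(prod)
    df = pd.DataFrame({"evalue": evalues})
    df["evalue_adj"] = np.nan
    mask = df["evalue"] < 1
    if mask.any():
        clipped = df.loc[mask, "evalue"].clip(upper=1.0)
        df.loc[mask, "evalue_adj"] = multipletests(
            clipped, method="fdr_bh"
        )[1]
    return df


SPACER = "A" * 10


def export_stockholm(
    block1: Sequence[Tuple[str, str]],
    block2: Sequence[Tuple[str, str]],
    structure: Sequence[Tuple[int, int]],
    path=None,
    min_rows: int = 15,
) -> str:
    """Merge two arm alignments into one Stockholm alignment with SS_cons.

    ``block1``/``block2`` are (taxon, aligned sequence) rows; rows with
    indels (gaps) relative to the reference are dropped, and the
    surviving taxa must coincide between blocks.  The blocks are joined
    by a 10-adenine spacer; ``structure`` lists (column in block 1,
    column in block 2) base pairs annotated as ``<``/``>`` in SS_cons.
    """
    from io import StringIO

    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import AlignIO

    taxa1 = [t for t, _ in block1]
    taxa2 = [t for t, _ in block2]
    mismatch = sorted(set(taxa1) ^ set(taxa2))
    if mismatch:
        raise ValueError(f"taxa differ between blocks: {mismatch}")
    rows1, rows2 = dict(block1), dict(block2)
    # organisms with an indel in either arm are removed
    common = [
        t
        for t in taxa1
        if "-" not in rows1[t] + rows2[t] and "." not in rows1[t] + rows2[t]
    ]
    if len(common) < min_rows:
        raise ValueError(
            f"only {len(common)} gap-free rows; need >= {min_rows}"
        )
    w1 = len(next(iter(rows1.values())))
    w2 = len(next(iter(rows2.values())))
    ss = ["."] * (w1 + len(SPACER) + w2)
    for c1, c2 in structure:
        if not (0 <= c1 < w1 and 0 <= c2 < w2):
            raise ValueError(f"structure column ({c1},{c2}) out of range")
        ss[c1] = "<"
        ss[w1 + len(SPACER) + c2] = ">"
    records = [
        SeqRecord(Seq(rows1[t] + SPACER + rows2[t]), id=t, description="")
        for t in common
    ]
    msa = MultipleSeqAlignment(records)
    msa.column_annotations["secondary_structure"] = "".join(ss)
    buf = StringIO()
    AlignIO.write(msa, buf, "stockholm")
    text = buf.getvalue()
    if path is not None:
        with open(str(path), "w") as fh:
            fh.write(text)
    return text
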