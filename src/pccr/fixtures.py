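"""Deterministic toy genomes and feature tracks with planted ground truth.

The generator emulates the standard inputs of the pipeline — genome FASTA,
gene annotation GTF, conserved-element BED, and the optional SNV / peak /
editing / reactivity / junction tracks — on a scale where every planted
signal is known exactly.  Panhandles are planted by writing a stem
sequence and its (optionally loop-interrupted) complement into two
intronic conserved islands of the same gene at a controlled spread; decoy
islands contain shuffled stem sequence so that the false-discovery
machinery has realistic non-cognate complementarity to chew on.
Background sequence is i.i.d. with configurable GC content.  All
randomness flows from a single mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import CIR, Gene
from .duplex import SearchParams, find_duplexes
from .energies import (
    WATSON_CRICK,
    WOBBLE,
    KmerEnergyTable,
    build_kmer_table,
    duplex_energy,
    revcomp_dna,
)
from .intervals import GenomicInterval
from .tracks import Genome

__all__ = ["FixtureSpec", "PlantedDuplex", "ToyGenome", "ToyTracks",
           "make_toy_genome", "make_toy_tracks"]

_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
_LOOP_SIZES = ((0, 1), (1, 0), (1, 1), (0, 2), (2, 0), (1, 2), (2, 1), (2, 2))
_PLANT_PARAMS = SearchParams()


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the toy genome; the seed is mandatory."""

    seed: int
    n_genes: int = 50
    gene_length: Tuple[int, int] = (6_000, 14_000)
    exon_count: Tuple[int, int] = (2, 4)
    n_panhandles: int = 120
    dg_range: Tuple[float, float] = (-40.0, -15.0)
    spread_range: Tuple[int, int] = (100, 9_000)
    loop_prob: float = 0.3
    wobble_prob: float = 0.1
    decoys_per_gene: int = 2
    gc_background: float = 0.45
    intergenic: int = 300
    margin_max: int = 3
    # track-generation conditions
    snv_rate: float = 0.02
    snv_ccr_depletion: float = 0.10
    n_compensatory: int = 3
    peak_mode: str = "independent"  # independent | forked | on-ccr
    peak_prob: float = 0.3
    editing_rate_ccr: float = 0.30
    editing_rate_bg: float = 0.03
    reactivity_depression: float = 0.5
    loopout_delta_psi: float = -0.2
    mean_junction_reads: int = 60

    def __post_init__(self):
        for lo, hi in (self.gene_length, self.exon_count, self.spread_range):
            if lo > hi:
                raise ValueError("invalid range in fixture spec")
        if self.dg_range[0] > self.dg_range[1]:
            raise ValueError("invalid dg_range")


@dataclass(frozen=True)
class PlantedDuplex:
    """Ground truth for one planted panhandle."""

    gene_id: str
    ccr1: GenomicInterval  # transcription order
    ccr2: GenomicInterval
    island1: GenomicInterval  # conserved islands hosting the arms
    island2: GenomicInterval
    base_pairs: Tuple[Tuple[int, int], ...]  # genomic coordinates
    dG: float
    seq1: str  # sense-strand RNA of arm 1
    seq2: str
    sense_pairs: Tuple[Tuple[int, int], ...]  # (i into seq1, j into seq2)


@dataclass
class ToyGenome:
    spec: FixtureSpec
    genome: Genome
    genes: List[Gene]
    conserved: List[GenomicInterval]
    truth: List[PlantedDuplex]
    chrom_seqs: Dict[str, str]


@dataclass
class ToyTracks:
    snvs: "object"  # pandas DataFrame: chrom pos ref alt af
    compensatory_pairs: List[Tuple[Tuple[int, int], Tuple[str, str]]]
    peaks_by_rbp: Dict[str, List[GenomicInterval]]
    editing_sites: List[GenomicInterval]
    reactivity: Dict[str, np.ndarray]
    junctions: "object"  # DataFrame: exon_id inc exc
    exons: List[GenomicInterval]
    looped_exons: List[str]
    polya: List[GenomicInterval]
    cage: List[GenomicInterval]


def _draw_stem(
    rng: np.random.Generator,
    target: float,
    loop: Optional[Tuple[int, int]],
    wobble_prob: float,
    table: KmerEnergyTable,
    k: int = 5,
) -> Tuple[str, str, Tuple[Tuple[int, int], ...], float]:
    """Grow a stem until its energy reaches ``target``; returns the two
    sense sequences, the (i, j) pair list, and the exact energy."""
    for _ in range(200):
        pairs_letters: List[Tuple[str, str]] = []
        n_target = max(10, int(abs(target) / 2))
        while len(pairs_letters) < 40:
            a = rng.choice(list("ACGU"))
            if rng.random() < wobble_prob and a in "GU":
                b = "U" if a == "G" else "G"
            else:
                b = _WC_PARTNER[a]
            pairs_letters.append((a, b))
            if len(pairs_letters) >= n_target:
                s1x = "".join(p[0] for p in pairs_letters)
                s2x = "".join(p[1] for p in pairs_letters)[::-1]
                bp = tuple(
                    (i, len(pairs_letters) - 1 - i)
                    for i in range(len(pairs_letters))
                )
                try:
                    e = duplex_energy(bp, s1x, s2x, k=k, table=table)
                except ValueError:
                    break  # wobble window violation; redraw
                if e <= target:
                    n = len(pairs_letters)
                    if loop is None or n < 2 * k + 1:
                        return s1x, s2x, bp, e
                    # split into two helices around an internal loop
                    a_sz, b_sz = loop
                    h1 = rng.integers(k, n - k + 1)
                    left = pairs_letters[:h1]
                    right = pairs_letters[h1:]
                    loop1 = "".join(rng.choice(list("AC"), a_sz))
                    loop2 = "".join(rng.choice(list("CA"), b_sz))
                    s1x = (
                        "".join(p[0] for p in left)
                        + loop1
                        + "".join(p[0] for p in right)
                    )
                    s2x = (
                        "".join(p[1] for p in right)[::-1]
                        + loop2
                        + "".join(p[1] for p in left)[::-1]
                    )
                    bp_list: List[Tuple[int, int]] = []
                    L2 = len(s2x)
                    for i in range(h1):
                        bp_list.append((i, L2 - 1 - i))
                    for t in range(len(right)):
                        bp_list.append((h1 + a_sz + t, len(right) - 1 - t))
                    bp = tuple(bp_list)
                    try:
                        e = duplex_energy(bp, s1x, s2x, k=k, table=table)
                    except ValueError:
                        break
                    return s1x, s2x, bp, e
    raise RuntimeError("could not draw a stem matching the requested energy")


def _gene_layout(
    rng: np.random.Generator, spec: FixtureSpec, start: int, gid: str, chrom: str
) -> Gene:
    length = int(rng.integers(spec.gene_length[0], spec.gene_length[1] + 1))
    n_ex = int(rng.integers(spec.exon_count[0], spec.exon_count[1] + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    exon_lens = rng.integers(80, 200, n_ex)
    intron_total = length - int(exon_lens.sum())
    if intron_total < (n_ex - 1) * 400:
        exon_lens = np.full(n_ex, 80)
        intron_total = length - int(exon_lens.sum())
    cuts = np.sort(rng.random(n_ex - 2)) if n_ex > 2 else np.array([])
    parts = np.diff(np.concatenate([[0.0], cuts, [1.0]])) if n_ex > 1 else []
    intron_lens = [max(400, int(round(p * intron_total))) for p in parts]
    exons = []
    pos = start
    for idx in range(n_ex):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[idx]), strand))
        pos += int(exon_lens[idx])
        if idx < n_ex - 1:
            pos += intron_lens[idx]
    return Gene(
        id=gid,
        interval=GenomicInterval(chrom, start, pos, strand, name=gid),
        exons=tuple(exons),
    )


def _introns(gene: Gene) -> List[Tuple[int, int]]:
    out = []
    for e1, e2 in zip(gene.exons, gene.exons[1:]):
        out.append((e1.end, e2.start))
    return out


def make_toy_genome(spec: FixtureSpec, out_dir: Optional[str] = None) -> ToyGenome:
    """Generate the toy genome, annotation, conserved track, and truth.

    With ``out_dir``, also writes genome.fa, genes.gtf, conserved.bed and
    ground_truth.tsv; outputs are byte-identical for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    table = build_kmer_table(5, 2)
    chrom = "chr1"
    genes: List[Gene] = []
    pos = spec.intergenic
    for g in range(spec.n_genes):
        gene = _gene_layout(rng, spec, pos, f"g{g + 1:03d}", chrom)
        genes.append(gene)
        pos = gene.interval.end + spec.intergenic
    chrom_len = pos + spec.intergenic
    p_gc = spec.gc_background
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    seq = rng.choice(list("ACGT"), size=chrom_len, p=probs)

    margin_pad = 15  # clearance from exon boundaries and between islands
    truth: List[PlantedDuplex] = []
    conserved: List[GenomicInterval] = []
    occupied: Dict[str, List[Tuple[int, int]]] = {g.id: [] for g in genes}

    def free_slot(gene: Gene, size: int, lo: int, hi: int, rng) -> Optional[int]:
        """A start position for ``size`` nts inside [lo, hi) clear of
        exon pads and previous islands."""
        spans = []
        for s, e in _introns(gene):
            s2, e2 = max(s + margin_pad, lo), min(e - margin_pad, hi)
            if e2 - s2 >= size:
                spans.append((s2, e2))
        rng.shuffle(spans)
        for s2, e2 in spans:
            for _ in range(20):
                cand = int(rng.integers(s2, e2 - size + 1))
                if all(
                    cand + size + margin_pad <= os or cand >= oe + margin_pad
                    for os, oe in occupied[gene.id]
                ):
                    return cand
        return None

    lo_dg, hi_dg = spec.dg_range
    for idx in range(spec.n_panhandles):
        gene = genes[idx % len(genes)]
        placed = False
        for _ in range(60):
            # leave headroom for the last stack's overshoot (<= 3.42)
            t_hi = hi_dg - 0.5
            t_lo = min(lo_dg + 3.6, t_hi)
            target = float(rng.uniform(t_lo, t_hi))
            loop = (
                tuple(_LOOP_SIZES[rng.integers(len(_LOOP_SIZES))])
                if rng.random() < spec.loop_prob
                else None
            )
            s1, s2, bp, e = _draw_stem(
                rng, target, loop, spec.wobble_prob, table
            )
            if not (lo_dg <= e <= hi_dg):
                continue
            # reject stems whose own optimal fold differs from the plant
            # (the search is independently validated against enumeration)
            probe = find_duplexes(s1, s2, table, _PLANT_PARAMS)
            if not probe or probe[0].structure.base_pairs != bp:
                continue
            m1 = int(rng.integers(0, spec.margin_max + 1))
            m2 = int(rng.integers(0, spec.margin_max + 1))
            spread = int(rng.integers(spec.spread_range[0], spec.spread_range[1] + 1))
            # genomic layout: on plus strand arm 1 (transcriptionally first)
            # is the left island; on minus strand it is the right island
            if gene.strand == "+":
                seq_left, m_left, seq_right, m_right = s1, m1, s2, m2
            else:
                seq_left, m_left, seq_right, m_right = s2, m2, s1, m1
            size_left = len(seq_left) + 2 * m_left
            size_right = len(seq_right) + 2 * m_right
            start_left = free_slot(
                gene, size_left, gene.interval.start, gene.interval.end, rng
            )
            if start_left is None:
                continue
            start_right = free_slot(
                gene,
                size_right,
                start_left + size_left + max(spread - 50, margin_pad),
                min(start_left + size_left + spread + 50, gene.interval.end),
                rng,
            )
            if start_right is None:
                continue
            for sense_seq, isl_start, m in (
                (seq_left, start_left, m_left),
                (seq_right, start_right, m_right),
            ):
                dna = sense_seq.replace("U", "T")
                # guard margins are C on the sense strand (C·C cannot pair,
                # so the planted structure cannot be extended into them)
                if gene.strand == "-":
                    block = "G" * m + revcomp_dna(dna) + "G" * m
                else:
                    block = "C" * m + dna + "C" * m
                seq[isl_start : isl_start + len(block)] = list(block)
            isl_left = GenomicInterval(chrom, start_left, start_left + size_left,
                                       gene.strand)
            isl_right = GenomicInterval(chrom, start_right,
                                        start_right + size_right, gene.strand)
            occupied[gene.id] += [
                (start_left, start_left + size_left),
                (start_right, start_right + size_right),
            ]
            if gene.strand == "+":
                arm1 = GenomicInterval(
                    chrom, start_left + m_left, start_left + m_left + len(s1), "+"
                )
                arm2 = GenomicInterval(
                    chrom, start_right + m_right,
                    start_right + m_right + len(s2), "+",
                )
                gpairs = tuple((arm1.start + i, arm2.start + j) for i, j in bp)
                island_up, island_down = isl_left, isl_right
            else:
                arm1 = GenomicInterval(
                    chrom, start_right + m_right,
                    start_right + m_right + len(s1), "-",
                )
                arm2 = GenomicInterval(
                    chrom, start_left + m_left, start_left + m_left + len(s2), "-"
                )
                gpairs = tuple(
                    (arm1.end - 1 - i, arm2.end - 1 - j) for i, j in bp
                )
                island_up, island_down = isl_right, isl_left
            conserved += [isl_left, isl_right]
            truth.append(
                PlantedDuplex(
                    gene_id=gene.id,
                    ccr1=arm1,
                    ccr2=arm2,
                    island1=island_up,
                    island2=island_down,
                    base_pairs=gpairs,
                    dG=round(e, 6),
                    seq1=s1,
                    seq2=s2,
                    sense_pairs=bp,
                )
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place panhandle {idx + 1} (spec infeasible?)"
            )

    # decoy conserved islands: shuffled copies of planted stems
    for gene in genes:
        for _ in range(spec.decoys_per_gene):
            if not truth:
                break
            src = truth[int(rng.integers(len(truth)))]
            letters = list(src.seq1.replace("U", "T"))
            rng.shuffle(letters)
            size = len(letters)
            start = free_slot(gene, size, gene.interval.start, gene.interval.end, rng)
            if start is None:
                continue
            seq[start : start + size] = letters
            occupied[gene.id].append((start, start + size))
            conserved.append(GenomicInterval(chrom, start, start + size, gene.strand))

    chrom_seq = "".join(seq)
    toy = ToyGenome(
        spec=spec,
        genome=Genome({chrom: chrom_seq}),
        genes=genes,
        conserved=sorted(conserved),
        truth=truth,
        chrom_seqs={chrom: chrom_seq},
    )
    if out_dir is not None:
        _write_toy_genome(toy, Path(out_dir))
    return toy


def _write_toy_genome(toy: ToyGenome, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for chrom, s in sorted(toy.chrom_seqs.items()):
            fh.write(f">{chrom}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
    with open(out / "genes.gtf", "w") as fh:
        for gene in toy.genes:
            attrs = f'gene_id "{gene.id}"; gene_biotype "{gene.biotype}";'
            iv = gene.interval
            fh.write(
                f"{iv.chrom}\ttoy\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for exon in gene.exons:
                fh.write(
                    f"{exon.chrom}\ttoy\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\t{attrs}\n"
                )
    with open(out / "conserved.bed", "w") as fh:
        for iv in toy.conserved:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
    with open(out / "ground_truth.tsv", "w") as fh:
        fh.write(
            "gene_id\tccr1_start\tccr1_end\tccr2_start\tccr2_end\tdG\tbase_pairs\n"
        )
        for p in toy.truth:
            bp = ",".join(f"{i}:{j}" for i, j in p.base_pairs)
            fh.write(
                f"{p.gene_id}\t{p.ccr1.start}\t{p.ccr1.end}\t{p.ccr2.start}\t"
                f"{p.ccr2.end}\t{p.dG:.6f}\t{bp}\n"
            )


def make_toy_tracks(
    spec: FixtureSpec, toy: ToyGenome, out_dir: Optional[str] = None
) -> ToyTracks:
    """Feature tracks with planted statistical structure over a toy genome."""
    import pandas as pd

    rng = np.random.default_rng(spec.seed + 1)
    chrom = next(iter(toy.chrom_seqs))
    seq = toy.chrom_seqs[chrom]
    ccr_pos = set()
    paired_pos = set()
    for p in toy.truth:
        ccr_pos.update(range(p.ccr1.start, p.ccr1.end))
        ccr_pos.update(range(p.ccr2.start, p.ccr2.end))
        for g1, g2 in p.base_pairs:
            paired_pos.update((g1, g2))
    cir_pos = set()
    for iv in toy.conserved:
        cir_pos.update(range(iv.start, iv.end))
    bg_pos = sorted(cir_pos - ccr_pos)

    # --- SNVs: depleted inside CCRs, with planted compensatory pairs ---
    rows = []
    for posn in sorted(cir_pos):
        rate = spec.snv_rate * (
            1 - spec.snv_ccr_depletion if posn in ccr_pos else 1.0
        )
        if rng.random() < rate:
            ref = seq[posn]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            af = float(10 ** rng.uniform(-3, -0.5))
            rows.append((chrom, posn, ref, alt, af))
    comp_pairs: List[Tuple[Tuple[int, int], Tuple[str, str]]] = []
    dna_pairs = {"A": "T", "T": "A", "G": "C", "C": "G"}
    chosen = rng.choice(len(toy.truth), size=min(spec.n_compensatory, len(toy.truth)),
                        replace=False)
    for t_idx in chosen:
        p = toy.truth[t_idx]
        g1, g2 = p.base_pairs[len(p.base_pairs) // 2]
        ref1, ref2 = seq[g1], seq[g2]
        # pick an alternative complementary DNA pair
        for alt1 in "ACGT":
            alt2 = dna_pairs[alt1]
            if alt1 != ref1 and alt2 != ref2:
                break
        rows.append((chrom, g1, ref1, alt1, 0.05))
        rows.append((chrom, g2, ref2, alt2, 0.05))
        comp_pairs.append(((g1, g2), (alt1, alt2)))
    snvs = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "af"]
    ).drop_duplicates("pos", keep="last").sort_values("pos").reset_index(drop=True)

    # --- eCLIP-like peaks around CCR arms ---
    peaks: Dict[str, List[GenomicInterval]] = {}
    rbps = [f"RBP{i + 1}" for i in range(4)]
    for rbp in rbps:
        lst = []
        for p in toy.truth:
            for arm_idx, arm in enumerate((p.ccr1, p.ccr2)):
                if spec.peak_mode == "forked":
                    hit = rng.random() < spec.peak_prob if arm_idx == 0 else None
                    if arm_idx == 0:
                        both = hit
                    take = both
                elif spec.peak_mode == "on-ccr":
                    take = rng.random() < spec.peak_prob
                else:  # independent placement at the two arms
                    take = rng.random() < spec.peak_prob
                if take:
                    centre = int(rng.integers(arm.start - 20, arm.end + 20))
                    lst.append(
                        GenomicInterval(
                            chrom, max(centre - 15, 0), centre + 15, arm.strand,
                            name=rbp,
                        )
                    )
        peaks[rbp] = sorted(lst)

    # --- A-to-I editing sites on sense-strand adenosines ---
    editing = []
    gene_by_id = {g.id: g for g in toy.genes}
    for posn in sorted(cir_pos):
        strand = "+"
        for g in toy.genes:
            if g.interval.start <= posn < g.interval.end:
                strand = g.strand
                break
        base = seq[posn]
        is_a = (base == "A" and strand == "+") or (base == "T" and strand == "-")
        if not is_a:
            continue
        rate = spec.editing_rate_ccr if posn in ccr_pos else spec.editing_rate_bg
        if rng.random() < rate:
            editing.append(GenomicInterval(chrom, posn, posn + 1, strand))

    # --- reactivity: depressed at paired nucleotides, scaled by stability ---
    react = rng.uniform(0.3, 0.9, size=len(seq))
    for p in toy.truth:
        depth = spec.reactivity_depression * min(abs(p.dG) / 40.0, 1.0)
        for g1, g2 in p.base_pairs:
            react[g1] *= 1 - depth
            react[g2] *= 1 - depth
    reactivity = {chrom: react}

    # --- junction counts: looped-out exons have lower inclusion ---
    exon_rows = []
    exons: List[GenomicInterval] = []
    looped: List[str] = []
    loop_spans = []
    for p in toy.truth:
        left = min(p.ccr1, p.ccr2, key=lambda c: c.start)
        right = max(p.ccr1, p.ccr2, key=lambda c: c.start)
        loop_spans.append((left.end, right.start))
    for g in toy.genes:
        for e_idx, exon in enumerate(g.exons[1:-1], start=2):
            eid = f"{g.id}_e{e_idx}"
            exons.append(
                GenomicInterval(exon.chrom, exon.start, exon.end, exon.strand,
                                name=eid)
            )
            is_looped = any(
                s <= exon.start and exon.end <= e for s, e in loop_spans
            )
            psi = float(
                np.clip(
                    rng.normal(0.8 + (spec.loopout_delta_psi if is_looped else 0.0),
                               0.08),
                    0.02, 0.98,
                )
            )
            total = int(rng.poisson(spec.mean_junction_reads)) + 12
            inc = int(rng.binomial(total, psi))
            exc = (total - inc) // 2
            exon_rows.append((eid, inc, exc))
            if is_looped:
                looped.append(eid)
    junctions = pd.DataFrame(exon_rows, columns=["exon_id", "inc", "exc"])

    # --- transcript end clusters, enriched in PCCR inner loops ---
    polya, cage = [], []
    for s, e in loop_spans:
        if e - s > 10 and rng.random() < 0.5:
            c = int(rng.integers(s, e - 1))
            polya.append(GenomicInterval(chrom, c, c + 2, "+"))
        if e - s > 10 and rng.random() < 0.5:
            c = int(rng.integers(s, e - 1))
            cage.append(GenomicInterval(chrom, c, c + 2, "+"))

    tracks = ToyTracks(
        snvs=snvs,
        compensatory_pairs=comp_pairs,
        peaks_by_rbp=peaks,
        editing_sites=editing,
        reactivity=reactivity,
        junctions=junctions,
        exons=exons,
        looped_exons=looped,
        polya=sorted(polya),
        cage=sorted(cage),
    )
    if out_dir is not None:
        _write_toy_tracks(tracks, chrom, Path(out_dir))
    return tracks


def _write_toy_tracks(tracks: ToyTracks, chrom: str, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "snvs.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in tracks.snvs.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"AF={row.af:.6f}\n"
            )
    with open(out / "peaks.bed", "w") as fh:
        for rbp, lst in sorted(tracks.peaks_by_rbp.items()):
            for iv in lst:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rbp}\t0\t{iv.strand}\n")
    with open(out / "editing.bed", "w") as fh:
        for iv in tracks.editing_sites:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
    with open(out / "reactivity.bedgraph", "w") as fh:
        for c, arr in tracks.reactivity.items():
            for i, v in enumerate(arr):
                fh.write(f"{c}\t{i}\t{i + 1}\t{v:.4f}\n")
    tracks.junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
    for name, lst in (("polya.bed", tracks.polya), ("cage.bed", tracks.cage)):
        with open(out / name, "w") as fh:
            for iv in lst:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
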