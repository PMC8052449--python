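"""Nearest-neighbor thermodynamics for near-perfect RNA duplexes.

The free energy of an antiparallel duplex is modelled as the sum of
dinucleotide stacking terms within helices plus fixed destabilizing
penalties for the short internal loops and bulges allowed between
helices.  No duplex-initiation or terminal-AU terms are included: the
model scores pure helix extension, which is what the seed-and-extend
dynamic program optimizes.

Admissible base pairs are Watson-Crick (A·U, U·A, G·C, C·G) and wobble
(G·U, U·G).  Stacking parameters are the Turner-2004 RNA dG°37 values
bundled in :mod:`pccr.data` (see the data files for provenance).  DNA
input is transcribed to the RNA alphabet (T -> U) before lookup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

__all__ = [
    "WATSON_CRICK",
    "WOBBLE",
    "ADMISSIBLE",
    "is_admissible",
    "is_wobble",
    "to_rna",
    "revcomp_dna",
    "stack_energy",
    "loop_penalty",
    "KmerEnergyTable",
    "build_kmer_table",
    "duplex_energy",
    "InadmissiblePairError",
]

WATSON_CRICK = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE = frozenset({("G", "U"), ("U", "G")})
ADMISSIBLE = WATSON_CRICK | WOBBLE

#: partners[right] = left-strand nucleotides that may pair with ``right``
PARTNERS: Dict[str, Tuple[str, ...]] = {
    "U": ("A", "G"),
    "A": ("U",),
    "G": ("C", "U"),
    "C": ("G",),
}

_RNA_TRANSLATE = str.maketrans("acgtuTn", "ACGUUUN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InadmissiblePairError(ValueError):
    """Raised when a nucleotide pair is neither Watson-Crick nor wobble."""


def to_rna(seq: str) -> str:
    """Uppercase and transcribe a DNA/RNA string to the RNA alphabet."""
    return seq.upper().translate(_RNA_TRANSLATE)


def revcomp_dna(seq: str) -> str:
    """Reverse complement of a DNA string (uppercased)."""
    return seq.upper().translate(_DNA_COMPLEMENT)[::-1]


def is_admissible(left: str, right: str) -> bool:
    return (left, right) in ADMISSIBLE


def is_wobble(left: str, right: str) -> bool:
    return (left, right) in WOBBLE


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pccr").joinpath("data", name)))


def _load_stacks() -> Dict[Tuple[str, str], float]:
    """Load the stacking table, expanding each step to its mirror image.

    A step ``5'ab3'/3'cd5'`` read from the other strand is ``5'dc3'/3'ba5'``
    and must carry the same free energy; the loader enforces this.
    Keys are ((a, c), (b, d)): the two base pairs in strand-1 order.
    """
    stacks: Dict[Tuple[str, str], float] = {}
    with open(_data_path("turner_stacks.tsv")) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("top"):
                continue
            top, bottom, dg = line.split("\t")
            value = float(dg)
            for t, b in ((top, bottom), (bottom[::-1], top[::-1])):
                key = (t[0] + b[0], t[1] + b[1])
                if key in stacks and abs(stacks[key] - value) > 1e-9:
                    raise ValueError(f"inconsistent stack entry {key}")
                stacks[key] = value
    return stacks


def _load_loops() -> Dict[Tuple[int, int], float]:
    loops: Dict[Tuple[int, int], float] = {}
    with open(_data_path("loop_penalties.tsv")) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("n1"):
                continue
            n1, n2, penalty = line.split("\t")
            value = float(penalty)
            loops[(int(n1), int(n2))] = value
            loops[(int(n2), int(n1))] = value
    return loops


_STACKS = _load_stacks()
_LOOPS = _load_loops()

#: Maximum loop size per strand supported by the bundled penalty table.
MAX_LOOP = max(n for n, _ in _LOOPS)


def stack_energy(pair1: Tuple[str, str], pair2: Tuple[str, str]) -> float:
    """dG°37 of stacking ``pair2`` onto ``pair1``.

    Each pair is (left, right): the strand-1 nucleotide and its strand-2
    partner, strand-1 read 5'->3'.  Raises :class:`InadmissiblePairError`
    if either pair is not admissible.
    """
    for left, right in (pair1, pair2):
        if (left, right) not in ADMISSIBLE:
            raise InadmissiblePairError(f"{left}·{right} cannot base pair")
    return _STACKS[(pair1[0] + pair1[1], pair2[0] + pair2[1])]


def loop_penalty(n1: int, n2: int, m: int = 2) -> float:
    """Penalty for an internal loop/bulge of n1 x n2 unpaired nucleotides.

    Defined for 0 <= n1, n2 <= m with (n1, n2) != (0, 0); symmetric.
    """
    if (n1, n2) == (0, 0):
        raise ValueError("(0,0) is not a loop")
    if not (0 <= n1 <= m and 0 <= n2 <= m):
        raise ValueError(f"loop size ({n1},{n2}) exceeds m={m}")
    if m > MAX_LOOP:
        raise ValueError(f"bundled table only covers loops up to {MAX_LOOP}")
    return _LOOPS[(n1, n2)]


def _count_wobbles(kmer1: str, kmer2: str) -> int:
    return sum(1 for a, b in zip(kmer1, kmer2) if (a, b) in WOBBLE)


def _helix_energy(kmer1: str, kmer2: str) -> float:
    """Sum of the len-1 stacking steps of a perfect (gap-free) helix."""
    total = 0.0
    for t in range(len(kmer1) - 1):
        total += stack_energy((kmer1[t], kmer2[t]), (kmer1[t + 1], kmer2[t + 1]))
    return total


@dataclass(frozen=True)
class KmerEnergyTable:
    """Hybridization energies of all admissible k-mer pairs.

    ``entries`` maps (kmer1, kmer2) -> dG where ``kmer2`` is written in
    duplex orientation: position t of kmer2 pairs position t of kmer1
    (i.e. kmer2 is the strand-2 window read 3'->5').  Every entry has k
    consecutive admissible pairs with at most ``max_gu`` wobbles, and its
    energy is the sum of the k-1 stacking terms.
    """

    k: int
    max_gu: int
    entries: Dict[Tuple[str, str], float] = field(repr=False)

    def __contains__(self, key: Tuple[str, str]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def energy(self, kmer1: str, kmer2: str) -> float:
        return self.entries[(kmer1, kmer2)]

    def get(self, kmer1: str, kmer2: str):
        return self.entries.get((kmer1, kmer2))

    def partners(self, kmer2: str) -> List[str]:
        """All strand-1 k-mers admissible against a strand-2 window."""
        out: List[str] = [""]
        budgets = [0]
        for b in kmer2:
            if b not in PARTNERS:
                return []
            nxt, nxt_budget = [], []
            for prefix, used in zip(out, budgets):
                for a in PARTNERS[b]:
                    w = used + ((a, b) in WOBBLE)
                    if w <= self.max_gu:
                        nxt.append(prefix + a)
                        nxt_budget.append(w)
            out, budgets = nxt, nxt_budget
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# k={self.k} max_gu={self.max_gu}\n")
            for (k1, k2), dg in sorted(self.entries.items()):
                fh.write(f"{k1}\t{k2}\t{dg:.6f}\n")

    @classmethod
    def from_tsv(cls, path) -> "KmerEnergyTable":
        entries: Dict[Tuple[str, str], float] = {}
        k = max_gu = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    parts = dict(p.split("=") for p in line[1:].split())
                    k, max_gu = int(parts["k"]), int(parts["max_gu"])
                    continue
                k1, k2, dg = line.rstrip("\n").split("\t")
                entries[(k1, k2)] = float(dg)
        if k is None:
            raise ValueError(f"{path}: missing header line")
        return cls(k=k, max_gu=max_gu, entries=entries)


def build_kmer_table(k: int, max_gu: int) -> KmerEnergyTable:
    """Precompute hybridization energies for all admissible k-mer pairs."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if max_gu < 0:
        raise ValueError("max_gu must be >= 0")
    entries: Dict[Tuple[str, str], float] = {}
    for kmer1 in map("".join, itertools.product("ACGU", repeat=k)):
        # enumerate strand-2 windows admissible against kmer1
        stack: List[Tuple[str, int]] = [("", 0)]
        for a in kmer1:
            nxt = []
            for partial, used in stack:
                for b in "ACGU":
                    if (a, b) in ADMISSIBLE:
                        w = used + ((a, b) in WOBBLE)
                        if w <= max_gu:
                            nxt.append((partial + b, w))
            stack = nxt
        for kmer2, _ in stack:
            entries[(kmer1, kmer2)] = round(_helix_energy(kmer1, kmer2), 10)
    return KmerEnergyTable(k=k, max_gu=max_gu, entries=entries)


def duplex_energy(
    base_pairs: Sequence[Tuple[int, int]],
    seq1: str,
    seq2: str,
    *,
    k: int | None = None,
    m: int = 2,
    table: KmerEnergyTable | None = None,
) -> float:
    """Free energy of a duplex structure by direct summation.

    ``base_pairs`` is the ordered list of (i, j): position i of ``seq1``
    (5'->3') paired with position j of ``seq2`` (5'->3'); i must be
    strictly increasing and j strictly decreasing (antiparallel duplex).
    Energy is the sum of stacking terms over consecutive pairs within
    helices plus one loop penalty per inter-helix gap.  If ``k`` (and
    optionally ``table``) is given, the helix grammar is validated: every
    helix at least k pairs, every k-window of a helix a table entry.
    """
    if not base_pairs:
        raise ValueError("empty structure")
    s1, s2 = to_rna(seq1), to_rna(seq2)
    for i, j in base_pairs:
        if not (0 <= i < len(s1) and 0 <= j < len(s2)):
            raise ValueError(f"pair ({i},{j}) outside sequences")
        if (s1[i], s2[j]) not in ADMISSIBLE:
            raise InadmissiblePairError(f"({i},{j}) {s1[i]}·{s2[j]} cannot pair")
    helices: List[List[Tuple[int, int]]] = [[tuple(base_pairs[0])]]
    for (pi, pj), (i, j) in zip(base_pairs, base_pairs[1:]):
        if i <= pi or j >= pj:
            raise ValueError("base pairs must be i-increasing, j-decreasing")
        if i == pi + 1 and j == pj - 1:
            helices[-1].append((i, j))
        else:
            a, b = i - pi - 1, pj - j - 1
            if (a, b) == (0, 0) or a > m or b > m:
                raise ValueError(f"gap ({a},{b}) violates loop bounds (m={m})")
            helices.append([(i, j)])
    total = 0.0
    for helix in helices:
        if k is not None and len(helix) < k:
            raise ValueError(f"helix of {len(helix)} pairs shorter than k={k}")
        for (pi, pj), (i, j) in zip(helix, helix[1:]):
            total += stack_energy((s1[pi], s2[pj]), (s1[i], s2[j]))
        if table is not None and k is not None:
            for t in range(len(helix) - k + 1):
                w1 = "".join(s1[i] for i, _ in helix[t : t + k])
                w2 = "".join(s2[j] for _, j in helix[t : t + k])
                if (w1, w2) not in table:
                    raise ValueError(f"helix window ({w1},{w2}) not in table")
    prev_end = helices[0][-1]
    for helix in helices[1:]:
        i, j = helix[0]
        total += loop_penalty(i - prev_end[0] - 1, prev_end[1] - j - 1, m=m)
        prev_end = helix[-1]
    return total
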