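"""Seed-and-extend dynamic program for near-perfect complementary region pairs.

The search finds, for two input sequences, all local antiparallel duplexes
made of helices of at least k consecutive base pairs (every k-window of a
helix must be an entry of the precomputed k-mer energy table, which caps
the number of wobble pairs per window) separated by internal loops or
bulges of at most m nucleotides per strand.  A cell of the dynamic
program is the k-mer window in which the last helix of a structure ends;
transitions are a one-pair stacking extension or a loop jump followed by
a fresh k-mer seed.  Hits passing the energy threshold are reported with
a traceback whose direct-summation energy equals the cell energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .energies import (
    ADMISSIBLE,
    KmerEnergyTable,
    duplex_energy,
    loop_penalty,
    stack_energy,
    to_rna,
)

__all__ = [
    "SearchParams",
    "DuplexStructure",
    "DuplexHit",
    "find_duplexes",
    "brute_force_duplexes",
    "select_nonintersecting",
]


@dataclass(frozen=True)
class SearchParams:
    """Search parameters: seed length k, loop cap m, wobble cap, thresholds."""

    k: int = 5
    m: int = 2
    max_gu: int = 2
    energy_threshold: float = -15.0
    min_len: int = 10

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.min_len < self.k:
            raise ValueError("min_len must be >= k")
        if self.energy_threshold >= 0:
            raise ValueError("energy_threshold must be negative")


@dataclass(frozen=True)
class DuplexStructure:
    """Ordered base pairs (i into seq1, j into seq2), i up / j down."""

    base_pairs: Tuple[Tuple[int, int], ...]

    @property
    def helices(self) -> List[List[Tuple[int, int]]]:
        out: List[List[Tuple[int, int]]] = [[self.base_pairs[0]]]
        for (pi, pj), (i, j) in zip(self.base_pairs, self.base_pairs[1:]):
            if i == pi + 1 and j == pj - 1:
                out[-1].append((i, j))
            else:
                out.append([(i, j)])
        return out

    @property
    def loops(self) -> List[Tuple[int, int]]:
        gaps = []
        for (pi, pj), (i, j) in zip(self.base_pairs, self.base_pairs[1:]):
            if not (i == pi + 1 and j == pj - 1):
                gaps.append((i - pi - 1, pj - j - 1))
        return gaps


@dataclass(frozen=True)
class DuplexHit:
    """One complementary region pair: intervals, structure, and energy."""

    region1: Tuple[int, int]  # [start, end) on seq1
    region2: Tuple[int, int]  # [start, end) on seq2
    structure: DuplexStructure
    dG: float

    @property
    def length1(self) -> int:
        return self.region1[1] - self.region1[0]

    @property
    def length2(self) -> int:
        return self.region2[1] - self.region2[0]


def _seed_cells(
    s1: str, r2: str, table: KmerEnergyTable
) -> Dict[Tuple[int, int], float]:
    """All admissible k-window cells (i, u) with their table energies.

    ``r2`` is strand 2 reversed, so windows align position-wise.
    """
    k = table.k
    index: Dict[str, List[int]] = {}
    for i in range(len(s1) - k + 1):
        kmer = s1[i : i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    cells: Dict[Tuple[int, int], float] = {}
    partner_cache: Dict[str, List[str]] = {}
    for u in range(len(r2) - k + 1):
        window = r2[u : u + k]
        if "N" in window:
            continue
        partners = partner_cache.get(window)
        if partners is None:
            partners = table.partners(window)
            partner_cache[window] = partners
        for kmer1 in partners:
            for i in index.get(kmer1, ()):
                cells[(i, u)] = table.entries[(kmer1, window)]
    return cells


def find_duplexes(
    seq1: str,
    seq2: str,
    table: KmerEnergyTable,
    params: SearchParams = SearchParams(),
) -> List[DuplexHit]:
    """All locally optimal duplex hits between two sequences.

    Returns hits whose dG passes ``params.energy_threshold`` and whose
    shorter region spans at least ``params.min_len`` nucleotides; for each
    end cell the reported dG is the minimum over all structures ending
    there.  Hits may intersect; see :func:`select_nonintersecting`.
    """
    if table.k != params.k or table.max_gu != params.max_gu:
        raise ValueError("table was built with different (k, max_gu)")
    k, m = params.k, params.m
    s1, s2 = to_rna(seq1), to_rna(seq2)
    if len(s1) < k or len(s2) < k:
        return []
    r2 = s2[::-1]
    seeds = _seed_cells(s1, r2, table)
    if not seeds:
        return []
    energy: Dict[Tuple[int, int], float] = {}
    # parent[cell] = (previous cell, kind) with kind "stack" or (a, b) loop
    parent: Dict[Tuple[int, int], Optional[Tuple[Tuple[int, int], object]]] = {}
    for i, u in sorted(seeds):
        seed_e = seeds[(i, u)]
        best, origin = seed_e, None
        prev = (i - 1, u - 1)
        if prev in energy:
            step = stack_energy(
                (s1[i + k - 2], r2[u + k - 2]), (s1[i + k - 1], r2[u + k - 1])
            )
            cand = energy[prev] + step
            if cand < best - 1e-12:
                best, origin = cand, (prev, "stack")
        for a in range(m + 1):
            for b in range(m + 1):
                if (a, b) == (0, 0):
                    continue
                prev = (i - k - a, u - k - b)
                if prev in energy:
                    cand = energy[prev] + loop_penalty(a, b, m=m) + seed_e
                    if cand < best - 1e-12:
                        best, origin = cand, (prev, (a, b))
        energy[(i, u)] = best
        parent[(i, u)] = origin

    hits: List[DuplexHit] = []
    for (i, u), e in energy.items():
        if e > params.energy_threshold:
            continue
        succ = (i + 1, u + 1)
        if succ in energy and energy[succ] <= e:
            continue  # interior to an equal-or-better continuation
        pairs = _traceback(i, u, parent, k)
        start_i = pairs[0][0]
        start_u = pairs[0][1]
        len1 = i + k - start_i
        len2 = u + k - start_u
        if min(len1, len2) < params.min_len:
            continue
        # map r2 positions back to original seq2 coordinates
        bp = tuple((pi, len(s2) - 1 - pu) for pi, pu in pairs)
        region1 = (start_i, i + k)
        region2 = (len(s2) - (u + k), len(s2) - start_u)
        hit = DuplexHit(
            region1=region1, region2=region2, structure=DuplexStructure(bp), dG=e
        )
        assert abs(duplex_energy(bp, s1, s2, k=k, m=m) - e) < 1e-6
        hits.append(hit)
    hits.sort(key=_hit_order)
    return hits


def _traceback(i, u, parent, k) -> List[Tuple[int, int]]:
    """Reconstruct base pairs (in r2 coordinates) ending at window (i, u)."""
    segments: List[Tuple[int, int, int]] = []  # (start_i, start_u, n_pairs)
    cell = (i, u)
    length = k
    while True:
        origin = parent[cell]
        if origin is None:
            segments.append((cell[0], cell[1], length))
            break
        prev, kind = origin
        if kind == "stack":
            length += 1
            cell = prev
        else:
            segments.append((cell[0], cell[1], length))
            length = k
            cell = prev
    pairs: List[Tuple[int, int]] = []
    for si, su, n in reversed(segments):
        for t in range(n):
            pairs.append((si + t, su + t))
    return pairs


def _hit_order(hit: DuplexHit):
    return (
        hit.dG,
        -(hit.length1 + hit.length2),
        hit.region1[0],
        hit.region2[0],
    )


def select_nonintersecting(hits: Sequence[DuplexHit]) -> List[DuplexHit]:
    """Greedy selection of pairwise non-intersecting hits.

    Two hits intersect only if their region-1 intervals share nucleotides
    AND their region-2 intervals share nucleotides; sharing one strand
    only is allowed.  Most stable (lowest dG) first; ties broken by
    longer total length, then leftmost region 1.  Duplicates collapse.
    """
    kept: List[DuplexHit] = []
    seen = set()
    for hit in sorted(hits, key=_hit_order):
        key = hit.structure.base_pairs
        if key in seen:
            continue
        if any(
            _overlaps(hit.region1, other.region1)
            and _overlaps(hit.region2, other.region2)
            for other in kept
        ):
            continue
        seen.add(key)
        kept.append(hit)
    return kept


def _overlaps(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def enumerate_structures(
    seq1: str,
    seq2: str,
    table: KmerEnergyTable,
    params: SearchParams = SearchParams(),
    max_cells: int = 400,
):
    """Yield every valid structure under the grammar, for tiny inputs.

    Yields (end_window_cell, base_pairs_in_seq2_coords, energy) where the
    energy comes from direct summation (:func:`duplex_energy`), fully
    independent of the dynamic program's recurrences.
    """
    s1, s2 = to_rna(seq1), to_rna(seq2)
    if len(s1) * len(s2) > max_cells:
        raise ValueError(f"input larger than {max_cells} cells; oracle refused")
    if len(s1) < params.k or len(s2) < params.k:
        return
    k, m = params.k, params.m
    r2 = s2[::-1]
    seeds = _seed_cells(s1, r2, table)

    def walk(pairs: List[Tuple[int, int]]):
        end = (pairs[-1][0] - k + 1, pairs[-1][1] - k + 1)
        bp = tuple((pi, len(s2) - 1 - pu) for pi, pu in pairs)
        e = duplex_energy(bp, s1, s2, k=k, m=m)
        yield end, bp, e
        li, lu = pairs[-1]
        # stacking extension: next pair must close another admissible window
        if (li - k + 2, lu - k + 2) in seeds:
            yield from walk(pairs + [(li + 1, lu + 1)])
        # loop jump followed by a fresh seed
        for a in range(m + 1):
            for b in range(m + 1):
                if (a, b) == (0, 0):
                    continue
                ni, nu = li + 1 + a, lu + 1 + b
                if (ni, nu) in seeds:
                    yield from walk(pairs + [(ni + t, nu + t) for t in range(k)])

    for (i, u) in sorted(seeds):
        yield from walk([(i + t, u + t) for t in range(k)])


def brute_force_duplexes(
    seq1: str,
    seq2: str,
    table: KmerEnergyTable,
    params: SearchParams = SearchParams(),
    max_cells: int = 400,
) -> List[DuplexHit]:
    """Exhaustive enumeration oracle over the same structural grammar.

    Enumerates every valid structure (helices of >= k pairs whose
    k-windows are table entries, separated by loops bounded by m) via
    :func:`enumerate_structures` and keeps the optimum per end window.
    Only for tiny inputs.
    """
    s1, s2 = to_rna(seq1), to_rna(seq2)
    best: Dict[Tuple[int, int], Tuple[float, Tuple[Tuple[int, int], ...]]] = {}
    for end, bp_genomic, e in enumerate_structures(
        seq1, seq2, table, params, max_cells
    ):
        cur = best.get(end)
        if cur is None or e < cur[0] - 1e-12:
            best[end] = (e, bp_genomic)

    hits: List[DuplexHit] = []
    for (i, u), (e, bp) in best.items():
        if e > params.energy_threshold:
            continue
        succ = (i + 1, u + 1)
        if succ in best and best[succ][0] <= e:
            continue
        region1 = (bp[0][0], bp[-1][0] + 1)
        region2 = (bp[-1][1], bp[0][1] + 1)
        if min(region1[1] - region1[0], region2[1] - region2[0]) < params.min_len:
            continue
        hits.append(
            DuplexHit(
                region1=region1,
                region2=region2,
                structure=DuplexStructure(bp),
                dG=e,
            )
        )
    hits.sort(key=_hit_order)
    return hits
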