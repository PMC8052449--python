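"""Genome sequence and per-nucleotide score track accessors."""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np

from .energies import revcomp_dna
from .intervals import GenomicInterval

__all__ = ["Genome", "ScoreTrack"]


class Genome:
    """Random-access genome: a FASTA file (via pyfaidx) or an in-memory dict."""

    def __init__(self, source):
        if isinstance(source, Mapping):
            self._seqs: Optional[Dict[str, str]] = {
                c: str(s).upper() for c, s in source.items()
            }
            self._fasta = None
        else:
            import pyfaidx

            self._seqs = None
            self._fasta = pyfaidx.Fasta(str(source))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()

    def sense(self, interval: GenomicInterval) -> str:
        """Sense-strand (transcribed) DNA sequence of a stranded interval."""
        seq = self.fetch(interval.chrom, interval.start, interval.end)
        return revcomp_dna(seq) if interval.strand == "-" else seq

    def length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])


class ScoreTrack:
    """Dense per-nucleotide scores per chromosome; uncovered positions are 0."""

    def __init__(self, arrays: Dict[str, np.ndarray]):
        self.arrays = {c: np.asarray(a, dtype=float) for c, a in arrays.items()}

    @classmethod
    def from_bedgraph(cls, path) -> "ScoreTrack":
        spans: Dict[str, list] = {}
        with open(str(path)) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, value = line.split()[:4]
                spans.setdefault(chrom, []).append(
                    (int(start), int(end), float(value))
                )
        arrays = {}
        for chrom, rows in spans.items():
            size = max(e for _, e, _ in rows)
            arr = np.zeros(size)
            for s, e, v in rows:
                arr[s:e] = v
            arrays[chrom] = arr
        return cls(arrays)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores over [start, end); positions outside coverage are 0."""
        out = np.zeros(max(end - start, 0))
        arr = self.arrays.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if lo < hi:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def mean(self, chrom: str, start: int, end: int) -> float:
        vals = self.values(chrom, start, end)
        return float(vals.mean()) if len(vals) else 0.0
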