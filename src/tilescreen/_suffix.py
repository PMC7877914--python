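"""Suffix-array construction and matching statistics for MUM finding.

The reference (all chromosomes, forward plus reverse complement, joined
by sentinel bytes) is indexed once with a prefix-doubling suffix array.
For each query offset, an incremental binary search narrows the suffix
interval one character at a time, yielding the longest-match length, the
occurrence count at that length, one match position, and the shortest
prefix length at which the match becomes unique. The inner search is
JIT-compiled with numba when available; a pure-Python implementation of
the same code path is used otherwise.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 1, "C": 2, "G": 3, "T": 4}


def encode(seq: str) -> np.ndarray:
    """ACGT -> 1..4, anything else -> 0 (sentinel, never matches)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.zeros(arr.shape, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def suffix_array(text: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array of a small-alphabet byte array."""
    n = int(text.size)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = text.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[:n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_sorted = rank[order]
        k_sorted = key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        if n > 1:
            changed[1:] = np.cumsum(
                (r_sorted[1:] != r_sorted[:-1])
                | (k_sorted[1:] != k_sorted[:-1]))
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = changed
        rank = new_rank
        if changed[-1] == n - 1:
            break
        k *= 2
    return order.astype(np.int64)


def _matching_stats_py(text, sa, query, match_len, occ, pos, min_unique):
    """Matching statistics for every query offset (reference algorithm).

    For offset i: the longest prefix of query[i:] occurring in text, its
    occurrence count, the text position of the first occurrence in suffix
    order, and the shortest prefix length at which the occurrence count
    first reaches 1 (0 if never unique).
    """
    n = sa.shape[0]
    q = query.shape[0]
    tlen = text.shape[0]
    for i in range(q):
        lo, hi = 0, n
        length = 0
        mul = 0
        while i + length < q:
            c = query[i + length]
            if c == 0:
                break
            # narrow [lo, hi) to suffixes whose character at depth
            # `length` equals c (that column is sorted within the block)
            a, b = lo, hi
            while a < b:           # lower bound
                mid = (a + b) // 2
                p = sa[mid] + length
                tc = text[p] if p < tlen else 0
                if tc < c:
                    a = mid + 1
                else:
                    b = mid
            nlo = a
            a, b = nlo, hi
            while a < b:           # upper bound
                mid = (a + b) // 2
                p = sa[mid] + length
                tc = text[p] if p < tlen else 0
                if tc <= c:
                    a = mid + 1
                else:
                    b = mid
            nhi = a
            if nlo >= nhi:
                break
            lo, hi = nlo, nhi
            length += 1
            if mul == 0 and hi - lo == 1:
                mul = length
        match_len[i] = length
        occ[i] = (hi - lo) if length > 0 else 0
        pos[i] = sa[lo] if length > 0 else -1
        min_unique[i] = mul


try:                                        # pragma: no cover
    from numba import njit
    _matching_stats = njit(cache=False)(_matching_stats_py)
except Exception:                           # pragma: no cover
    _matching_stats = _matching_stats_py


class ReferenceIndex:
    """Suffix-array index over forward + reverse-complement reference."""

    def __init__(self, genome: dict[str, str]):
        from .genemodel import revcomp
        parts: list[np.ndarray] = []
        self.blocks: list[tuple[str, str, int, int]] = []  # chrom,strand,s,e
        offset = 0
        for chrom, seq in genome.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                enc = encode(s)
                parts.append(enc)
                parts.append(np.zeros(1, dtype=np.uint8))
                self.blocks.append((chrom, strand, offset, offset + enc.size))
                offset += enc.size + 1
        self.chrom_lengths = {c: len(s) for c, s in genome.items()}
        self.text = np.concatenate(parts) if parts else np.zeros(
            0, dtype=np.uint8)
        self.sa = suffix_array(self.text)
        self._block_starts = np.array([b[2] for b in self.blocks])
        self._block_ends = np.array([b[3] for b in self.blocks])
        # warm up the jitted kernel on a tiny input
        _matching_stats(self.text, self.sa, encode("A"),
                        np.zeros(1, np.int64), np.zeros(1, np.int64),
                        np.zeros(1, np.int64), np.zeros(1, np.int64))

    def locate(self, pos: int, length: int) -> tuple[str, str, int]:
        """Map a text position to (chrom, strand, forward-strand start)."""
        i = int(np.searchsorted(self._block_ends, pos, side="right"))
        chrom, strand, s, _e = self.blocks[i]
        rel = pos - s
        if strand == "+":
            return chrom, "+", rel
        return chrom, "-", self.chrom_lengths[chrom] - rel - length

    def matching_statistics(self, query: str):
        """Longest match, occurrence count, position and min-unique length
        for every offset of ``query`` against the doubled reference."""
        q = encode(query)
        m = q.size
        match_len = np.zeros(m, dtype=np.int64)
        occ = np.zeros(m, dtype=np.int64)
        pos = np.zeros(m, dtype=np.int64)
        mul = np.zeros(m, dtype=np.int64)
        if m and self.sa.size:
            _matching_stats(self.text, self.sa, q,
                            match_len, occ, pos, mul)
        return match_len, occ, pos, mul
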