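"""Pairwise contig overlap detection by k-mer anchoring.

Full dynamic programming over two 100-kb contigs is needlessly quadratic; the
screen only needs to decide whether a large, high-identity overlap exists.
Shared 21-mers (encoded exactly in 42 bits, so hashing is collision-free) are
located with vectorised numpy set operations, grouped into diagonal bands,
and the bounding region of each band is aligned with edlib (bit-vector edit
distance) to obtain identity and span.
"""

from __future__ import annotations

import edlib
import numpy as np

from .containers import seq_to_array

DEFAULT_K = 21
# anchors whose diagonals differ by at most this much belong to one band
DIAG_TOLERANCE = 100
# skip bands shorter than this on the query (noise)
MIN_BAND_SPAN = 200
# cap on anchor pairs examined per band grouping, guards repeats
MAX_ANCHORS = 200_000

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


def _kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Exact 2-bit packed k-mer codes (uint64) at every position.

    Positions containing a non-ACGT base hash to a sentinel that never
    matches a clean k-mer.
    """
    codes = _CODE[seq_to_array(seq)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    codes64 = np.where(valid, codes, 0).astype(np.uint64)
    powers = (np.uint64(4) ** np.arange(k, dtype=np.uint64))
    windows = np.lib.stride_tricks.sliding_window_view(codes64, k)
    hashes = windows @ powers
    # windows touching an ambiguous base get an out-of-range sentinel
    bad = ~np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    hashes[bad] = np.uint64(1) << np.uint64(63)
    return hashes


def _shared_anchors(query: str, target: str, k: int) -> np.ndarray:
    """(diagonal, query position) pairs of all shared k-mers, or empty."""
    hq = _kmer_hashes(query, k)
    ht = _kmer_hashes(target, k)
    if len(hq) == 0 or len(ht) == 0:
        return np.empty((0, 2), dtype=np.int64)
    order = np.argsort(ht, kind="stable")
    ht_sorted = ht[order]
    left = np.searchsorted(ht_sorted, hq, side="left")
    right = np.searchsorted(ht_sorted, hq, side="right")
    counts = right - left
    hit_q = np.flatnonzero(counts)
    total = int(counts[hit_q].sum())
    if total == 0 or total > MAX_ANCHORS:
        # no anchors, or pathologically repetitive input: fall back to the
        # densest positions only
        if total == 0:
            return np.empty((0, 2), dtype=np.int64)
        hit_q = hit_q[np.argsort(counts[hit_q])[::-1]]
        keep = []
        run = 0
        for i in hit_q:
            run += int(counts[i])
            keep.append(i)
            if run > MAX_ANCHORS:
                break
        hit_q = np.array(sorted(keep))
    out = np.empty((int(counts[hit_q].sum()), 2), dtype=np.int64)
    pos = 0
    for i in hit_q:
        tpos = order[left[i] : right[i]]
        m = len(tpos)
        out[pos : pos + m, 0] = tpos - i  # diagonal
        out[pos : pos + m, 1] = i
        pos += m
    return out[:pos]


def find_best_overlap(
    query: str,
    target: str,
    k: int = DEFAULT_K,
    diag_tolerance: int = DIAG_TOLERANCE,
) -> tuple[float, float] | None:
    """Best high-identity overlap of ``query`` (the shorter contig) in ``target``.

    Returns ``(identity, span_fraction)`` for the strongest anchored band,
    where span_fraction is relative to the query length, or None when no
    usable anchor band exists. Identity comes from an edlib alignment of the
    band's bounding substrings (query substring located freely in the target
    substring).
    """
    if len(query) < k or len(target) < k:
        return None
    anchors = _shared_anchors(query, target, k)
    if len(anchors) == 0:
        return None
    anchors = anchors[np.lexsort((anchors[:, 1], anchors[:, 0]))]
    diags = anchors[:, 0]
    breaks = np.flatnonzero(np.diff(diags) > diag_tolerance) + 1
    best: tuple[float, float] | None = None
    for band in np.split(anchors, breaks):
        qs = int(band[:, 1].min())
        qe = int(band[:, 1].max()) + k
        if qe - qs < MIN_BAND_SPAN:
            continue
        ts = max(0, qs + int(band[:, 0].min()))
        te = min(len(target), qe + int(band[:, 0].max()))
        sub_q = query[qs:qe]
        sub_t = target[ts:te]
        res = edlib.align(sub_q, sub_t, mode="HW", task="distance")
        if res["editDistance"] < 0:
            continue
        identity = 1.0 - res["editDistance"] / len(sub_q)
        span = (qe - qs) / len(query)
        if best is None or identity * span > best[0] * best[1]:
            best = (identity, span)
    return best
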