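"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities through routes the
package does not use (per-base bitmaps, quadratic dynamic programming,
exhaustive re-evaluation) so agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from dotfinder import AlignmentHit


# ---------------------------------------------------------------------------
# Alignment oracles
# ---------------------------------------------------------------------------


def nw_global_identity(a: str, b: str, match: int = 1, mismatch: int = -1,
                       gap: int = -2) -> float:
    """Needleman-Wunsch with traceback; identity = matched columns / columns."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            u = score[i - 1, j] + gap
            l = score[i, j - 1] + gap
            best = max(d, u, l)
            score[i, j] = best
            ptr[i, j] = 0 if best == d else (1 if best == u else 2)
    i, j = n, m
    matches = columns = 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        columns += 1
        if p == 0:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    return matches / columns


def max_matches_dp(a: str, b: str) -> int:
    """Maximum matching residues over all global alignments (= weighted LCS),
    computed with a row-vectorised DP independent of any alignment library."""
    if not a or not b:
        return 0
    bn = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int64)
    for ch in a.encode():
        eq = (bn == ch).astype(np.int64)
        cur = np.empty_like(prev)
        cur[0] = 0
        cur[1:] = np.maximum(prev[1:], prev[:-1] + eq)
        np.maximum.accumulate(cur, out=cur)
        prev = cur
    return int(prev[-1])


def shorter_identity(a: str, b: str) -> float:
    """CD-HIT-convention identity from the independent DP."""
    return max_matches_dp(a, b) / min(len(a), len(b))


# ---------------------------------------------------------------------------
# Interval bitmap oracle
# ---------------------------------------------------------------------------


def bitmap_covered(intervals, length: int) -> int:
    """Per-base covered count on a bitmap — the naive coverage oracle."""
    bm = np.zeros(length, dtype=bool)
    for s, e in intervals:
        bm[max(s, 0):min(e, length)] = True
    return int(bm.sum())


# ---------------------------------------------------------------------------
# Random hit generator
# ---------------------------------------------------------------------------


def random_hits(rng: np.random.Generator, n: int, n_queries: int = 20,
                n_targets: int = 5) -> list[AlignmentHit]:
    hits = []
    for _ in range(n):
        qlen = int(rng.integers(50, 300))
        qs = int(rng.integers(0, qlen - 10))
        qe = int(rng.integers(qs + 1, qlen + 1))
        tlen = int(rng.integers(10_000, 100_000))
        span = 3 * (qe - qs)
        ts = int(rng.integers(0, tlen - span))
        aln_len = qe - qs
        matches = int(rng.integers(1, aln_len + 1))
        hits.append(AlignmentHit(
            query_id=f"p{rng.integers(0, n_queries)}", query_len=qlen,
            query_start=qs, query_end=qe,
            target_id=f"s{rng.integers(0, n_targets)}", target_len=tlen,
            target_start=ts, target_end=ts + span,
            strand="+" if rng.random() < 0.5 else "-",
            matches=matches, aln_len=aln_len,
            score=int(rng.integers(0, 500)), identity=matches / aln_len,
        ))
    return hits


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
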