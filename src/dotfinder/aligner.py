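"""Protein-to-genome mapping: built-in translated search plus adapters.

The built-in searcher six-frame translates the assembly, finds exact
amino-acid seed-word matches against the query proteins and extends them
ungapped in both directions under an x-drop rule. It is intentionally
intron-unaware: it exists so the pipeline is self-contained on intron-free
fixtures. Real genomes should be mapped with an external spliced aligner
(e.g. miniprot) and ingested through :func:`import_external_hits`; the
pipeline's own computation (top-hit selection, identity filtering,
counting, sorting) is aligner-agnostic.

All heavy lifting is vectorised: frames are encoded as uint8 code arrays,
seed matches are found with a rolling base-23 k-mer hash against a bitmask
plus CSR lookup, and extensions run in windowed numpy batches with scalar
escalation for the rare extensions that outgrow the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .io_formats import AlignmentHit, Assembly, SequenceRecord, parse_paf, read_hits_gff3

logger = logging.getLogger(__name__)

# --- encoding ---------------------------------------------------------------

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODE = 20          # '*'
X_CODE = 21             # genome unknown residue (from N-containing codons)
SENT_CODE = 22          # inter-frame sentinel in the concatenated target
HASH_BASE = 23          # codes 0..22 are hashable
PROT_OTHER = 24         # non-standard residue in a query protein
PROT_PAD = 25           # query matrix padding
AA_DECODE = AA_ORDER + "*X"

_NT_LUT = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _NT_LUT[ord(base)] = i
    _NT_LUT[ord(base.lower())] = i

_AA_LUT = np.full(256, PROT_OTHER, dtype=np.uint8)
for i, aa in enumerate(AA_ORDER):
    _AA_LUT[ord(aa)] = i
    _AA_LUT[ord(aa.lower())] = i
_AA_LUT[ord("*")] = STOP_CODE


def _codon_lut() -> np.ndarray:
    """Map base-5 codon index (A0 C1 G2 T3 N4) -> amino-acid code.

    N-containing codons whose resolutions all agree translate to that
    residue (e.g. GTN -> V); otherwise to X, matching standard ambiguous
    translation.
    """
    table = CodonTable.unambiguous_dna_by_id[1]
    lut = np.full(125, X_CODE, dtype=np.uint8)
    order = "ACGTN"
    for i0, b0 in enumerate(order):
        for i1, b1 in enumerate(order):
            for i2, b2 in enumerate(order):
                idx = i0 * 25 + i1 * 5 + i2
                resolved = {
                    ("*" if c in table.stop_codons else table.forward_table[c])
                    for c in (x0 + x1 + x2
                              for x0 in (order[:4] if b0 == "N" else b0)
                              for x1 in (order[:4] if b1 == "N" else b1)
                              for x2 in (order[:4] if b2 == "N" else b2))
                }
                if len(resolved) == 1:
                    aa = resolved.pop()
                    lut[idx] = STOP_CODE if aa == "*" else AA_ORDER.index(aa)
    return lut


_CODON_LUT = _codon_lut()


def _encode_dna(seq: str) -> np.ndarray:
    return _NT_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _encode_protein(seq: str) -> np.ndarray:
    return _AA_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(enc: np.ndarray) -> np.ndarray:
    rc = np.where(enc == 4, np.uint8(4), (3 - enc).astype(np.uint8))
    return rc[::-1]


def _translate_codes(enc: np.ndarray, offset: int) -> np.ndarray:
    n = (len(enc) - offset) // 3
    if n <= 0:
        return np.empty(0, dtype=np.uint8)
    c0 = enc[offset:offset + 3 * n:3].astype(np.int32)
    c1 = enc[offset + 1:offset + 1 + 3 * n:3].astype(np.int32)
    c2 = enc[offset + 2:offset + 2 + 3 * n:3].astype(np.int32)
    return _CODON_LUT[c0 * 25 + c1 * 5 + c2]


# --- six-frame translation (public) -----------------------------------------


@dataclass(frozen=True)
class TranslatedFrame:
    """One reading frame of a DNA sequence.

    ``strand`` is '+' or '-', ``offset`` 0..2. ``codon_interval(p)`` maps an
    amino-acid position back to its exact genomic bp interval (half-open).
    """

    strand: str
    offset: int
    aa: str
    source_length: int

    def codon_interval(self, aa_pos: int) -> tuple[int, int]:
        if not (0 <= aa_pos < len(self.aa)):
            raise IndexError(f"aa position {aa_pos} out of frame of length {len(self.aa)}")
        if self.strand == "+":
            start = self.offset + 3 * aa_pos
        else:
            start = self.source_length - self.offset - 3 * aa_pos - 3
        return start, start + 3


def six_frame_translate(record: SequenceRecord) -> list[TranslatedFrame]:
    """Translate a DNA record in all six frames (standard genetic code).

    Codons containing N translate to ``X``; stop codons to ``*``. Frames
    shorter than one codon are empty.
    """
    enc = _encode_dna(record.sequence)
    rc = _revcomp_codes(enc)
    frames = []
    for strand, codes in (("+", enc), ("-", rc)):
        for off in range(3):
            aa_codes = _translate_codes(codes, off)
            aa = "".join(AA_DECODE[c] for c in aa_codes)
            frames.append(TranslatedFrame(strand=strand, offset=off, aa=aa,
                                          source_length=len(record.sequence)))
    return frames


# --- search parameters -------------------------------------------------------


@dataclass(frozen=True)
class SearchParams:
    """Tunables of the built-in translated search.

    ``min_identity`` (0.70) is the pipeline's alignment-identity filter;
    hits below ``min_score`` (the score of a ~15-residue exact match) are
    treated as seed noise and never reported.
    """

    seed_word: int = 5
    xdrop: int = 20
    match_score: int = 2
    mismatch_score: int = -1
    min_identity: float = 0.70
    min_seed_hits: int = 1
    min_score: int = 30

    def __post_init__(self) -> None:
        if self.seed_word < 3:
            raise ValueError("seed_word must be >= 3")
        if not (0 <= self.min_identity <= 1.01):
            raise ValueError("min_identity must be a fraction")


_WINDOW = 48     # batch-extension window; longer extensions escalate to scalar
_SENT_GAP = _WINDOW + 8


# --- protein index -----------------------------------------------------------


class _ProteinIndex:
    def __init__(self, proteins: Sequence[SequenceRecord], k: int):
        self.proteins = list(proteins)
        self.k = k
        self.codes = [_encode_protein(p.sequence) for p in self.proteins]
        self.qlens = np.array([len(c) for c in self.codes], dtype=np.int64)
        # concatenated query codes for the compiled extension kernel
        self.qcat = (np.concatenate(self.codes) if self.codes
                     else np.empty(0, dtype=np.uint8))
        self.qoff = np.concatenate(([0], np.cumsum(self.qlens))).astype(np.int64)

        hashes, pids, qpos = [], [], []
        for i, c in enumerate(self.codes):
            n = len(c) - k + 1
            if n <= 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(c, k)
            ok = (windows < 20).all(axis=1)
            h = np.zeros(n, dtype=np.int64)
            for j in range(k):
                h = h * HASH_BASE + windows[:, j]
            idx = np.flatnonzero(ok)
            hashes.append(h[idx])
            pids.append(np.full(len(idx), i, dtype=np.int64))
            qpos.append(idx.astype(np.int64))
        if hashes:
            h = np.concatenate(hashes)
            order = np.argsort(h, kind="stable")
            self.kmer_hash = h[order]
            self.kmer_pid = np.concatenate(pids)[order]
            self.kmer_qpos = np.concatenate(qpos)[order]
        else:
            self.kmer_hash = np.empty(0, dtype=np.int64)
            self.kmer_pid = np.empty(0, dtype=np.int64)
            self.kmer_qpos = np.empty(0, dtype=np.int64)
        self.uhash, starts = np.unique(self.kmer_hash, return_index=True)
        self.starts = np.append(starts, len(self.kmer_hash))
        self.mask = np.zeros(HASH_BASE ** k, dtype=bool)
        self.mask[self.uhash] = True


# --- concatenated target -----------------------------------------------------


class _TargetIndex:
    """All six frames of every scaffold concatenated with sentinel gaps."""

    def __init__(self, assembly: Assembly):
        parts = [np.full(_SENT_GAP, SENT_CODE, dtype=np.uint8)]
        starts, lens, scaf, strands, offsets = [], [], [], [], []
        pos = _SENT_GAP
        for si, rec in enumerate(assembly.records):
            enc = _encode_dna(rec.sequence)
            rc = _revcomp_codes(enc)
            for strand, codes in ((0, enc), (1, rc)):
                for off in range(3):
                    aa = _translate_codes(codes, off)
                    parts.append(aa)
                    parts.append(np.full(_SENT_GAP, SENT_CODE, dtype=np.uint8))
                    starts.append(pos)
                    lens.append(len(aa))
                    scaf.append(si)
                    strands.append(strand)
                    offsets.append(off)
                    pos += len(aa) + _SENT_GAP
        self.T = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        self.frame_start = np.array(starts, dtype=np.int64)
        self.frame_len = np.array(lens, dtype=np.int64)
        self.frame_scaf = np.array(scaf, dtype=np.int64)
        self.frame_strand = np.array(strands, dtype=np.int64)
        self.frame_offset = np.array(offsets, dtype=np.int64)
        self.scaf_len = np.array([len(r) for r in assembly.records], dtype=np.int64)
        self.scaf_ids = assembly.ids()


# --- seed finding ------------------------------------------------------------


def _find_seeds(tidx: _TargetIndex, pidx: _ProteinIndex, k: int):
    T = tidx.T
    n = len(T) - k + 1
    if n <= 0 or len(pidx.uhash) == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    chunk = 1 << 22
    tpos_all, pid_all, qpos_all = [], [], []
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        seg = T[lo:hi + k - 1].astype(np.int64)
        h = seg[:hi - lo].copy()
        for j in range(1, k):
            h *= HASH_BASE
            h += seg[j:j + hi - lo]
        cand = np.flatnonzero(pidx.mask[h])
        if len(cand) == 0:
            continue
        ch = h[cand]
        idx = np.searchsorted(pidx.uhash, ch)
        ok = pidx.uhash[idx] == ch
        cand, idx = cand[ok], idx[ok]
        cnt = pidx.starts[idx + 1] - pidx.starts[idx]
        total = int(cnt.sum())
        if total == 0:
            continue
        rep_t = np.repeat(cand + lo, cnt)
        base = np.repeat(pidx.starts[idx], cnt)
        within = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        flat = base + within
        tpos_all.append(rep_t)
        pid_all.append(pidx.kmer_pid[flat])
        qpos_all.append(pidx.kmer_qpos[flat])
    if not tpos_all:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    return (np.concatenate(tpos_all), np.concatenate(pid_all),
            np.concatenate(qpos_all))


# --- extension ---------------------------------------------------------------

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    raise


@_njit(cache=False)
def _extend_one(T, qcat, qs_off, qlen, q0, t0, direction, match, mismatch, xdrop):
    """Ungapped x-drop extension in one direction (compiled inner loop).

    ``q0``/``t0`` are the first probed columns; stop codons and sentinels
    terminate the extension outright. Returns (length, score, matches) of
    the best-scoring prefix (0, 0, 0 when nothing positive is reachable).
    """
    cur = 0
    curmatch = 0
    best = 0
    best_len = 0
    best_match = 0
    d = 0
    while True:
        qi = q0 + direction * d
        if qi < 0 or qi >= qlen:
            break
        tv = T[t0 + direction * d]
        if tv == 20 or tv == 22:          # stop codon / sentinel
            break
        if qcat[qs_off + qi] == tv and tv < 20:
            cur += match
            curmatch += 1
        else:
            cur += mismatch
        d += 1
        if cur > best:
            best = cur
            best_len = d
            best_match = curmatch
        if best - cur > xdrop:
            break
    return best_len, best, best_match


@_njit(cache=False)
def _extend_all(T, qcat, qoff, qlens, pids, qpos, tpos, k, match, mismatch, xdrop):
    """Bidirectional extension of every seed; returns an (n, 6) array of
    (left_len, left_score, left_matches, right_len, right_score,
    right_matches)."""
    n = pids.shape[0]
    out = np.zeros((n, 6), dtype=np.int64)
    for i in range(n):
        p = pids[i]
        q0 = qpos[i]
        t0 = tpos[i]
        off = qoff[p]
        ql = qlens[p]
        ll, ls, lm = _extend_one(T, qcat, off, ql, q0 - 1, t0 - 1, -1,
                                 match, mismatch, xdrop)
        rl, rs, rm = _extend_one(T, qcat, off, ql, q0 + k, t0 + k, 1,
                                 match, mismatch, xdrop)
        out[i, 0] = ll
        out[i, 1] = ls
        out[i, 2] = lm
        out[i, 3] = rl
        out[i, 4] = rs
        out[i, 5] = rm
    return out


def _extend_scalar(T, qrow, qlen, q0, t0, params, direction):
    """Exact ungapped x-drop extension; q0/t0 are the first columns probed."""
    match, mismatch, xdrop = params.match_score, params.mismatch_score, params.xdrop
    cur = 0
    curmatch = 0
    best = 0
    best_len = 0
    best_match = 0
    d = 0
    while True:
        qi = q0 + direction * d
        ti = t0 + direction * d
        if qi < 0 or qi >= qlen:
            break
        tv = T[ti]
        if tv == STOP_CODE or tv == SENT_CODE:
            break
        if qrow[qi] == tv and tv < 20:
            cur += match
            curmatch += 1
        else:
            cur += mismatch
        d += 1
        if cur > best:
            best, best_len, best_match = cur, d, curmatch
        if best - cur > xdrop:
            break
    return best_len, best, best_match


# --- the searcher ------------------------------------------------------------


def search_proteins(proteins: Sequence[SequenceRecord], assembly: Assembly,
                    params: SearchParams = SearchParams()) -> list[AlignmentHit]:
    """Map many proteins onto an assembly with the built-in translated search.

    Seeds are exact ``seed_word`` amino-acid matches; seeds sharing a
    (protein, frame, diagonal) group are extended once from the earliest
    seed, with further extensions only for seeds beyond the covered span,
    so overlapping same-diagonal extensions are merged. Hits scoring below
    ``min_score`` are discarded as seed noise. Hits are returned sorted by
    score descending (deterministic tie-break).
    """
    k = params.seed_word
    pidx = _ProteinIndex(proteins, k)
    tidx = _TargetIndex(assembly)
    tpos, pid, qpos = _find_seeds(tidx, pidx, k)
    hits: list[AlignmentHit] = []
    if len(tpos) == 0:
        return hits

    n_rows = max(len(tidx.frame_start), 1)
    frame_row = np.searchsorted(tidx.frame_start, tpos, side="right") - 1
    diag_span = 2 * len(tidx.T) + int(pidx.qlens.max()) + 2
    key = (pid * n_rows + frame_row) * diag_span + (tpos - qpos + len(tidx.T))
    order = np.lexsort((qpos, key))
    key_s, pid_s, qpos_s, tpos_s, row_s = (key[order], pid[order], qpos[order],
                                           tpos[order], frame_row[order])
    boundaries = np.flatnonzero(np.diff(key_s)) + 1
    group_starts = np.concatenate(([0], boundaries))
    group_ends = np.concatenate((boundaries, [len(key_s)]))
    sizes = group_ends - group_starts
    keep = sizes >= params.min_seed_hits
    group_starts, group_ends, sizes = group_starts[keep], group_ends[keep], sizes[keep]

    rp, rq, rt, rr = (pid_s[group_starts], qpos_s[group_starts],
                      tpos_s[group_starts], row_s[group_starts])
    ext = _extend_all(tidx.T, pidx.qcat, pidx.qoff, pidx.qlens, rp, rq, rt,
                      k, params.match_score, params.mismatch_score, params.xdrop)
    llen, lsc, lm = ext[:, 0], ext[:, 1], ext[:, 2]
    rlen, rsc, rm = ext[:, 3], ext[:, 4], ext[:, 5]

    def emit_hit(p: int, row: int, qs: int, qe: int, local_ts: int,
                 score: int, matches: int) -> None:
        aln_len = qe - qs
        local_te = local_ts + aln_len
        scaf = int(tidx.frame_scaf[row])
        slen = int(tidx.scaf_len[scaf])
        off = int(tidx.frame_offset[row])
        if tidx.frame_strand[row] == 0:
            g_start, g_end = off + 3 * local_ts, off + 3 * local_te
            strand = "+"
        else:
            g_start, g_end = slen - off - 3 * local_te, slen - off - 3 * local_ts
            strand = "-"
        hits.append(AlignmentHit(
            query_id=pidx.proteins[p].id, query_len=int(pidx.qlens[p]),
            query_start=qs, query_end=qe,
            target_id=tidx.scaf_ids[scaf], target_len=slen,
            target_start=g_start, target_end=g_end, strand=strand,
            matches=matches, aln_len=aln_len, score=score,
            identity=matches / aln_len,
        ))

    min_score = params.min_score
    for i in range(len(group_starts)):
        gi = i
        p, row = int(rp[i]), int(rr[i])
        q0, t0 = int(rq[i]), int(rt[i])
        total_score = int(lsc[i]) + int(rsc[i]) + params.match_score * k
        covered_qe = q0 + k + int(rlen[i])
        if total_score >= min_score:
            qs = q0 - int(llen[i])
            qe = covered_qe
            local_ts = (t0 - int(llen[i])) - int(tidx.frame_start[row])
            emit_hit(p, row, qs, qe, local_ts,
                     total_score, int(lm[i]) + int(rm[i]) + k)
        if sizes[gi] > 1:
            qrow, qlen = pidx.codes[p], int(pidx.qlens[p])
            for j in range(group_starts[gi] + 1, group_ends[gi]):
                q1, t1 = int(qpos_s[j]), int(tpos_s[j])
                if q1 < covered_qe:
                    continue
                ll, ls, lmm = _extend_scalar(tidx.T, qrow, qlen, q1 - 1, t1 - 1, params, -1)
                rl, rs, rmm = _extend_scalar(tidx.T, qrow, qlen, q1 + k, t1 + k, params, +1)
                sc = ls + rs + params.match_score * k
                covered_qe = q1 + k + rl
                if sc >= min_score:
                    emit_hit(p, row, q1 - ll, q1 + k + rl,
                             (t1 - ll) - int(tidx.frame_start[row]),
                             sc, lmm + rmm + k)

    hits.sort(key=lambda h: (-h.score, -h.identity, -h.aln_len,
                             h.target_id, h.target_start, h.query_id))
    return hits


def search_protein(protein: SequenceRecord, assembly: Assembly,
                   params: SearchParams = SearchParams()) -> list[AlignmentHit]:
    """Map a single protein onto an assembly (see :func:`search_proteins`)."""
    return search_proteins([protein], assembly, params)


# --- external-aligner ingestion ----------------------------------------------


def import_external_hits(path_or_stream, dialect: str = "paf") -> list[AlignmentHit]:
    """Normalise external aligner output (PAF or miniprot-dialect GFF3)."""
    if dialect == "paf":
        return parse_paf(path_or_stream)
    if dialect in ("gff3", "miniprot-gff3"):
        return read_hits_gff3(path_or_stream)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'paf' or 'miniprot-gff3'")


# --- top hit and identity filter ---------------------------------------------


def _better(a: AlignmentHit, b: AlignmentHit) -> AlignmentHit:
    ka = (a.score, a.identity, a.aln_len)
    kb = (b.score, b.identity, b.aln_len)
    if ka != kb:
        return a if ka > kb else b
    kt_a = (a.target_id, a.target_start)
    kt_b = (b.target_id, b.target_start)
    return a if kt_a <= kt_b else b


def top_hit_per_protein(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Keep the single best hit per query protein.

    Ranking: score, then identity, then alignment length; remaining ties
    break to the lexicographically smallest target id and smallest start,
    so the result is a deterministic function of the hit multiset.
    """
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        best[h.query_id] = h if cur is None else _better(cur, h)
    return best


def filter_min_identity(top_hits, min_identity: float = 0.70):
    """Remove hits with identity strictly below the threshold.

    A hit at exactly the threshold is retained ("less than" is removed).
    Accepts a mapping (query -> hit) or a sequence, returning the same kind.
    """
    if isinstance(top_hits, Mapping):
        return {q: h for q, h in top_hits.items() if h.identity >= min_identity}
    return [h for h in top_hits if h.identity >= min_identity]
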