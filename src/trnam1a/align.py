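"""Glocal alignment of processed reads to the mature-tRNA reference set.

The aligner is read-global / reference-local ("glocal"): the whole read
must align (up to a small free soft-clip at either read end) while the
reference may be entered and left anywhere for free.  Gaps are affine
(open -3, extend -1 by default).  This is the geometry of a full-length
tRNA cDNA landing inside a tRNA reference, and it is deliberately tolerant
of the single expected mismatch at position 58.

Scoring is computed with a vectorised Gotoh recurrence (one numpy pass per
read row); the traceback is recovered on the winning reference only.  A
read-gap run never pays two gap openings, which lets the within-row
dependency collapse to a prefix running maximum (valid because
gap_open <= gap_extend).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import AlignmentRecord, ReadRecord
from .simulate import TRNARef

NEG = -1e9


@dataclass
class AlignParams:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -3.0
    gap_extend: float = -1.0
    min_score_fraction: float = 0.8
    multimap_policy: str = "best-unique"
    soft_clip: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.min_score_fraction <= 1):
            raise ValueError("min_score_fraction must be in (0, 1]")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must not exceed gap_extend")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _dp_matrices(read: str, ref: str, p: AlignParams):
    """Full Gotoh DP with free reference ends and free read-end soft clips.

    Returns (H, F, base) matrices of shape (n+1, m+1): H is the best score
    ending at each cell, F the best score ending in a gap-in-reference
    (read base consumed), base = H without the same-row read-gap option
    (used to reopen read gaps during traceback).
    """
    r = _encode(read)
    q = _encode(ref)
    n, m = len(r), len(q)
    go, ge = p.gap_open, p.gap_extend
    jj = np.arange(m + 1)

    H = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    B = np.full((n + 1, m + 1), NEG)
    H[0, :] = 0.0  # reference prefix is free
    B[0, :] = 0.0
    sub = np.where(q[None, :] == r[:, None], p.match, p.mismatch)
    sub[r == ord("N"), :] = 0.0  # N: neither match nor mismatch

    for i in range(1, n + 1):
        F[i] = np.maximum(H[i - 1] + go, F[i - 1] + ge)
        base = F[i].copy()
        base[1:] = np.maximum(base[1:], H[i - 1, :-1] + sub[i - 1])
        if i <= p.soft_clip:
            base = np.maximum(base, 0.0)  # free 5' read clip
        # same-row read gap (reference consumed): prefix running max
        A = base - jj * ge
        pref = np.maximum.accumulate(A)
        E = np.full(m + 1, NEG)
        E[1:] = pref[:-1] + go + (jj[1:] - 1) * ge
        H[i] = np.maximum(base, E)
        B[i] = base
    return H, F, B


def _best_end(H: np.ndarray, n: int, clip: int) -> Tuple[float, int, int]:
    best = (NEG, n, 0)
    for i in range(max(0, n - clip), n + 1):
        j = int(np.argmax(H[i]))
        if H[i, j] > best[0]:
            best = (float(H[i, j]), i, j)
    return best


def glocal_score(read: str, ref: str, params: Optional[AlignParams] = None) -> float:
    """Best glocal alignment score of ``read`` against ``ref``."""
    params = params or AlignParams()
    H, _, _ = _dp_matrices(read, ref, params)
    score, _, _ = _best_end(H, len(read), params.soft_clip)
    return score


def _traceback(read: str, ref: str, p: AlignParams):
    """Recover one optimal aligned-pairs path (score ties broken
    deterministically: diagonal, then read-gap, then ref-gap)."""
    H, F, B = _dp_matrices(read, ref, p)
    n, m = len(read), len(ref)
    go, ge = p.gap_open, p.gap_extend
    score, i, j = _best_end(H, n, p.soft_clip)
    pairs: List[Tuple[Optional[int], Optional[int]]] = []
    r = _encode(read)
    q = _encode(ref)
    sub = lambda ii, jj: (
        0.0 if r[ii - 1] == ord("N") else (p.match if r[ii - 1] == q[jj - 1] else p.mismatch)
    )
    eps = 1e-6
    while i > 0:
        h = H[i, j]
        if (i <= p.soft_clip or i == 0) and abs(h) < eps and abs(B[i, j]) < eps:
            break  # free 5' clip start
        if j > 0 and abs(h - (H[i - 1, j - 1] + sub(i, j))) < eps:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            continue
        if abs(h - B[i, j]) > eps:
            # same-row read gap: jump back to the opening column k
            jj = np.arange(j)
            cand = B[i, :j] + go + (j - 1 - jj) * ge
            k = int(np.argmax(cand))
            for col in range(j - 1, k - 1, -1):
                pairs.append((None, col))
            j = k
            continue
        if abs(h - F[i, j]) < eps:
            # vertical: read bases against gap in reference
            while i > 0:
                pairs.append((i - 1, None))
                closed = abs(F[i, j] - (H[i - 1, j] + go)) < eps
                i -= 1
                if closed:
                    break
            continue
        break  # free start (H==0 via reference prefix at row 0 handled by loop exit)
    pairs.reverse()
    return score, pairs


def _score_against_refs(read: str, refs: Sequence[TRNARef], params: AlignParams) -> np.ndarray:
    return np.array([glocal_score(read, ref.sequence, params) for ref in refs])


def align_read(
    read: ReadRecord, refs: Sequence[TRNARef], params: Optional[AlignParams] = None
) -> Optional[AlignmentRecord]:
    """Best glocal alignment of one read across all references.

    Returns ``None`` (unaligned) when the best score falls below
    ``min_score_fraction * len(read)``.  On a score tie across references
    the first reference wins and ``is_unique`` is False.
    """
    recs = align_read_all(read, refs, params)
    return recs[0] if recs else None


def align_read_all(
    read: ReadRecord, refs: Sequence[TRNARef], params: Optional[AlignParams] = None
) -> List[AlignmentRecord]:
    """All references tied at the best score, as full alignment records."""
    params = params or AlignParams()
    if not read.sequence or not refs:
        raise ValueError("read and reference set must be non-empty")
    scores = _score_against_refs(read.sequence, refs, params)
    best = scores.max()
    if best < params.min_score_fraction * len(read.sequence):
        return []
    tied = [i for i in np.flatnonzero(np.isclose(scores, best))]
    records = []
    for idx in tied:
        ref = refs[idx]
        score, pairs = _traceback(read.sequence, ref.sequence, params)
        matched = [(a, b) for a, b in pairs if a is not None and b is not None]
        if not matched:
            continue
        n_mism = sum(
            1
            for a, b in matched
            if read.sequence[a] != ref.sequence[b] and read.sequence[a] != "N"
        )
        ref_start = matched[0][1]
        gapless = (
            len(pairs) == len(matched)
            and all(b - a == pairs[0][1] - pairs[0][0] for a, b in matched)
        )
        read_lo, read_hi = matched[0][0], matched[-1][0] + 1
        records.append(
            AlignmentRecord(
                read_id=read.read_id,
                ref_id=ref.ref_id,
                ref_start=ref_start,
                sequence=read.sequence[read_lo:read_hi] if gapless else read.sequence,
                aligned_pairs=None if gapless else pairs,
                n_mismatch=n_mism,
                score=float(score),
                is_unique=len(tied) == 1,
                umi=read.umi,
            )
        )
    return records


def resolve_multimap(
    alns: List[AlignmentRecord], policy: str = "best-unique", seed: int = 0
) -> Optional[AlignmentRecord]:
    """Resolve ties among equally-scoring alignments of one read.

    ``best-unique`` and ``drop`` discard ambiguous reads; ``random-tiebreak``
    picks uniformly with a seeded RNG (deterministic given the seed and the
    read id).
    """
    if policy not in ("best-unique", "drop", "random-tiebreak"):
        raise ValueError(f"unknown multimap policy {policy!r}")
    if not alns:
        return None
    if len({a.read_id for a in alns}) != 1:
        raise ValueError("resolve_multimap expects alignments of a single read")
    if len(alns) == 1:
        return alns[0]
    if policy in ("best-unique", "drop"):
        return None
    import zlib

    rng = np.random.default_rng([seed, zlib.crc32(alns[0].read_id.encode())])
    return alns[int(rng.integers(0, len(alns)))]


def collapse_identical_refs(refs: Sequence[TRNARef]) -> List[TRNARef]:
    """Collapse byte-identical reference sequences into one jointly named
    entry (mismatch attribution between indistinguishable refs is undefined)."""
    seen = {}
    order = []
    for ref in refs:
        if ref.sequence in seen:
            seen[ref.sequence].append(ref)
        else:
            seen[ref.sequence] = [ref]
            order.append(ref.sequence)
    out = []
    for seq in order:
        group = seen[seq]
        if len(group) == 1:
            out.append(group[0])
        else:
            joint = "|".join(r.ref_id for r in group)
            first = group[0]
            out.append(
                TRNARef(
                    ref_id=joint,
                    sequence=first.sequence,
                    anticodon=first.anticodon,
                    a58_index=first.a58_index,
                    decoded_codons=frozenset().union(*(r.decoded_codons for r in group)),
                )
            )
    return out


def align_reads(
    reads: Sequence[ReadRecord],
    refs: Sequence[TRNARef],
    params: Optional[AlignParams] = None,
) -> Tuple[List[AlignmentRecord], dict]:
    """Align a batch of reads; multimaps resolved per the configured policy."""
    params = params or AlignParams()
    refs = collapse_identical_refs(refs)
    out = []
    stats = {"input": 0, "aligned": 0, "unaligned": 0, "multimapped_dropped": 0}
    for read in reads:
        stats["input"] += 1
        recs = align_read_all(read, refs, params)
        if not recs:
            stats["unaligned"] += 1
            continue
        chosen = resolve_multimap(recs, params.multimap_policy, params.seed)
        if chosen is None:
            stats["multimapped_dropped"] += 1
            continue
        out.append(chosen)
        stats["aligned"] += 1
    return out, stats
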