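"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately share no code with the package internals: plain-Python
dynamic programming for alignment scores, set construction for
deduplication, and direct recounting for pileups.
"""

from __future__ import annotations

NEG = -1e9


def nw_free_ref_ends(read: str, ref: str, match=1.0, mismatch=-1.0,
                     gap_open=-3.0, gap_extend=-1.0) -> float:
    """Affine Needleman-Wunsch with free reference ends (read fully aligned)."""
    n, m = len(read), len(ref)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        H[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(m + 1):
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            best = F[i][j]
            if j > 0:
                E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
                s = 0.0 if read[i - 1] == "N" else (match if read[i - 1] == ref[j - 1] else mismatch)
                best = max(best, E[i][j], H[i - 1][j - 1] + s)
            H[i][j] = best
    return max(H[n])


def glocal_with_clips(read: str, ref: str, soft_clip=2, **scores) -> float:
    """Glocal score allowing up to ``soft_clip`` free bases clipped off
    either read end: enumerate all clip combinations, take the best."""
    best = NEG
    for cs in range(soft_clip + 1):
        for ce in range(soft_clip + 1):
            sub = read[cs : len(read) - ce] if ce else read[cs:]
            if not sub:
                continue
            best = max(best, nw_free_ref_ends(sub, ref, **scores))
    return best


def distinct_dedup_keys(frame) -> set:
    """Independent construction of the deduplication key set."""
    return {
        (row.ref_id, row.ref_start, row.umi) for row in frame.itertuples(index=False)
    }


def recount_pileup(frame, refs) -> dict:
    """From-scratch per-position base recount from the alignment table."""
    counts = {r.ref_id: {} for r in refs}
    for row in frame.itertuples(index=False):
        if row.pairs is None:
            pairs = [(k, row.ref_start + k) for k in range(len(row.seq))]
        else:
            pairs = [(a, b) for a, b in row.pairs if a is not None and b is not None]
        for read_i, ref_i in pairs:
            base = row.seq[read_i]
            if base == "N":
                continue
            key = (ref_i, base)
            counts[row.ref_id][key] = counts[row.ref_id].get(key, 0) + 1
    return counts
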