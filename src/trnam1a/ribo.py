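"""Ribosome-profiling QC and translation efficiency.

QC checks the geometry expected of true footprints: lengths concentrated
at 28-32 nt, a fixed offset (12 nt) between the footprint 5' end and the
P-site codon at initiation, and 3-nt periodicity (P-sites in frame 0 of
the CDS).  Expression is summarised as RPKM over the CDS; translation
efficiency (TE) is the ratio Ribo RPKM / RNA RPKM, and transcripts moving
at least 4-fold in TE between conditions are classed up/down.

``total_mapped`` in RPKM is the number of reads assigned to the CDS
regions of the analysed transcript set per library, which keeps the Ribo
and RNA denominators commensurable; this choice is recorded in output
metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import Transcript

DEFAULT_P_SITE_OFFSET = 12


@dataclass
class FootprintProfile:
    """Per-transcript footprint geometry: 5'-end counts by coordinate,
    read-length histogram, and P-site frame counts relative to the CDS."""

    transcript_id: str
    five_prime_counts: Dict[int, int] = field(default_factory=dict)
    length_histogram: Dict[int, int] = field(default_factory=dict)
    frame_counts: tuple = (0, 0, 0)


def build_profiles(
    positions: pd.DataFrame,
    transcripts: Sequence[Transcript],
    offset: int = DEFAULT_P_SITE_OFFSET,
) -> Dict[str, FootprintProfile]:
    """Aggregate a footprint position table (transcript_id, five_prime,
    length) into per-transcript profiles.  Frames are assigned to the
    P-site (5' end + offset) relative to the CDS start."""
    by_t = {t.gene_id: t for t in transcripts}
    profiles: Dict[str, FootprintProfile] = {}
    for tid, sub in positions.groupby("transcript_id", sort=True):
        t = by_t[tid]
        five = sub["five_prime"].to_numpy(np.int64)
        lengths = sub["length"].to_numpy(np.int64)
        frames = np.mod(five + offset - t.cds_start, 3)
        fc = tuple(int((frames == k).sum()) for k in range(3))
        fp_counts = pd.Series(five).value_counts().to_dict()
        len_counts = pd.Series(lengths).value_counts().to_dict()
        profiles[tid] = FootprintProfile(
            transcript_id=tid,
            five_prime_counts={int(k): int(v) for k, v in fp_counts.items()},
            length_histogram={int(k): int(v) for k, v in len_counts.items()},
            frame_counts=fc,
        )
    return profiles


def length_histogram(profiles: Dict[str, FootprintProfile]) -> pd.Series:
    total: Dict[int, int] = {}
    for prof in profiles.values():
        for length, n in prof.length_histogram.items():
            total[length] = total.get(length, 0) + n
    return pd.Series(total).sort_index()


def p_site_offset(
    profiles: Dict[str, FootprintProfile],
    transcripts: Sequence[Transcript],
    search: Iterable[int] = range(0, 19),
) -> int:
    """Offset (nt) between footprint 5' ends and the initiating P-site.

    Searches 0..18 for the shift maximising the aggregate 5'-end count at
    ``cds_start - offset`` over all transcripts: the initiation pile-up.
    Raises when no footprints land near any start codon.
    """
    by_t = {t.gene_id: t for t in transcripts}
    scores = {}
    for off in search:
        total = 0
        for tid, prof in profiles.items():
            start = by_t[tid].cds_start
            total += prof.five_prime_counts.get(start - off, 0)
        scores[off] = total
    if not scores or max(scores.values()) == 0:
        raise ValueError("no footprints near translation starts; offset undefined")
    best = max(scores.values())
    return min(off for off, v in scores.items() if v == best)


def periodicity(profiles: Dict[str, FootprintProfile]) -> float:
    """Fraction of P-site assignments falling in frame 0 of the CDS."""
    frames = np.zeros(3, dtype=np.int64)
    for prof in profiles.values():
        frames += np.asarray(prof.frame_counts)
    total = int(frames.sum())
    if total == 0:
        raise ValueError("no assigned positions; periodicity undefined")
    return float(frames[0]) / total


def rpkm(count: float, cds_length: int, total_mapped: int) -> float:
    """Reads per kilobase of CDS per million mapped reads."""
    if cds_length <= 0 or total_mapped <= 0:
        raise ValueError("cds_length and total_mapped must be positive")
    return count / ((cds_length / 1000.0) * (total_mapped / 1e6))


def translation_efficiency(rpkm_ribo: float, rpkm_rna: float) -> float:
    """TE = Ribo RPKM / RNA RPKM; NaN (flagged undefined) when RNA RPKM is 0."""
    if rpkm_rna == 0:
        return float("nan")
    return rpkm_ribo / rpkm_rna


def classify_te_change(te_a: float, te_b: float, fc_threshold: float = 4.0) -> str:
    """up / down / unchanged by fold change in TE between conditions."""
    if math.isnan(te_a) or math.isnan(te_b):
        return "undefined"
    if te_a == 0:
        return "up" if te_b > 0 else "unchanged"
    fc = te_b / te_a
    if fc >= fc_threshold:
        return "up"
    if fc <= 1.0 / fc_threshold:
        return "down"
    return "unchanged"


def cds_counts(
    positions: pd.DataFrame,
    transcripts: Sequence[Transcript],
    offset: int = 0,
) -> pd.Series:
    """Reads assigned to each transcript's CDS.

    A read is counted when its (5' end + offset) falls inside the CDS; use
    ``offset=12`` for footprints (P-site) and 0 for RNA fragments.
    """
    by_t = {t.gene_id: t for t in transcripts}
    counts = {t.gene_id: 0 for t in transcripts}
    if not positions.empty:
        for tid, sub in positions.groupby("transcript_id", sort=False):
            t = by_t[tid]
            site = sub["five_prime"].to_numpy(np.int64) + offset
            counts[tid] = int(((site >= t.cds_start) & (site < t.cds_end)).sum())
    return pd.Series(counts, name="count")


def differential_te(
    te_A: pd.Series, te_B: pd.Series, fc_threshold: float = 4.0
) -> pd.DataFrame:
    """Per-transcript TE class between two conditions; transcripts with an
    undefined TE in either condition are excluded (reported 'undefined')."""
    idx = te_A.index.union(te_B.index)
    rows = []
    for tid in idx:
        a = float(te_A.get(tid, float("nan")))
        b = float(te_B.get(tid, float("nan")))
        cls = classify_te_change(a, b, fc_threshold)
        log2fc = (
            math.log2(b / a) if (a > 0 and b > 0 and not math.isnan(a) and not math.isnan(b))
            else float("nan")
        )
        rows.append((tid, a, b, log2fc, cls))
    return pd.DataFrame(
        rows, columns=["transcript_id", "te_A", "te_B", "log2fc_te", "te_class"]
    )


class TranslationEfficiencyModel:
    """RPKM-ratio model of translation efficiency for one condition.

    Built from per-transcript CDS read counts of the Ribo-seq and RNA-seq
    libraries.  ``fit`` computes RPKMs, TE and a delta-method standard
    error of log TE (1/n_ribo + 1/n_rna under Poisson counts).
    """

    def __init__(
        self,
        ribo_counts: pd.Series,
        rna_counts: pd.Series,
        cds_lengths: pd.Series,
    ):
        self.ribo_counts = ribo_counts
        self.rna_counts = rna_counts
        self.cds_lengths = cds_lengths

    @classmethod
    def from_positions(
        cls,
        ribo_positions: pd.DataFrame,
        rna_positions: pd.DataFrame,
        transcripts: Sequence[Transcript],
        offset: int = DEFAULT_P_SITE_OFFSET,
    ) -> "TranslationEfficiencyModel":
        lengths = pd.Series(
            {t.gene_id: t.cds_end - t.cds_start for t in transcripts}, name="cds_length"
        )
        return cls(
            cds_counts(ribo_positions, transcripts, offset=offset),
            cds_counts(rna_positions, transcripts, offset=0),
            lengths,
        )

    def fit(self) -> "TEResults":
        idx = self.cds_lengths.index
        ribo = self.ribo_counts.reindex(idx, fill_value=0).astype(float)
        rna = self.rna_counts.reindex(idx, fill_value=0).astype(float)
        total_ribo = int(ribo.sum())
        total_rna = int(rna.sum())
        if total_ribo == 0 or total_rna == 0:
            raise ValueError("no mapped reads in one of the libraries")
        rpkm_ribo = pd.Series(
            [rpkm(c, l, total_ribo) for c, l in zip(ribo, self.cds_lengths)], index=idx
        )
        rpkm_rna = pd.Series(
            [rpkm(c, l, total_rna) for c, l in zip(rna, self.cds_lengths)], index=idx
        )
        te = pd.Series(
            [translation_efficiency(a, b) for a, b in zip(rpkm_ribo, rpkm_rna)], index=idx
        )
        se_log = pd.Series(
            [
                math.sqrt(1 / r + 1 / n) if r > 0 and n > 0 else float("nan")
                for r, n in zip(ribo, rna)
            ],
            index=idx,
        )
        table = pd.DataFrame(
            {
                "transcript_id": idx,
                "count_ribo": ribo.to_numpy(int),
                "count_rna": rna.to_numpy(int),
                "rpkm_ribo": rpkm_ribo.to_numpy(),
                "rpkm_rna": rpkm_rna.to_numpy(),
                "te": te.to_numpy(),
                "se_log_te": se_log.to_numpy(),
            }
        ).reset_index(drop=True)
        return TEResults(self, table, total_ribo, total_rna)


class TEResults:
    """Fitted per-transcript RPKMs and translation efficiencies."""

    def __init__(self, model, table: pd.DataFrame, total_ribo: int, total_rna: int):
        self.model = model
        self.table = table
        self.total_mapped_ribo = total_ribo
        self.total_mapped_rna = total_rna

    @property
    def te(self) -> pd.Series:
        return self.table.set_index("transcript_id")["te"]

    def compare(self, other: "TEResults", fc_threshold: float = 4.0) -> pd.DataFrame:
        """Differential translation (self = condition A, other = B)."""
        return differential_te(self.te, other.te, fc_threshold)

    def summary(self, max_rows: int = 20) -> str:
        head = self.table.head(max_rows)
        lines = [
            "Translation efficiency (Ribo RPKM / RNA RPKM)",
            "=" * 64,
            f"transcripts: {len(self.table)}   mapped ribo: {self.total_mapped_ribo}"
            f"   mapped rna: {self.total_mapped_rna}",
            "-" * 64,
            f"{'transcript':<12}{'n_ribo':>8}{'n_rna':>8}{'rpkm_ribo':>11}"
            f"{'rpkm_rna':>10}{'te':>8}",
            "-" * 64,
        ]
        for row in head.itertuples(index=False):
            lines.append(
                f"{row.transcript_id:<12}{row.count_ribo:>8}{row.count_rna:>8}"
                f"{row.rpkm_ribo:>11.1f}{row.rpkm_rna:>10.1f}{row.te:>8.3f}"
            )
        if len(self.table) > max_rows:
            lines.append(f"... ({len(self.table) - max_rows} more)")
        lines.append("-" * 64)
        return "\n".join(lines)

    def plot(self, other: Optional["TEResults"] = None, fc_threshold: float = 4.0, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if other is None:
            ax.hist(np.log2(self.te.dropna().clip(lower=1e-6)), bins=30)
            ax.set_xlabel("log2 TE")
        else:
            diff = self.compare(other, fc_threshold)
            colors = diff["te_class"].map(
                {"up": "red", "down": "blue", "unchanged": "black", "undefined": "grey"}
            )
            ax.scatter(np.log2(diff["te_A"]), np.log2(diff["te_B"]), c=colors, s=10)
            ax.set_xlabel("log2 TE, condition A")
            ax.set_ylabel("log2 TE, condition B")
        return ax
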