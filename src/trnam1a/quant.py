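"""m1A58 stoichiometry quantification from RT misincorporation.

The estimator rests on a simple observation model: reverse transcription
across N1-methyladenosine misreads the base, so at the canonical position
58 the fraction of non-reference bases among deduplicated reads estimates
the methylated fraction of molecules (the stoichiometry).  A parallel
demethylase-treated library provides the contrast: a genuine m1A signal
collapses after treatment, while SNPs and sequencing error do not.  A site
is *called* when both arms are adequately covered and the untreated-minus-
treated rate difference clears ``delta_min``.

Workflow: PCR deduplication on the (reference, position, barcode) key ->
per-position pileup -> mismatch rates -> demethylation-contrast calling ->
cross-condition differential table.  The statsmodels-style entry point is
:class:`M1AStoichiometryModel`, whose :meth:`~M1AStoichiometryModel.fit`
returns an :class:`M1AResults` with estimates, binomial standard errors
and a summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import AlignmentRecord, records_to_frame
from .simulate import TRNARef

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class CallConfig:
    """Thresholds for site calling; declared defaults, all config-exposed.

    Stoichiometry bands: low < ``band_medium`` <= medium < ``band_high`` <= high.
    """

    min_coverage: int = 50
    delta_min: float = 0.05
    background_subtract: bool = False
    band_medium: float = 0.3
    band_high: float = 0.9
    elevation_min: float = 0.05
    count_deletions_as_mismatch: bool = False

    def __post_init__(self):
        if not (0 < self.delta_min < 1):
            raise ValueError("delta_min must be in (0, 1)")
        if not (0 < self.band_medium < self.band_high <= 1):
            raise ValueError("band bounds must be ordered in (0, 1]")

    def band(self, stoichiometry: float) -> str:
        if math.isnan(stoichiometry):
            return "undefined"
        if stoichiometry >= self.band_high:
            return "high"
        if stoichiometry >= self.band_medium:
            return "medium"
        return "low"


AlignmentInput = Union[pd.DataFrame, Iterable[AlignmentRecord]]


def _as_frame(alns: AlignmentInput) -> pd.DataFrame:
    if isinstance(alns, pd.DataFrame):
        return alns
    return records_to_frame(alns)


def dedup(alns: AlignmentInput) -> pd.DataFrame:
    """Collapse PCR duplicates: one representative per
    (ref_id, ref_start, UMI) key — identical mapping position *and* the
    same random barcode are both required.  The representative is the
    first record in a stable sort by read id, so the outcome is
    deterministic and idempotent.
    """
    frame = _as_frame(alns)
    if frame.empty:
        return frame
    if frame["umi"].isna().any():
        raise ValueError("dedup requires a UMI on every alignment record")
    ordered = frame.sort_values("read_id", kind="mergesort")
    kept = ordered.drop_duplicates(subset=["ref_id", "ref_start", "umi"], keep="first")
    return kept.reset_index(drop=True)


class Pileup:
    """Per-position base counts for each reference.

    ``base_counts[ref_id]`` is an (L, 4) array over A/C/G/T; deletions are
    tracked separately in ``deletions[ref_id]`` and excluded from coverage.
    'N' read bases contribute to neither.
    """

    def __init__(self, refs: Sequence[TRNARef]):
        self.refs = {r.ref_id: r for r in refs}
        self.base_counts: Dict[str, np.ndarray] = {
            r.ref_id: np.zeros((len(r.sequence), 4), dtype=np.int64) for r in refs
        }
        self.deletions: Dict[str, np.ndarray] = {
            r.ref_id: np.zeros(len(r.sequence), dtype=np.int64) for r in refs
        }

    def coverage(self, ref_id: str, position: int) -> int:
        return int(self.base_counts[ref_id][position].sum())

    def counts_at(self, ref_id: str, position: int) -> np.ndarray:
        return self.base_counts[ref_id][position]


def pileup(alns: AlignmentInput, refs: Sequence[TRNARef]) -> Pileup:
    """Accumulate deduplicated alignments into per-position base counts."""
    frame = _as_frame(alns)
    pile = Pileup(refs)
    if frame.empty:
        return pile
    unknown = set(frame["ref_id"]) - set(pile.refs)
    if unknown:
        raise ValueError(f"alignments reference unknown refs: {sorted(unknown)}")
    pairs_col = frame["pairs"] if "pairs" in frame.columns else pd.Series([None] * len(frame))
    gapless_mask = pairs_col.isna() if pairs_col.dtype == object else pd.Series(True, index=frame.index)

    for ref_id, sub in frame[gapless_mask.values].groupby("ref_id", sort=False):
        counts = pile.base_counts[ref_id]
        L = counts.shape[0]
        seqs = sub["seq"].tolist()
        starts = sub["ref_start"].to_numpy(np.int64)
        lens = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
        blob = _CODE[np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)]
        pos = np.repeat(starts, lens) + _concat_aranges(lens)
        ok = (blob != 255) & (pos >= 0) & (pos < L)
        np.add.at(counts, (pos[ok], blob[ok].astype(np.int64)), 1)

    for row in frame[~gapless_mask.values].itertuples(index=False):
        counts = pile.base_counts[row.ref_id]
        dels = pile.deletions[row.ref_id]
        for read_i, ref_i in row.pairs:
            if ref_i is None:
                continue
            if read_i is None:
                dels[ref_i] += 1
                continue
            base = row.seq[read_i]
            if base in _BASE_INDEX:
                counts[ref_i, _BASE_INDEX[base]] += 1
    return pile


def _concat_aranges(lengths: np.ndarray) -> np.ndarray:
    total = int(lengths.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(lengths)[:-1]
    out[ends] = -lengths[:-1] + 1
    return np.cumsum(out)


def mismatch_rate(
    counts: np.ndarray, ref_base: str, deletions: int = 0,
    count_deletions_as_mismatch: bool = False,
) -> float:
    """Fraction of non-reference bases at a position; NaN when uncovered.

    Deletions are excluded from numerator and denominator unless
    ``count_deletions_as_mismatch`` (read-through chemistry yields
    mismatches, not gaps).
    """
    coverage = int(np.sum(counts))
    numer = coverage - int(counts[_BASE_INDEX[ref_base]])
    if count_deletions_as_mismatch:
        coverage += deletions
        numer += deletions
    if coverage == 0:
        return float("nan")
    return numer / coverage


def position_mismatch_table(pile: Pileup) -> pd.DataFrame:
    """Full per-position mismatch TSV payload (all sites tabulated; only
    position 58 is *called*).  Positions reported 1-based."""
    rows = []
    for ref_id, ref in pile.refs.items():
        counts = pile.base_counts[ref_id]
        dels = pile.deletions[ref_id]
        cov = counts.sum(axis=1)
        for pos, base in enumerate(ref.sequence):
            rate = mismatch_rate(counts[pos], base, int(dels[pos])) if base in _BASE_INDEX else float("nan")
            rows.append(
                (ref_id, pos + 1, base, int(cov[pos]), *counts[pos].tolist(),
                 int(dels[pos]), rate)
            )
    return pd.DataFrame(
        rows,
        columns=["ref_id", "position", "ref_base", "coverage", "A", "C", "G", "T",
                 "deletions", "mismatch_rate"],
    )


def call_m1a58(
    pileup_untreated: Pileup,
    pileup_demethylated: Pileup,
    refs: Sequence[TRNARef],
    cfg: Optional[CallConfig] = None,
) -> pd.DataFrame:
    """Call m1A58 per tRNA from the demethylation contrast.

    For each reference's position-58 adenosine: the untreated and
    demethylated mismatch rates, their difference (delta), the
    stoichiometry estimate (the raw untreated rate by default, delta when
    ``background_subtract``), a Wald binomial standard error, coverage
    gates, the call flag and a stoichiometry band.  Uncovered sites are
    recorded with ``min_cov_ok=False``, never dropped.  The ``position``
    column is 1-based.
    """
    cfg = cfg or CallConfig()
    rows = []
    for ref in refs:
        pos = ref.a58_index
        c_u = pileup_untreated.counts_at(ref.ref_id, pos)
        c_d = pileup_demethylated.counts_at(ref.ref_id, pos)
        cov_u, cov_d = int(c_u.sum()), int(c_d.sum())
        rate_u = mismatch_rate(c_u, "A", int(pileup_untreated.deletions[ref.ref_id][pos]),
                               cfg.count_deletions_as_mismatch)
        rate_d = mismatch_rate(c_d, "A", int(pileup_demethylated.deletions[ref.ref_id][pos]),
                               cfg.count_deletions_as_mismatch)
        delta = rate_u - rate_d if not (math.isnan(rate_u) or math.isnan(rate_d)) else float("nan")
        stoich = delta if cfg.background_subtract else rate_u
        min_cov_ok = cov_u >= cfg.min_coverage and cov_d >= cfg.min_coverage
        called = bool(min_cov_ok and not math.isnan(delta) and delta >= cfg.delta_min)
        se = (
            math.sqrt(max(stoich * (1 - stoich), 0.0) / cov_u)
            if cov_u > 0 and not math.isnan(stoich)
            else float("nan")
        )
        rows.append(
            (ref.ref_id, pos + 1, cov_u, cov_d, rate_u, rate_d, delta, stoich, se,
             min_cov_ok, called, cfg.band(stoich) if called or min_cov_ok else "undefined")
        )
    return pd.DataFrame(
        rows,
        columns=["ref_id", "position", "cov_untreated", "cov_demethylated",
                 "mism_untreated", "mism_demethylated", "delta", "stoichiometry",
                 "se", "min_cov_ok", "called", "band"],
    )


def differential_m1a(
    calls_A: pd.DataFrame, calls_B: pd.DataFrame, cfg: Optional[CallConfig] = None
) -> pd.DataFrame:
    """Cross-condition differential methylation table.

    ``elevated_in_B`` requires the site to be called in both conditions and
    the stoichiometry gain to clear ``elevation_min``.  The band is taken
    from the lower-stoichiometry condition.  References present in only one
    condition are flagged and excluded from the elevated set.  Sorted by
    diff descending.
    """
    cfg = cfg or CallConfig()
    a = calls_A.set_index("ref_id")
    b = calls_B.set_index("ref_id")
    universe = sorted(set(a.index) | set(b.index))
    rows = []
    for ref_id in universe:
        in_a, in_b = ref_id in a.index, ref_id in b.index
        s_a = float(a.loc[ref_id, "stoichiometry"]) if in_a else float("nan")
        s_b = float(b.loc[ref_id, "stoichiometry"]) if in_b else float("nan")
        called_a = bool(a.loc[ref_id, "called"]) if in_a else False
        called_b = bool(b.loc[ref_id, "called"]) if in_b else False
        diff = s_b - s_a
        lower = min(s_a, s_b) if not (math.isnan(s_a) or math.isnan(s_b)) else float("nan")
        elevated = bool(
            in_a and in_b and called_a and called_b and not math.isnan(diff)
            and diff >= cfg.elevation_min
        )
        rows.append(
            (ref_id, s_a, s_b, diff, cfg.band(lower), called_a, called_b,
             elevated, not (in_a and in_b))
        )
    out = pd.DataFrame(
        rows,
        columns=["ref_id", "stoich_A", "stoich_B", "diff", "band", "called_A",
                 "called_B", "elevated_in_B", "missing_condition"],
    )
    return out.sort_values("diff", ascending=False, kind="mergesort").reset_index(drop=True)


class M1AStoichiometryModel:
    """Binomial misincorporation model for per-tRNA m1A58 stoichiometry.

    Built from the untreated and demethylase-treated pileups (or directly
    from alignment tables via :meth:`from_alignments`, which deduplicates
    first).  ``fit`` evaluates the contrast at each reference's position-58
    adenosine and returns an :class:`M1AResults`.
    """

    def __init__(
        self,
        pileup_untreated: Pileup,
        pileup_demethylated: Pileup,
        refs: Sequence[TRNARef],
        config: Optional[CallConfig] = None,
    ):
        self.pileup_untreated = pileup_untreated
        self.pileup_demethylated = pileup_demethylated
        self.refs = list(refs)
        self.config = config or CallConfig()

    @classmethod
    def from_alignments(
        cls,
        alns_untreated: AlignmentInput,
        alns_demethylated: AlignmentInput,
        refs: Sequence[TRNARef],
        config: Optional[CallConfig] = None,
        deduplicate: bool = True,
    ) -> "M1AStoichiometryModel":
        frame_u = _as_frame(alns_untreated)
        frame_d = _as_frame(alns_demethylated)
        if deduplicate:
            frame_u = dedup(frame_u)
            frame_d = dedup(frame_d)
        return cls(pileup(frame_u, refs), pileup(frame_d, refs), refs, config)

    def fit(self) -> "M1AResults":
        calls = call_m1a58(self.pileup_untreated, self.pileup_demethylated,
                           self.refs, self.config)
        return M1AResults(self, calls)


class M1AResults:
    """Fitted per-tRNA stoichiometries with uncertainties and call status."""

    def __init__(self, model: M1AStoichiometryModel, calls: pd.DataFrame):
        self.model = model
        self.calls = calls

    @property
    def stoichiometry(self) -> pd.Series:
        return self.calls.set_index("ref_id")["stoichiometry"]

    def compare(self, other: "M1AResults", config: Optional[CallConfig] = None) -> pd.DataFrame:
        """Differential methylation against another condition (self = A,
        other = B)."""
        return differential_m1a(self.calls, other.calls, config or self.model.config)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "m1A58 stoichiometry (misincorporation contrast)",
            "=" * 72,
            f"references: {len(self.calls)}   called: {int(self.calls['called'].sum())}"
            f"   min_coverage={cfg.min_coverage}  delta_min={cfg.delta_min}",
            "-" * 72,
            f"{'tRNA':<22}{'pos':>4}{'mism_untr':>11}{'mism_dem':>10}"
            f"{'stoich':>8}{'se':>8}{'band':>8}{'called':>8}",
            "-" * 72,
        ]
        for row in self.calls.itertuples(index=False):
            lines.append(
                f"{row.ref_id:<22}{row.position:>4}{row.mism_untreated:>11.4f}"
                f"{row.mism_demethylated:>10.4f}{row.stoichiometry:>8.4f}"
                f"{row.se:>8.4f}{row.band:>8}{str(row.called):>8}"
            )
        lines.append("-" * 72)
        return "\n".join(lines)

    def plot(self, other: Optional["M1AResults"] = None, ax=None):
        """Scatter of per-tRNA stoichiometry; with ``other``, condition A
        vs condition B with elevated tRNAs highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if other is None:
            ax.errorbar(range(len(self.calls)), self.calls["stoichiometry"],
                        yerr=self.calls["se"], fmt="o")
            ax.set_xticks(range(len(self.calls)))
            ax.set_xticklabels(self.calls["ref_id"], rotation=90)
            ax.set_ylabel("m1A58 stoichiometry")
        else:
            diff = self.compare(other)
            colors = np.where(diff["elevated_in_B"], "red", "black")
            ax.scatter(diff["stoich_A"], diff["stoich_B"], c=colors, s=18)
            lim = [0, 1]
            ax.plot(lim, lim, lw=0.5, color="grey")
            ax.set_xlabel("stoichiometry, condition A")
            ax.set_ylabel("stoichiometry, condition B")
        return ax
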