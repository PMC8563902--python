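"""Read preprocessing: quality trimming, 3' adapter removal, 5' barcode
extraction and ribosome-footprint length filtering.

Settings mirror a Trim-Galore-style default run: 3' quality trimming at
Q20 with the BWA running-sum rule, adapter removal by the earliest
sufficiently matching suffix overlap (minimum 5 nt, 10% mismatch
tolerance).  The untreated and demethylase-treated arms must be processed
with identical settings; the config hash recorded in outputs enforces
this.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from typing import Iterable, List, Optional, Tuple

from .io import ReadRecord
from .simulate import LibraryDesign


@dataclass
class PreprocessConfig:
    adapter3: str = LibraryDesign.adapter3
    min_quality: int = 20
    umi_length: int = 10
    footprint_min: int = 25
    footprint_max: int = 33
    min_overlap: int = 5
    mismatch_tolerance: float = 0.1

    def __post_init__(self):
        if not (0 < self.footprint_min <= self.footprint_max):
            raise ValueError("footprint bounds must satisfy 0 < min <= max")
        if self.min_quality < 0:
            raise ValueError("min_quality must be >= 0")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _quality_trim_index(qualities: str, threshold: int) -> int:
    """BWA-style 3' quality trim: cut at the position maximising the
    running sum of (threshold - q) from the 3' end; returns the new length."""
    best_sum = 0
    best_len = len(qualities)
    running = 0
    for i in range(len(qualities) - 1, -1, -1):
        running += threshold - (ord(qualities[i]) - 33)
        if running > best_sum:
            best_sum = running
            best_len = i
    return best_len


def _adapter_start(seq: str, adapter: str, min_overlap: int, tolerance: float) -> Optional[int]:
    """Earliest position where a suffix of the read matches a prefix of the
    adapter with at most ``tolerance`` mismatches per overlap base."""
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter))
        if overlap < min_overlap:
            break
        allowed = int(tolerance * overlap)
        mism = 0
        for a, b in zip(seq[i : i + overlap], adapter[:overlap]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return i
    return None


def trim_read(read: ReadRecord, cfg: PreprocessConfig) -> Optional[ReadRecord]:
    """Quality-trim then adapter-trim one read; ``None`` means discarded."""
    cut = _quality_trim_index(read.qualities, cfg.min_quality)
    seq, qual = read.sequence[:cut], read.qualities[:cut]
    start = _adapter_start(seq, cfg.adapter3, cfg.min_overlap, cfg.mismatch_tolerance)
    if start is not None:
        seq, qual = seq[:start], qual[:start]
    if not seq:
        return None
    return ReadRecord(read.read_id, seq, qual, umi=read.umi)


def extract_umi(read: ReadRecord, umi_length: int = 10) -> Optional[Tuple[str, ReadRecord]]:
    """Split off the 5' random barcode; ``None`` if nothing would remain."""
    if len(read) <= umi_length:
        return None
    umi = read.sequence[:umi_length]
    rest = ReadRecord(
        read.read_id,
        read.sequence[umi_length:],
        read.qualities[umi_length:],
        umi=umi,
    )
    return umi, rest


def preprocess_reads(
    reads: Iterable[ReadRecord], cfg: Optional[PreprocessConfig] = None
) -> Tuple[List[ReadRecord], dict]:
    """Full tRNA-seq preprocessing: trim, then extract the barcode.

    Returns the surviving reads (with ``umi`` set) and a per-stage
    accounting summary.
    """
    cfg = cfg or PreprocessConfig()
    out: List[ReadRecord] = []
    stats = {"input": 0, "discarded_trim": 0, "discarded_short": 0, "passed": 0,
             "config_hash": cfg.config_hash()}
    for read in reads:
        stats["input"] += 1
        trimmed = trim_read(read, cfg)
        if trimmed is None:
            stats["discarded_trim"] += 1
            continue
        split = extract_umi(trimmed, cfg.umi_length)
        if split is None:
            stats["discarded_short"] += 1
            continue
        out.append(split[1])
        stats["passed"] += 1
    return out, stats


def filter_footprints(
    reads: Iterable[ReadRecord], cfg: Optional[PreprocessConfig] = None
) -> Tuple[List[ReadRecord], dict]:
    """Keep reads whose length is a plausible ribosome footprint (25-33 nt)."""
    cfg = cfg or PreprocessConfig()
    kept = []
    stats = {"input": 0, "passed": 0}
    for read in reads:
        stats["input"] += 1
        if cfg.footprint_min <= len(read) <= cfg.footprint_max:
            kept.append(read)
            stats["passed"] += 1
    return kept, stats
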