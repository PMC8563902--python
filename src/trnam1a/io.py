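"""Readers and writers for the pipeline's on-disk formats.

FASTA and FASTQ parsing is delegated to Biopython; thin wrappers add
record-index error reporting, uppercase normalisation of reference bases,
and gzip autodetection by suffix.  Tabular reports are TSV files with
``#``-prefixed metadata lines, handled through pandas.  A minimal write-only
SAM exporter and a pysam-based SAM importer are provided for
interoperability with external aligners; the pipeline's native interchange
for alignments is the in-memory alignment table (see
:func:`records_to_frame`).
"""

from __future__ import annotations

import gzip
import io as _io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_UMI_RE = re.compile(r"^[ACGTN]+$")


class FastqParseError(ValueError):
    """Raised when a FASTQ record cannot be parsed; names the record index."""


@dataclass
class ReadRecord:
    """A single sequencing read.

    ``qualities`` is the Phred+33 ASCII string, same length as ``sequence``.
    ``umi`` is the extracted 10-nt random barcode, or ``None`` before
    extraction.
    """

    read_id: str
    sequence: str
    qualities: str
    umi: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if self.umi is not None and not _UMI_RE.match(self.umi):
            raise ValueError(f"read {self.read_id!r}: malformed UMI {self.umi!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """One read aligned to one reference.

    ``aligned_pairs`` lists ``(read_index, ref_index)`` tuples; either member
    may be ``None`` inside a gap.  For gapless alignments ``aligned_pairs``
    may be ``None``, in which case read base ``k`` of ``sequence`` pairs with
    reference position ``ref_start + k``.
    """

    read_id: str
    ref_id: str
    ref_start: int
    sequence: str
    aligned_pairs: Optional[list] = None
    n_mismatch: int = 0
    score: float = 0.0
    is_unique: bool = True
    umi: Optional[str] = None


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # mtime frozen so repeated runs are byte-identical
            raw = open(path, "wb")
            gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
            return _io.TextIOWrapper(gz, encoding="ascii", newline="\n")
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, mode, encoding="ascii", newline="\n" if "w" in mode else None)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from a (possibly gzipped) FASTQ file."""
    with _open_text(path, "rt") as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"FASTQ record {index}: {exc}") from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"FASTQ record {index}: sequence/quality length mismatch"
                )
            yield ReadRecord(read_id=title, sequence=seq, qualities=qual)
            index += 1


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    """Write reads as 4-line FASTQ (gzip if the path ends in .gz). Returns count."""
    n = 0
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{rec.qualities}\n")
            n += 1
    return n


def read_fasta(path) -> Iterator[tuple]:
    """Stream ``(id, sequence)`` pairs; sequences are uppercased."""
    with _open_text(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq).upper()


def write_fasta(records: Iterable[tuple], path, width: int = 60) -> int:
    n = 0
    with _open_text(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
            n += 1
    return n


def write_tsv(table: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Write a report table as TSV with ``#key=value`` metadata header lines."""
    with _open_text(path, "wt") as handle:
        for key in sorted(metadata or {}):
            handle.write(f"# {key}={(metadata or {})[key]}\n")
        table.to_csv(handle, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def records_to_frame(records: Iterable[AlignmentRecord]) -> pd.DataFrame:
    """Collect alignment records into the pipeline's alignment table.

    Columns: read_id, ref_id, ref_start (0-based), umi, seq (the read bases,
    aligned left-to-right), pairs (``None`` for gapless alignments, else the
    aligned-pairs list).
    """
    rows = []
    for rec in records:
        rows.append(
            (rec.read_id, rec.ref_id, rec.ref_start, rec.umi, rec.sequence, rec.aligned_pairs)
        )
    return pd.DataFrame(
        rows, columns=["read_id", "ref_id", "ref_start", "umi", "seq", "pairs"]
    )


def write_sam(records: Iterable[AlignmentRecord], refs, path) -> int:
    """Minimal unsorted SAM export (write-only): header with the tRNA refs,
    one gapless-or-gapped line per record with a CIGAR derived from the pairs."""
    ref_list = list(refs)
    n = 0
    with _open_text(path, "wt") as handle:
        handle.write("@HD\tVN:1.6\tSO:unsorted\n")
        for ref in ref_list:
            handle.write(f"@SQ\tSN:{ref.ref_id}\tLN:{len(ref.sequence)}\n")
        for rec in records:
            cigar = _cigar_from_pairs(rec)
            umi_tag = f"\tRX:Z:{rec.umi}" if rec.umi else ""
            handle.write(
                f"{rec.read_id}\t0\t{rec.ref_id}\t{rec.ref_start + 1}\t"
                f"{60 if rec.is_unique else 0}\t{cigar}\t*\t0\t0\t"
                f"{rec.sequence}\t*\tNM:i:{rec.n_mismatch}{umi_tag}\n"
            )
            n += 1
    return n


def _cigar_from_pairs(rec: AlignmentRecord) -> str:
    if rec.aligned_pairs is None:
        return f"{len(rec.sequence)}M"
    ops = []
    for read_i, ref_i in rec.aligned_pairs:
        if read_i is not None and ref_i is not None:
            op = "M"
        elif read_i is None:
            op = "D"
        else:
            op = "I"
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])
    return "".join(f"{count}{op}" for op, count in ops)


def read_sam(path) -> list:
    """Import external alignments (e.g. BWA-MEM) from a plain SAM file into
    :class:`AlignmentRecord` objects.  The UMI is taken from the RX tag when
    present, else from a trailing ``_UMI`` suffix on the read name."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            umi = None
            if aln.has_tag("RX"):
                umi = aln.get_tag("RX")
            elif "_" in aln.query_name:
                tail = aln.query_name.rsplit("_", 1)[1]
                if _UMI_RE.match(tail):
                    umi = tail
            pairs = [
                (q, r)
                for q, r in aln.get_aligned_pairs()
                if not (q is None and r is None)
            ]
            gapless = all(q is not None and r is not None for q, r in pairs)
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    ref_id=aln.reference_name,
                    ref_start=aln.reference_start,
                    sequence=aln.query_sequence or "",
                    aligned_pairs=None if gapless else pairs,
                    n_mismatch=int(nm),
                    score=float(aln.get_tag("AS")) if aln.has_tag("AS") else 0.0,
                    is_unique=(aln.mapping_quality or 0) > 0,
                    umi=umi,
                )
            )
    return records
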