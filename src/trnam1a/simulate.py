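"""Synthetic data generation for every stage of the pipeline.

The simulators emulate the study design end to end: a mature-tRNA reference
set (a synthetic stand-in for a genomic tRNA catalogue), paired tRNA-seq
libraries (an untreated arm in which m1A58 causes reverse-transcription
misincorporation, and a demethylase-treated arm in which that signal is
erased with configurable efficiency), codon-biased coding transcriptomes,
and ribosome-profiling / RNA-seq read placements with a fixed 5'-to-P-site
offset and 3-nt periodicity.  Every simulator is deterministic given its
seed and emits a machine-readable truth table so parameter recovery can be
scored exactly.

Library constants (10-nt random barcode, 3' adapter, RT primer, 150-nt
reads with read 2 analysed) default to the sequenced library design and are
overridable through :class:`LibraryDesign`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ReadRecord, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG"
    for b in "TCAG"
    for c in "TCAG"
    if a + b + c not in STOP_CODONS
)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def decode_codons(anticodon: str, rule: str = "wobble") -> frozenset:
    """Sense codons read by a tRNA with the given anticodon.

    ``rule='exact'`` gives only the Watson-Crick codon (the reverse
    complement of the anticodon).  ``rule='wobble'`` adds the standard
    wobble expansions at the codon third position, keyed on the anticodon
    5' base (position 34): G34 also reads codon-3' T, T34 also reads G,
    A34 (read as inosine) also reads T and C.
    """
    exact = revcomp(anticodon)
    codons = {exact}
    if rule == "wobble":
        first = anticodon[0]
        extra = {"G": ("T",), "T": ("G",), "A": ("T", "C"), "C": ()}[first]
        for third in extra:
            codons.add(exact[:2] + third)
    elif rule != "exact":
        raise ValueError(f"unknown wobble rule {rule!r}")
    return frozenset(c for c in codons if c not in STOP_CODONS)


@dataclass(frozen=True)
class TRNARef:
    """A mature tRNA reference sequence.

    ``a58_index`` is the 0-based offset of the adenosine standing for
    canonical position 58 (T-loop); it must hold an 'A' and lie in the 3'
    quarter of the molecule.  The sequence carries the mature 3'-CCA end.
    """

    ref_id: str
    sequence: str
    anticodon: str
    a58_index: int
    decoded_codons: frozenset

    def __post_init__(self):
        if self.sequence[self.a58_index] != "A":
            raise ValueError(f"{self.ref_id}: base at a58_index is not A")
        if not self.sequence.endswith("CCA"):
            raise ValueError(f"{self.ref_id}: sequence does not end in CCA")
        if self.a58_index < (3 * len(self.sequence)) // 4:
            raise ValueError(f"{self.ref_id}: a58_index outside the 3' quarter")


@dataclass
class LibraryDesign:
    """Constants of the sequencing library; defaults match the assayed design."""

    umi_length: int = 10
    adapter3: str = "AGATCGGAAGAGCGTCGTG"
    rt_primer: str = "ACACGACGCTCTTCCGATCT"
    read_length: int = 150
    analyzed_read: int = 2


@dataclass
class SimTruth:
    """Ground truth shared by the simulators.

    ``trna`` has columns ref_id, stoich_condA, stoich_condB (methylation
    fractions in [0, 1]); ``genes`` has gene_id, true_te_condA,
    true_te_condB, gene_class.  Scalars: demethylation efficiency of the
    in-vitro treatment, per-base sequencing error rate, mean extra PCR
    copies per molecule, and the master seed.
    """

    trna: pd.DataFrame
    genes: Optional[pd.DataFrame] = None
    demethylation_efficiency: float = 1.0
    sequencing_error_rate: float = 0.002
    pcr_duplication_mean: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for col in ("stoich_condA", "stoich_condB"):
            vals = self.trna[col].to_numpy(float)
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{col} outside [0, 1]")
        if not 0 <= self.demethylation_efficiency <= 1:
            raise ValueError("demethylation_efficiency outside [0, 1]")

    def stoichiometry(self, ref_id: str, condition: str) -> float:
        col = f"stoich_cond{condition}"
        row = self.trna.loc[self.trna["ref_id"] == ref_id, col]
        if row.empty:
            raise KeyError(f"no truth entry for {ref_id}")
        return float(row.iloc[0])


# Anticodon families; the first four are the differentially methylated
# tRNAs highlighted by the study design.
_FAMILIES = [
    ("Asp", "GTC"), ("Ala", "AGC"), ("Glu", "CTC"), ("Ser", "GCT"),
    ("Gly", "GCC"), ("Lys", "CTT"), ("Val", "CAC"), ("Leu", "AAG"),
    ("Phe", "GAA"), ("Met", "CAT"), ("His", "GTG"), ("Arg", "ACG"),
    ("Thr", "AGT"), ("Ile", "AAT"), ("Pro", "AGG"), ("Gln", "CTG"),
    ("Asn", "GTT"), ("Trp", "CCA"), ("Tyr", "GTA"), ("Cys", "GCA"),
    ("Ser", "AGA"), ("Ala", "TGC"), ("Glu", "TTC"), ("Gly", "TCC"),
    ("Leu", "CAA"), ("Val", "TAC"), ("Arg", "TCT"), ("Thr", "TGT"),
]


def make_trna_reference(
    n_families: int, seed: int, wobble_rule: str = "wobble"
) -> List[TRNARef]:
    """Generate ``n_families`` synthetic mature tRNA references.

    Sequences are random 76-84-mers with the anticodon placed at positions
    34-36 (1-based), an 'A' at the canonical-58 offset and a 3'-terminal
    CCA.  Deterministic given the seed.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    refs: List[TRNARef] = []
    copy_counts: Dict[str, int] = {}
    for i in range(n_families):
        aa, anticodon = _FAMILIES[i % len(_FAMILIES)]
        family = f"tRNA-{aa}-{anticodon}"
        copy_counts[family] = copy_counts.get(family, 0) + 1
        length = int(rng.integers(76, 85))
        body = rng.choice(list("ACGT"), size=length - 3).tolist()
        body[33:36] = list(anticodon)
        a58 = length - 19  # within the 3' quarter for length >= 76
        body += list("CCA")
        body[a58] = "A"
        refs.append(
            TRNARef(
                ref_id=f"{family}-{copy_counts[family]}",
                sequence="".join(body),
                anticodon=anticodon,
                a58_index=a58,
                decoded_codons=decode_codons(anticodon, wobble_rule),
            )
        )
    return refs


def write_reference_fasta(refs: Sequence[TRNARef], path) -> None:
    write_fasta(((r.ref_id, r.sequence) for r in refs), path)


@dataclass
class MoleculeBatch:
    """Raw simulated molecules for one library arm (internal intermediate).

    ``reads`` is the per-read base matrix split per tRNA (list of uint8
    arrays, one row per read after PCR expansion); companion arrays give
    the molecule index, UMI and modification state of each read.
    """

    refs: Sequence[TRNARef]
    per_ref_reads: list
    per_ref_mol: list
    per_ref_umi: list
    per_ref_modified: list
    condition: str
    arm: str


def _decode_rows(mat: np.ndarray) -> List[str]:
    chars = _BASES[mat]
    return [row.tobytes().decode("ascii") for row in chars]


def _simulate_molecules(
    refs: Sequence[TRNARef],
    truth: SimTruth,
    n_molecules: int,
    demethylated: bool,
    condition: str,
    seed: int,
    abundance: Optional[np.ndarray] = None,
    spectrum: Sequence[float] = (1 / 3, 1 / 3, 1 / 3),
    truncation_rate: float = 0.0,
    pcr_duplication_mean: Optional[float] = None,
) -> MoleculeBatch:
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    known = set(truth.trna["ref_id"])
    missing = [r.ref_id for r in refs if r.ref_id not in known]
    if missing:
        raise ValueError(f"truth table missing entries for: {missing}")
    rng = np.random.default_rng(seed)
    n_refs = len(refs)
    if abundance is None:
        abundance = np.full(n_refs, 1.0 / n_refs)
    abundance = np.asarray(abundance, float)
    abundance = abundance / abundance.sum()
    counts = rng.multinomial(n_molecules, abundance)
    dup_mean = (
        truth.pcr_duplication_mean if pcr_duplication_mean is None else pcr_duplication_mean
    )
    spectrum = np.asarray(spectrum, float)
    spectrum = spectrum / spectrum.sum()
    eff = truth.demethylation_efficiency if demethylated else 0.0
    arm = "demethylated" if demethylated else "untreated"

    per_ref_reads, per_ref_mol, per_ref_umi, per_ref_mod = [], [], [], []
    for ref, n_r in zip(refs, counts):
        stoich = truth.stoichiometry(ref.ref_id, condition)
        length = len(ref.sequence)
        seq_codes = _CODE[np.frombuffer(ref.sequence.encode(), dtype=np.uint8)]
        # modification draw first, from its own uniform stream: raising the
        # demethylation efficiency only lowers the threshold, so for a fixed
        # seed the set of surviving methyl marks shrinks monotonically.
        u = rng.random(n_r)
        modified = u < stoich * (1.0 - eff)
        mat = np.tile(seq_codes, (n_r, 1))
        n_mod = int(modified.sum())
        if n_mod:
            # misincorporation base at position 58: C/G/T by the spectrum
            non_a = np.array([1, 2, 3], dtype=np.uint8)  # C, G, T
            mat[modified, ref.a58_index] = rng.choice(non_a, size=n_mod, p=spectrum)
        umi_codes = rng.integers(0, 4, size=(n_r, 10), dtype=np.uint8)
        copies = 1 + rng.poisson(dup_mean, size=n_r)
        idx = np.repeat(np.arange(n_r), copies)
        reads = mat[idx]
        if truth.sequencing_error_rate > 0 and reads.size:
            err = rng.random(reads.shape) < truth.sequencing_error_rate
            shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
            reads = np.where(err, (reads + shift) % 4, reads)
        if truncation_rate > 0 and n_mod:
            # optional RT fall-off at the modified base: truncated reads end
            # at position 58 (handled downstream by masking trailing bases)
            trunc = (rng.random(len(idx)) < truncation_rate) & modified[idx]
            reads = reads.copy()
            reads[trunc, ref.a58_index + 1 :] = 255  # sentinel: absent base
        per_ref_reads.append(reads)
        per_ref_mol.append(idx)
        per_ref_umi.append(umi_codes)
        per_ref_mod.append(modified)
    return MoleculeBatch(refs, per_ref_reads, per_ref_mol, per_ref_umi, per_ref_mod,
                         condition, arm)


def _umi_strings(umi_codes: np.ndarray) -> List[str]:
    return _decode_rows(umi_codes)


def batch_truth_sidecar(batch: MoleculeBatch) -> pd.DataFrame:
    """Molecule-level truth: one row per source molecule with its
    modification state and barcode (traceability of every emitted read)."""
    frames = []
    for ref, mol_umi, modified in zip(batch.refs, batch.per_ref_umi, batch.per_ref_modified):
        umis = _umi_strings(mol_umi)
        frames.append(
            pd.DataFrame(
                {
                    "condition": batch.condition,
                    "arm": batch.arm,
                    "ref_id": ref.ref_id,
                    "molecule_id": np.arange(len(umis)),
                    "umi": umis,
                    "modified": modified,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_trna_alignments(
    refs: Sequence[TRNARef],
    truth: SimTruth,
    n_molecules: int,
    demethylated: bool,
    condition: str,
    seed: int,
    **kwargs,
):
    """Simulate a library arm directly as an alignment table.

    Skips the FASTQ round trip: each read is emitted already placed at its
    (known) reference of origin, full length from position 0.  Returns
    ``(alignment_frame, truth_sidecar)``; the frame has the same schema as
    :func:`trnam1a.io.records_to_frame` so it feeds straight into dedup and
    pileup.
    """
    batch = _simulate_molecules(refs, truth, n_molecules, demethylated, condition,
                                seed, **kwargs)
    frames = []
    for ref, reads, mol, umi_codes in zip(
        batch.refs, batch.per_ref_reads, batch.per_ref_mol, batch.per_ref_umi
    ):
        if not len(reads):
            continue
        umis = _umi_strings(umi_codes)
        seqs = _decode_rows(np.where(reads == 255, 0, reads))
        # truncated tail (sentinel 255) is trimmed off the string
        if (reads == 255).any():
            lens = (reads != 255).sum(axis=1)
            seqs = [s[:l] for s, l in zip(seqs, lens)]
        copy_ord = np.arange(len(mol))
        frames.append(
            pd.DataFrame(
                {
                    "read_id": [
                        f"{batch.condition}-{batch.arm}-{ref.ref_id}-m{m}-c{c}"
                        for m, c in zip(mol, copy_ord)
                    ],
                    "ref_id": ref.ref_id,
                    "ref_start": 0,
                    "umi": [umis[m] for m in mol],
                    "seq": seqs,
                    "pairs": None,
                }
            )
        )
    aln = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["read_id", "ref_id", "ref_start", "umi", "seq", "pairs"]
    )
    return aln, batch_truth_sidecar(batch)


def simulate_trna_library(
    refs: Sequence[TRNARef],
    truth: SimTruth,
    n_molecules: int,
    demethylated: bool,
    condition: str,
    seed: int,
    design: Optional[LibraryDesign] = None,
    **kwargs,
):
    """Simulate one library arm as raw reads (the analysed read 2 layout).

    Each read is ``UMI (10 nt) + cDNA insert + 3' adapter``, padded with
    'A' / truncated to the design read length, all bases Q40.  Returns
    ``(list of ReadRecord, truth_sidecar)``.
    """
    design = design or LibraryDesign()
    batch = _simulate_molecules(refs, truth, n_molecules, demethylated, condition,
                                seed, **kwargs)
    reads_out: List[ReadRecord] = []
    for ref, reads, mol, umi_codes in zip(
        batch.refs, batch.per_ref_reads, batch.per_ref_mol, batch.per_ref_umi
    ):
        umis = _umi_strings(umi_codes)
        seqs = _decode_rows(np.where(reads == 255, 0, reads))
        if (reads == 255).any():
            lens = (reads != 255).sum(axis=1)
            seqs = [s[:l] for s, l in zip(seqs, lens)]
        for c, (m, insert) in enumerate(zip(mol, seqs)):
            full = umis[m] + insert + design.adapter3
            if len(full) < design.read_length:
                full = full + "A" * (design.read_length - len(full))
            full = full[: design.read_length]
            reads_out.append(
                ReadRecord(
                    read_id=f"{batch.condition}-{batch.arm}-{ref.ref_id}-m{m}-c{c}",
                    sequence=full,
                    qualities="I" * len(full),
                )
            )
    return reads_out, batch_truth_sidecar(batch)


@dataclass(frozen=True)
class Transcript:
    """A synthetic mRNA: 5' UTR + CDS + 3' UTR, with the CDS span recorded
    as a 0-based half-open interval on the transcript."""

    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int
    gene_class: str

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


def uniform_codon_bias() -> Dict[str, float]:
    return {c: 1.0 for c in SENSE_CODONS}


def shifted_codon_bias(target_codons: Sequence[str], shift: float) -> Dict[str, float]:
    """Uniform sense-codon weights with ``shift`` extra absolute frequency
    spread over the target codons (codons drawn i.i.d., so expected codon
    frequency equals its normalised weight)."""
    base = 1.0 / len(SENSE_CODONS)
    weights = {c: base for c in SENSE_CODONS}
    extra = shift / len(target_codons)
    for c in target_codons:
        weights[c] += extra
    scale = sum(weights.values())
    return {c: w / scale for c, w in weights.items()}


def make_transcriptome(
    n_genes: int,
    codon_bias: Optional[Dict[str, Dict[str, float]]] = None,
    seed: int = 0,
    target_fraction: float = 0.1,
    n_codons_range: tuple = (100, 300),
    utr_length: int = 30,
) -> List[Transcript]:
    """Generate a two-class coding transcriptome.

    ``codon_bias`` maps gene class -> codon weights; the default gives a
    'background' class with uniform sense-codon usage and a
    'target-codon-rich' class with a +0.03 absolute AGC+GAG frequency
    shift.  Internal codons are drawn i.i.d. from the class weights; every
    CDS is ATG ... TAA in frame, flanked by random UTRs.
    """
    if codon_bias is None:
        codon_bias = {
            "background": uniform_codon_bias(),
            "target-codon-rich": shifted_codon_bias(("AGC", "GAG"), 0.03),
        }
    for cls, weights in codon_bias.items():
        vals = np.array([weights.get(c, 0.0) for c in SENSE_CODONS], float)
        if (vals < 0).any():
            raise ValueError(f"negative codon weight in class {cls!r}")
        if vals.sum() <= 0:
            raise ValueError(f"all-zero codon weights in class {cls!r}")
    rng = np.random.default_rng(seed)
    classes = sorted(codon_bias)
    n_target = int(round(n_genes * target_fraction)) if len(classes) > 1 else 0
    out: List[Transcript] = []
    for g in range(n_genes):
        cls = classes[-1] if (len(classes) > 1 and g < n_target) else classes[0]
        weights = np.array([codon_bias[cls].get(c, 0.0) for c in SENSE_CODONS], float)
        weights = weights / weights.sum()
        n_codons = int(rng.integers(n_codons_range[0], n_codons_range[1] + 1))
        body = rng.choice(len(SENSE_CODONS), size=n_codons, p=weights)
        cds = "ATG" + "".join(SENSE_CODONS[k] for k in body) + "TAA"
        utr5 = "".join(rng.choice(list("ACGT"), size=utr_length))
        utr3 = "".join(rng.choice(list("ACGT"), size=utr_length))
        out.append(
            Transcript(
                gene_id=f"gene{g:04d}",
                sequence=utr5 + cds + utr3,
                cds_start=utr_length,
                cds_end=utr_length + len(cds),
                gene_class=cls,
            )
        )
    return out


def transcriptome_sidecar(transcripts: Sequence[Transcript]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in transcripts],
            "gene_class": [t.gene_class for t in transcripts],
            "cds_start": [t.cds_start for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
            "cds_length": [t.cds_end - t.cds_start for t in transcripts],
        }
    )


# footprint length distribution: concentrated on 28-32 nt within 25-33
DEFAULT_FOOTPRINT_LENGTHS = np.arange(25, 34)
DEFAULT_FOOTPRINT_PROBS = np.array(
    [0.01, 0.02, 0.05, 0.17, 0.25, 0.25, 0.15, 0.07, 0.03]
)


def simulate_ribo_rna(
    transcripts: Sequence[Transcript],
    truth: SimTruth,
    depth: int,
    seed: int,
    condition: str = "A",
    jitter: int = 0,
    offset: int = 12,
    init_peak_fraction: float = 0.1,
    length_probs: Optional[np.ndarray] = None,
    rna_depth: Optional[int] = None,
):
    """Simulate ribosome footprints and matched RNA-seq placements.

    Footprint counts per gene are proportional to abundance x true TE x CDS
    codon count; RNA counts to abundance x transcript length (uniform
    fragment start).  Each footprint's 5' end sits ``offset`` nt upstream of
    an in-frame P-site codon, with ``init_peak_fraction`` of footprints at
    the start codon (the initiation pile-up used for offset QC) and optional
    symmetric positional jitter of up to ``jitter`` nt.  Returns
    ``(ribo_positions, rna_positions, sidecar)`` DataFrames; positions carry
    transcript_id, five_prime (0-based) and length.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if truth.genes is None:
        raise ValueError("truth.genes is required")
    te_col = f"true_te_cond{condition}"
    te = truth.genes.set_index("gene_id")[te_col]
    if (te <= 0).any():
        raise ValueError("true TE must be positive for all transcripts")
    rng = np.random.default_rng(seed)
    rna_depth = depth if rna_depth is None else rna_depth
    probs = DEFAULT_FOOTPRINT_PROBS if length_probs is None else np.asarray(length_probs, float)
    probs = probs / probs.sum()

    n_codons = np.array([(t.cds_end - t.cds_start) // 3 - 2 for t in transcripts])
    abundance = np.ones(len(transcripts))
    if "abundance" in truth.genes.columns:
        abundance = truth.genes.set_index("gene_id").loc[
            [t.gene_id for t in transcripts], "abundance"
        ].to_numpy(float)
    te_vec = te.loc[[t.gene_id for t in transcripts]].to_numpy(float)

    ribo_w = abundance * te_vec * n_codons
    rna_w = abundance * np.array([len(t.sequence) for t in transcripts], float)
    ribo_counts = rng.multinomial(depth, ribo_w / ribo_w.sum())
    rna_counts = rng.multinomial(rna_depth, rna_w / rna_w.sum())

    ribo_rows, rna_rows = [], []
    for t, nc, n_fp, n_rna in zip(transcripts, n_codons, ribo_counts, rna_counts):
        if n_fp:
            at_init = rng.random(n_fp) < init_peak_fraction
            codon = np.where(
                at_init, 0, rng.integers(0, nc + 1, size=n_fp)
            )  # codon 0 is the start codon; elongating ribosomes uniform
            five = t.cds_start + 3 * codon - offset
            if jitter > 0:
                # symmetric jitter peaked at 0 (binomial weights), so the
                # offset distribution keeps its mode at the true offset
                shifts = np.arange(-jitter, jitter + 1)
                w = np.array([comb(2 * jitter, jitter + s) for s in shifts], float)
                five = five + rng.choice(shifts, size=n_fp, p=w / w.sum())
            lengths = rng.choice(DEFAULT_FOOTPRINT_LENGTHS, size=n_fp, p=probs)
            keep = (five >= 0) & (five + lengths <= len(t.sequence))
            ribo_rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": t.gene_id,
                        "five_prime": five[keep],
                        "length": lengths[keep],
                    }
                )
            )
        if n_rna:
            max_start = max(len(t.sequence) - 30, 1)
            starts = rng.integers(0, max_start, size=n_rna)
            rna_rows.append(
                pd.DataFrame(
                    {
                        "transcript_id": t.gene_id,
                        "five_prime": starts,
                        "length": 30,
                    }
                )
            )
    empty = pd.DataFrame(columns=["transcript_id", "five_prime", "length"])
    ribo = pd.concat(ribo_rows, ignore_index=True) if ribo_rows else empty.copy()
    rna = pd.concat(rna_rows, ignore_index=True) if rna_rows else empty.copy()
    sidecar = truth.genes.copy()
    sidecar["expected_te"] = sidecar[te_col]
    return ribo, rna, sidecar


def positions_to_reads(positions: pd.DataFrame, transcripts: Sequence[Transcript],
                       prefix: str = "fp") -> List[ReadRecord]:
    """Materialise placements as actual reads (Q40) for the FASTQ route."""
    seqs = {t.gene_id: t.sequence for t in transcripts}
    out = []
    for i, row in enumerate(positions.itertuples(index=False)):
        s = seqs[row.transcript_id][row.five_prime : row.five_prime + row.length]
        out.append(ReadRecord(f"{prefix}-{i}-{row.transcript_id}", s, "I" * len(s)))
    return out


def gene_truth(transcripts: Sequence[Transcript], te_up_fold: float = 16.0) -> pd.DataFrame:
    """Per-gene true TE table: target-class genes gain ``te_up_fold`` in
    condition B.  The fold is large relative to the 4x classification
    threshold because RPKM-ratio TE is compositional: shifting footprint
    mass onto the target class deflates every estimated fold change by the
    overall scale (1 + (fold-1) * target fraction)."""
    te_a = np.ones(len(transcripts))
    te_b = np.array(
        [te_up_fold if t.gene_class == "target-codon-rich" else 1.0 for t in transcripts]
    )
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in transcripts],
            "gene_class": [t.gene_class for t in transcripts],
            "true_te_condA": te_a,
            "true_te_condB": te_b,
        }
    )


def default_truth(
    refs: Sequence[TRNARef],
    transcripts: Optional[Sequence[Transcript]] = None,
    seed: int = 0,
    n_elevated: int = 4,
    elevated_delta: float = 0.25,
    stoich_levels: Sequence[float] = (0.0, 0.2, 0.5, 0.9),
    te_up_fold: float = 16.0,
    demethylation_efficiency: float = 1.0,
    sequencing_error_rate: float = 0.002,
    pcr_duplication_mean: float = 1.0,
) -> SimTruth:
    """Build a study-like truth table: stoichiometries cycle through the
    given levels in condition A; the first ``n_elevated`` tRNAs with a
    medium level gain ``elevated_delta`` in condition B (high- and
    zero-methylation tRNAs stay put); target-class genes get a TE
    up-shift in condition B."""
    ref_ids = [r.ref_id for r in refs]
    stoich_a = np.array([stoich_levels[i % len(stoich_levels)] for i in range(len(refs))])
    stoich_b = stoich_a.copy()
    elevated = 0
    for i, s in enumerate(stoich_a):
        if 0.1 <= s <= 0.6 and elevated < n_elevated:
            stoich_b[i] = min(s + elevated_delta, 1.0)
            elevated += 1
    trna = pd.DataFrame(
        {
            "ref_id": ref_ids,
            "stoich_condA": stoich_a,
            "stoich_condB": stoich_b,
            "elevated_in_B": stoich_b > stoich_a,
        }
    )
    genes = gene_truth(transcripts, te_up_fold) if transcripts is not None else None
    return SimTruth(
        trna=trna,
        genes=genes,
        demethylation_efficiency=demethylation_efficiency,
        sequencing_error_rate=sequencing_error_rate,
        pcr_duplication_mean=pcr_duplication_mean,
        seed=seed,
    )
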