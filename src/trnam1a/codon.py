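"""Codon composition analysis linking hypermethylated tRNAs to translation.

A transcript's codon profile counts internal sense codons (start and stop
excluded by default).  Transcriptome-wide enrichment of a codon in one
transcript is expressed as a rank percentile ("top X%" under a
strict-greater convention).  The link from differentially methylated
tRNAs to codons goes through the anticodon: each elevated tRNA contributes
its decoded codons (narrow Watson-Crick mapping by default, wobble
configurable).  Whether those codons are over-represented in
translationally upregulated genes is tested with a label-permutation test
on the mean summed target-codon frequency.  Dual-luciferase reporter
normalisation (F-luc/R-luc against a no-insert control) is included as
the arithmetic counterpart of the reporter experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .simulate import SENSE_CODONS, STOP_CODONS, Transcript, decode_codons


@dataclass
class CodonProfile:
    """Counts and frequencies over the 61 sense codons for one CDS."""

    transcript_id: str
    counts: Dict[str, int]
    n_internal_stops: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> Dict[str, float]:
        total = self.total
        return {c: n / total for c, n in self.counts.items()}

    def frequency(self, codon: str) -> float:
        return self.counts.get(codon, 0) / self.total


def codon_frequencies(
    cds: str, transcript_id: str = "", include_start: bool = False
) -> CodonProfile:
    """Codon profile of an in-frame CDS.

    Counts codons between the start and stop codon (the start is included
    only with ``include_start``); the terminal stop is never counted.
    Internal stops are counted in ``n_internal_stops`` and flagged, not
    raised.
    """
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    codons = [cds[i : i + 3].upper() for i in range(0, len(cds), 3)]
    first = 0 if include_start else 1
    internal = codons[first : len(codons) - 1]
    if not internal:
        raise ValueError("CDS has no internal codons to count")
    counts: Dict[str, int] = {}
    n_stops = 0
    for codon in internal:
        if codon in STOP_CODONS:
            n_stops += 1
            continue
        counts[codon] = counts.get(codon, 0) + 1
    if not counts:
        raise ValueError("CDS has no internal sense codons")
    return CodonProfile(transcript_id=transcript_id, counts=counts,
                        n_internal_stops=n_stops)


def profile_transcriptome(
    transcripts: Sequence[Transcript], include_start: bool = False
) -> Dict[str, CodonProfile]:
    return {
        t.gene_id: codon_frequencies(t.cds, t.gene_id, include_start)
        for t in transcripts
    }


def codon_rank_percentile(
    transcript_id: str, codon: str, profiles: Dict[str, CodonProfile]
) -> float:
    """Fraction of transcripts with strictly greater frequency of ``codon``.

    A value of 0.035 means the query is in the "top 3.5%" for that codon;
    ties rank equally (strict-greater convention).
    """
    if transcript_id not in profiles:
        raise ValueError(f"unknown transcript {transcript_id!r}")
    if codon not in SENSE_CODONS:
        raise ValueError(f"{codon!r} is not a sense codon")
    if len(profiles) < 2:
        raise ValueError("need at least 2 transcripts to rank")
    query = profiles[transcript_id].frequency(codon)
    greater = sum(1 for p in profiles.values() if p.frequency(codon) > query)
    return greater / len(profiles)


def summed_target_frequency(
    profiles: Dict[str, CodonProfile], ids: Sequence[str], target_codons: Iterable[str]
) -> np.ndarray:
    targets = list(target_codons)
    return np.array(
        [sum(profiles[i].frequency(c) for c in targets) for i in ids], float
    )


def te_codon_enrichment(
    te_up_ids: Sequence[str],
    background_ids: Sequence[str],
    target_codons: Iterable[str],
    profiles: Dict[str, CodonProfile],
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Permutation test for target-codon enrichment in TE-up genes.

    Statistic: mean summed target-codon frequency in the TE-up set minus
    the background set.  The p-value is one-sided with the add-one rule,
    ``(1 + #{permuted >= observed}) / (n_perm + 1)``, permuting set labels.
    """
    up = list(te_up_ids)
    bg = list(background_ids)
    if not up or not bg:
        raise ValueError("both gene sets must be non-empty")
    if set(up) & set(bg):
        raise ValueError("gene sets must be disjoint")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = summed_target_frequency(profiles, up + bg, target_codons)
    n_up = len(up)
    observed = values[:n_up].mean() - values[n_up:].mean()
    rng = np.random.default_rng(seed)
    # vectorised label permutations: each row is a shuffled assignment
    perm = np.argsort(rng.random((n_perm, len(values))), axis=1)
    shuffled = values[perm]
    stats = shuffled[:, :n_up].mean(axis=1) - shuffled[:, n_up:].mean(axis=1)
    p = (1 + int((stats >= observed).sum())) / (n_perm + 1)
    return float(observed), float(p)


def linked_codons(
    diff: pd.DataFrame,
    refs=None,
    wobble_rule: str = "exact",
) -> Set[str]:
    """Codons decoded by tRNAs elevated in condition B.

    With ``refs`` (TRNARef objects) the per-tRNA decoded-codon sets are
    used; otherwise the anticodon is parsed from the ref_id
    (family-anticodon-copy) and decoded with ``wobble_rule`` (narrow
    Watson-Crick by default).
    """
    elevated = diff.loc[diff["elevated_in_B"], "ref_id"]
    codons: Set[str] = set()
    by_id = {r.ref_id: r for r in refs} if refs is not None else {}
    for ref_id in elevated:
        if ref_id in by_id:
            codons |= set(by_id[ref_id].decoded_codons)
        else:
            anticodon = ref_id.split("-")[2]
            codons |= set(decode_codons(anticodon, wobble_rule))
    return codons


@dataclass
class ReporterMeasurement:
    """One dual-luciferase well: firefly (test) and renilla (transfection
    control) luminescence, for a codon-insert or no-insert construct."""

    f_luc: float
    r_luc: float
    construct: str = "codon-insert"
    condition: str = ""

    def __post_init__(self):
        if self.r_luc <= 0:
            raise ValueError("r_luc must be positive")

    @property
    def ratio(self) -> float:
        return self.f_luc / self.r_luc


def normalize_reporter(
    test: ReporterMeasurement, control: ReporterMeasurement
) -> float:
    """Translation index: (test F/R) / (control F/R).

    The renilla ratio removes transfection-level differences; dividing by
    the no-insert control removes the inherent translation difference
    between conditions.
    """
    if control.ratio == 0:
        raise ValueError("control F/R ratio is zero")
    return test.ratio / control.ratio
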