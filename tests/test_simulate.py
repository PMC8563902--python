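import io

import numpy as np
import pandas as pd
import pytest

from trnam1a.codon import codon_frequencies
from trnam1a.simulate import (
    SENSE_CODONS,
    SimTruth,
    decode_codons,
    default_truth,
    make_transcriptome,
    make_trna_reference,
    shifted_codon_bias,
    simulate_ribo_rna,
    simulate_trna_alignments,
    simulate_trna_library,
    uniform_codon_bias,
    write_reference_fasta,
)


class TestTRNAReference:
    def test_invariants_hold_for_every_reference(self, refs20):
        assert len({r.ref_id for r in refs20}) == 20
        for r in refs20:
            assert r.sequence[r.a58_index] == "A"
            assert r.sequence.endswith("CCA")
            assert r.a58_index >= (3 * len(r.sequence)) // 4
            assert 70 <= len(r.sequence) <= 95
            assert r.sequence[33:36] == r.anticodon

    def test_named_families_present(self, refs20):
        ids = {r.ref_id for r in refs20}
        for fam in ("tRNA-Asp-GTC-1", "tRNA-Ala-AGC-1", "tRNA-Glu-CTC-1", "tRNA-Ser-GCT-1"):
            assert fam in ids

    def test_fasta_output_deterministic(self, tmp_path):
        for name in ("a.fa", "b.fa"):
            write_reference_fasta(make_trna_reference(4, seed=7), tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_rejects_zero_families(self):
        with pytest.raises(ValueError):
            make_trna_reference(0, seed=1)

    def test_wobble_decoding(self):
        assert decode_codons("AGC", "exact") == frozenset({"GCT"})
        assert decode_codons("AGC", "wobble") == frozenset({"GCT", "GCC"})
        assert decode_codons("CTC", "wobble") == frozenset({"GAG"})


class TestTRNALibrary:
    def test_zero_stoichiometry_zero_error_gives_no_signal(self, refs20):
        truth = SimTruth(
            trna=pd.DataFrame(
                {"ref_id": [r.ref_id for r in refs20],
                 "stoich_condA": 0.0, "stoich_condB": 0.0}
            ),
            sequencing_error_rate=0.0,
        )
        aln, sidecar = simulate_trna_alignments(refs20, truth, 2000, False, "A", seed=5)
        by_id = {r.ref_id: r for r in refs20}
        for row in aln.itertuples(index=False):
            ref = by_id[row.ref_id]
            assert row.seq[ref.a58_index] == "A"
        assert not sidecar["modified"].any()

    def test_complete_demethylation_erases_signal(self, refs20):
        truth = SimTruth(
            trna=pd.DataFrame(
                {"ref_id": [r.ref_id for r in refs20],
                 "stoich_condA": 1.0, "stoich_condB": 1.0}
            ),
            demethylation_efficiency=1.0,
            sequencing_error_rate=0.0,
        )
        aln, sidecar = simulate_trna_alignments(refs20, truth, 2000, True, "A", seed=5)
        by_id = {r.ref_id: r for r in refs20}
        assert not sidecar["modified"].any()
        assert all(
            row.seq[by_id[row.ref_id].a58_index] == "A"
            for row in aln.itertuples(index=False)
        )

    def test_modified_fraction_matches_binomial_bound(self, refs20):
        # direct count of modified molecules in the sidecar, not via pileup
        truth = SimTruth(
            trna=pd.DataFrame(
                {"ref_id": [r.ref_id for r in refs20],
                 "stoich_condA": 0.5, "stoich_condB": 0.5}
            ),
            sequencing_error_rate=0.002,
        )
        n = 2000 * len(refs20)
        _, sidecar = simulate_trna_alignments(refs20, truth, n, False, "A", seed=11)
        frac = sidecar["modified"].mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_demethylation_monotone_in_efficiency(self, refs20):
        base = pd.DataFrame(
            {"ref_id": [r.ref_id for r in refs20],
             "stoich_condA": 0.6, "stoich_condB": 0.6}
        )
        counts = []
        for eff in (0.0, 0.3, 0.7, 1.0):
            truth = SimTruth(trna=base, demethylation_efficiency=eff)
            _, sidecar = simulate_trna_alignments(refs20, truth, 3000, True, "A", seed=21)
            counts.append(int(sidecar["modified"].sum()))
        assert counts == sorted(counts, reverse=True)

    def test_missing_truth_entry_rejected(self, refs20):
        truth = SimTruth(
            trna=pd.DataFrame(
                {"ref_id": [r.ref_id for r in refs20[:10]],
                 "stoich_condA": 0.5, "stoich_condB": 0.5}
            )
        )
        with pytest.raises(ValueError, match="missing"):
            simulate_trna_alignments(refs20, truth, 100, False, "A", seed=1)

    def test_read_layout_and_determinism(self, refs4):
        truth = default_truth(refs4, seed=7)
        reads1, _ = simulate_trna_library(refs4, truth, 100, False, "A", seed=9)
        reads2, _ = simulate_trna_library(refs4, truth, 100, False, "A", seed=9)
        assert [r.sequence for r in reads1] == [r.sequence for r in reads2]
        assert all(len(r) == 150 for r in reads1)
        # barcode + insert + adapter layout
        assert any("AGATCGGAAGAGCGTCGTG" in r.sequence for r in reads1)


class TestTranscriptome:
    def test_degenerate_bias_forces_single_codon(self):
        bias = {"only": {"GCT": 1.0}}
        ts = make_transcriptome(5, codon_bias=bias, seed=2)
        for t in ts:
            prof = codon_frequencies(t.cds)
            assert prof.frequencies == {"GCT": 1.0}

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            make_transcriptome(5, codon_bias={"bad": {c: 0.0 for c in SENSE_CODONS}}, seed=2)

    def test_deterministic(self):
        a = make_transcriptome(50, seed=3)
        b = make_transcriptome(50, seed=3)
        assert [t.sequence for t in a] == [t.sequence for t in b]

    def test_target_class_enriched_in_target_codons(self):
        bias = {
            "background": uniform_codon_bias(),
            "target-codon-rich": {
                c: (3.0 if c == "AGC" else 1.0) for c in SENSE_CODONS
            },
        }
        ts = make_transcriptome(200, codon_bias=bias, seed=4, target_fraction=0.3)
        freq = {
            cls: np.mean(
                [codon_frequencies(t.cds).frequency("AGC") for t in ts if t.gene_class == cls]
            )
            for cls in ("target-codon-rich", "background")
        }
        assert freq["target-codon-rich"] > freq["background"]

    def test_cds_structure(self, transcriptome100):
        for t in transcriptome100:
            cds = t.cds
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG") and cds.endswith("TAA")


class TestRiboSim:
    def _truth(self, transcripts):
        return default_truth(make_trna_reference(4, seed=1), transcripts, seed=1)

    def test_zero_jitter_places_all_ends_at_offset_12(self, transcriptome100):
        truth = self._truth(transcriptome100)
        ribo, _, _ = simulate_ribo_rna(transcriptome100, truth, 20000, seed=5, jitter=0)
        starts = {t.gene_id: t.cds_start for t in transcriptome100}
        rel = ribo["five_prime"].to_numpy() + 12 - ribo["transcript_id"].map(starts).to_numpy()
        assert (rel % 3 == 0).all()
        assert (rel >= 0).all()

    def test_length_histogram_mode_in_28_32(self, transcriptome100):
        truth = self._truth(transcriptome100)
        ribo, _, _ = simulate_ribo_rna(transcriptome100, truth, 20000, seed=6)
        mode = ribo["length"].value_counts().idxmax()
        assert 28 <= mode <= 32
        assert ribo["length"].between(25, 33).all()

    def test_depth_validation(self, transcriptome100):
        truth = self._truth(transcriptome100)
        with pytest.raises(ValueError):
            simulate_ribo_rna(transcriptome100, truth, 0, seed=1)
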