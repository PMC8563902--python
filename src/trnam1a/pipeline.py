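"""End-to-end orchestration: simulate -> preprocess -> align -> quantify ->
translation efficiency -> codon enrichment, with a reproducible report
bundle.

Every stage's parameters are serialised into the run manifest and the
config hash is embedded in each report header, so identical config + seed
reproduce the bundle byte for byte.  Per-stage read accounting goes to
``qc.json``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import __version__
from .align import AlignParams, align_reads
from .codon import linked_codons, profile_transcriptome, te_codon_enrichment
from .io import read_fasta, records_to_frame, write_fastq, write_tsv
from .preprocess import PreprocessConfig, preprocess_reads
from .quant import CallConfig, M1AStoichiometryModel, dedup, pileup, position_mismatch_table
from .ribo import TranslationEfficiencyModel, build_profiles, length_histogram, p_site_offset, periodicity
from .simulate import (
    TRNARef,
    decode_codons,
    default_truth,
    gene_truth,
    make_transcriptome,
    make_trna_reference,
    shifted_codon_bias,
    simulate_ribo_rna,
    simulate_trna_library,
    uniform_codon_bias,
    write_reference_fasta,
)


class ConfigError(ValueError):
    pass


def demo_config() -> Dict:
    """A small self-contained configuration that completes in well under a
    minute on one CPU: 4 tRNA families at ~110x deduplicated coverage,
    60 genes, 30k footprint placements."""
    return {
        "seed": 1,
        "n_trna_families": 4,
        "n_molecules": 450,
        "demethylation_efficiency": 1.0,
        "sequencing_error_rate": 0.002,
        "pcr_duplication_mean": 1.0,
        "n_genes": 60,
        "ribo_depth": 30000,
        "n_perm": 500,
        "min_coverage": 50,
        "delta_min": 0.05,
        "elevation_min": 0.05,
        "fc_threshold": 4.0,
        "target_codons": "auto",
        "trna_reference_fasta": None,
    }


def _config_hash(config: Dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def load_trna_reference(fasta_path, a58_annotations=None) -> list:
    """Load tRNA references from FASTA.

    ``a58_annotations`` is an optional TSV (ref_id, a58_index 0-based,
    anticodon); without it the anticodon is parsed from the id
    (family-anticodon-copy) and position 58 is taken 19 nt upstream of the
    3' end (the CCA-anchored default of the synthetic references).
    """
    ann = {}
    if a58_annotations is not None:
        table = pd.read_csv(a58_annotations, sep="\t", comment="#")
        ann = {
            row.ref_id: (int(row.a58_index), row.anticodon)
            for row in table.itertuples(index=False)
        }
    refs = []
    for ref_id, seq in read_fasta(fasta_path):
        if ref_id in ann:
            a58, anticodon = ann[ref_id]
        else:
            a58 = len(seq) - 19
            parts = ref_id.split("-")
            anticodon = parts[2] if len(parts) >= 3 else "NNN"
        refs.append(
            TRNARef(
                ref_id=ref_id,
                sequence=seq,
                anticodon=anticodon,
                a58_index=a58,
                decoded_codons=decode_codons(anticodon) if set(anticodon) <= set("ACGT") else frozenset(),
            )
        )
    return refs


def run_all(config: Optional[Dict] = None, outdir="run") -> Dict:
    """Run the full pipeline and write the report bundle.

    Produces calls_A.tsv / calls_B.tsv, diff.tsv, mismatch_positions TSVs,
    te.tsv, enrichment.tsv, qc.json and manifest.json under ``outdir``.
    Returns a dict with the in-memory results and output paths.
    """
    cfg = demo_config()
    cfg.update(config or {})
    unknown = set(cfg) - set(demo_config())
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    seed = int(cfg["seed"])
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    meta = {"config_hash": chash, "version": __version__, "seed": seed}
    qc: Dict = {"config_hash": chash}

    # --- references -----------------------------------------------------
    if cfg["trna_reference_fasta"]:
        path = Path(cfg["trna_reference_fasta"])
        if not path.exists():
            raise ConfigError(f"trna_reference_fasta: no such file: {path}")
        refs = load_trna_reference(path)
    else:
        refs = make_trna_reference(cfg["n_trna_families"], seed)
    write_reference_fasta(refs, out / "trna_ref.fa")

    truth = default_truth(
        refs,
        seed=seed,
        demethylation_efficiency=cfg["demethylation_efficiency"],
        sequencing_error_rate=cfg["sequencing_error_rate"],
        pcr_duplication_mean=cfg["pcr_duplication_mean"],
    )
    # the transcriptome's enriched codons are the ones decoded by the
    # truly elevated tRNAs, so the downstream enrichment link is real
    by_id = {r.ref_id: r for r in refs}
    true_targets = sorted(
        set().union(
            *(
                by_id[rid].decoded_codons
                for rid in truth.trna.loc[truth.trna["elevated_in_B"], "ref_id"]
            )
        )
    ) or ["AGC", "GAG"]
    transcripts = make_transcriptome(
        cfg["n_genes"],
        codon_bias={
            "background": uniform_codon_bias(),
            "target-codon-rich": shifted_codon_bias(true_targets, 0.03),
        },
        seed=seed + 101,
    )
    truth.genes = gene_truth(transcripts)
    write_tsv(truth.trna, out / "truth_trna.tsv", metadata=meta)

    # --- tRNA m1A-seq arms ---------------------------------------------
    call_cfg = CallConfig(
        min_coverage=cfg["min_coverage"],
        delta_min=cfg["delta_min"],
        elevation_min=cfg["elevation_min"],
    )
    pre_cfg = PreprocessConfig()
    aln_params = AlignParams()
    pileups = {}
    stage = 0
    for condition in ("A", "B"):
        for arm, demethylated in (("untreated", False), ("demethylated", True)):
            stage += 1
            reads, _ = simulate_trna_library(
                refs, truth, cfg["n_molecules"], demethylated, condition,
                seed=(seed * 1000 + stage) % (2**31),
            )
            fq = out / f"trna_{condition}_{arm}.fastq.gz"
            write_fastq(reads, fq)
            processed, pre_stats = preprocess_reads(reads, pre_cfg)
            records, aln_stats = align_reads(processed, refs, aln_params)
            frame = records_to_frame(records)
            deduped = dedup(frame)
            pileups[(condition, arm)] = pileup(deduped, refs)
            qc[f"trna_{condition}_{arm}"] = {
                "preprocess": pre_stats,
                "align": aln_stats,
                "dedup": {"input": int(len(frame)), "retained": int(len(deduped))},
            }

    results = {}
    calls = {}
    for condition in ("A", "B"):
        model = M1AStoichiometryModel(
            pileups[(condition, "untreated")], pileups[(condition, "demethylated")],
            refs, call_cfg,
        )
        res = model.fit()
        calls[condition] = res
        write_tsv(res.calls, out / f"calls_{condition}.tsv", metadata=meta)
        write_tsv(
            position_mismatch_table(pileups[(condition, "untreated")]),
            out / f"mismatch_positions_{condition}_untreated.tsv",
            metadata=meta,
        )
    diff = calls["A"].compare(calls["B"])
    write_tsv(diff, out / "diff.tsv", metadata=meta)
    results["m1a"] = calls
    results["diff"] = diff

    # --- Ribo-seq / RNA-seq ---------------------------------------------
    te_results = {}
    for k, condition in enumerate(("A", "B")):
        ribo_pos, rna_pos, _ = simulate_ribo_rna(
            transcripts, truth, cfg["ribo_depth"],
            seed=(seed * 1000 + 50 + k) % (2**31), condition=condition,
        )
        if condition == "A":
            profiles = build_profiles(ribo_pos, transcripts)
            offset = p_site_offset(profiles, transcripts)
            qc["p_site_offset"] = offset
            qc["frame0_fraction"] = periodicity(profiles)
            qc["footprint_length_histogram"] = {
                int(k): int(v) for k, v in length_histogram(profiles).items()
            }
        te_results[condition] = TranslationEfficiencyModel.from_positions(
            ribo_pos, rna_pos, transcripts
        ).fit()
    te_diff = te_results["A"].compare(te_results["B"], cfg["fc_threshold"])
    merged = te_diff.merge(
        te_results["B"].table[["transcript_id", "rpkm_ribo", "rpkm_rna"]],
        on="transcript_id",
    )
    write_tsv(merged, out / "te.tsv", metadata=meta)
    results["te"] = te_results
    results["te_diff"] = te_diff

    # --- codon enrichment -----------------------------------------------
    profiles_codon = profile_transcriptome(transcripts)
    if cfg["target_codons"] == "auto":
        targets = sorted(linked_codons(diff, refs))
    else:
        targets = sorted(cfg["target_codons"])
    up_ids = te_diff.loc[te_diff["te_class"] == "up", "transcript_id"].tolist()
    bg_ids = te_diff.loc[te_diff["te_class"] == "unchanged", "transcript_id"].tolist()
    if targets and up_ids and bg_ids:
        stat, pval = te_codon_enrichment(
            up_ids, bg_ids, targets, profiles_codon,
            n_perm=cfg["n_perm"], seed=(seed * 1000 + 77) % (2**31),
        )
    else:
        stat, pval = float("nan"), float("nan")
    enrichment = pd.DataFrame(
        {
            "target_codons": [",".join(targets)],
            "n_te_up": [len(up_ids)],
            "n_background": [len(bg_ids)],
            "mean_frequency_difference": [stat],
            "p_value": [pval],
        }
    )
    write_tsv(enrichment, out / "enrichment.tsv", metadata=meta)
    results["enrichment"] = enrichment

    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, sort_keys=True, indent=1)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": cfg, **meta}, fh, sort_keys=True, indent=1, default=str)
    results["outdir"] = out
    return results
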