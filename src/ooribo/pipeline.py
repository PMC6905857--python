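"""End-to-end orchestration: simulate -> assign -> count -> TPM -> factors
-> TE -> differential, in the order the analysis runs on real libraries.

Two entry layers: in-memory (:func:`analyze_experiment`) for tests and the
acceptance machinery, and file-based (:func:`run_simulate`,
:func:`run_pipeline`) behind the CLI, which round-trips everything through
FASTA/FASTQ/TSV on disk.  All randomness flows from the single config seed,
and outputs are written deterministically so identical seeds give
byte-identical result trees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assign import assign_reads, count_reads, index_from_transcriptomes
from .differential import differential_translation
from .io import (
    read_fasta,
    read_reads,
    sha256_of,
    write_count_matrix,
    write_reads_fastq,
    write_table,
    write_transcriptomes,
    write_truth,
)
from .quantify import (
    bulk_translation,
    log_tpm_correlation,
    mrna_stability_check,
    compute_tpm,
    scale_factors,
    spike_ratio,
    translational_efficiency,
)
from .simulate import (
    OrthologTranscriptomes,
    ReadSet,
    SimulatedExperiment,
    SimulationConfig,
    orthologs_from_sequences,
    simulate_experiment,
)

logger = logging.getLogger("ooribo")


@dataclass
class PipelineParams:
    """Analysis knobs shared by the CLI and the in-memory pipeline."""

    read_length: int = 30
    reference_timepoint: str | None = None
    alpha: float = 0.01
    pseudocount: float = 1.0
    tpm_floor: float = 1.0
    baseline: str | None = None  # default: reference timepoint
    aged: str | None = None  # default: last timepoint


@dataclass
class PipelineResults:
    count_matrices: dict
    footprint_tpm: pd.DataFrame
    mrna_tpm: pd.DataFrame
    factors: object
    mrna_factors: object
    bulk: pd.DataFrame
    mrna_levels: pd.DataFrame
    mrna_pvals: pd.DataFrame
    expression: object
    volcano: pd.DataFrame
    mrna_log_tpm_r2: float
    mean_te: pd.Series
    params: PipelineParams = field(default_factory=PipelineParams)


def analyze_experiment(
    transcriptomes: OrthologTranscriptomes,
    read_sets,
    sample_sheet: pd.DataFrame,
    params: PipelineParams,
) -> PipelineResults:
    """Run the full quantitative analysis on in-memory read sets."""
    ref = params.reference_timepoint
    if ref is None:
        raise ValueError("reference_timepoint is required")
    timepoints = list(dict.fromkeys(sample_sheet["timepoint"]))
    baseline = params.baseline or ref
    aged = params.aged or timepoints[-1]

    index = index_from_transcriptomes(transcriptomes, params.read_length)
    assignments = {}
    for rs in read_sets:
        a = assign_reads(index, rs)
        assignments[rs.sample] = a
        uniq = a[a["status"] == "unique"]
        nf = int((uniq["species"] == "focal").sum())
        ns = int((uniq["species"] == "spike").sum())
        logger.info(
            "sample %s: %d unique focal, %d unique spike, ratio %.2f",
            rs.sample, nf, ns, nf / ns if ns else float("nan"),
        )

    cms = count_reads(assignments, sample_sheet, gene_ids=transcriptomes.gene_ids)
    if "footprint" not in cms or "mrna" not in cms:
        raise ValueError("pipeline needs both a footprint and an mrna assay")
    lengths = pd.Series(transcriptomes.lengths, index=transcriptomes.gene_ids, dtype=float)

    fp_tpm = compute_tpm(cms["footprint"].counts, lengths)
    mrna_tpm = compute_tpm(cms["mrna"].counts, lengths)
    fp_factors = scale_factors(spike_ratio(cms["footprint"]), sample_sheet, ref)
    mrna_factors = scale_factors(spike_ratio(cms["mrna"]), sample_sheet, ref)
    for s, row in fp_factors.samples.iterrows():
        logger.info("factor %s: ratio %.3f scale %.3f", s, row["ratio"], row["scale_factor"])

    bulk = bulk_translation(fp_factors)
    mrna_levels, mrna_pvals = mrna_stability_check(mrna_factors)
    expr = translational_efficiency(
        fp_tpm, mrna_tpm, fp_factors, sample_sheet,
        pseudocount=params.pseudocount, tpm_floor=params.tpm_floor,
    )

    meta = sample_sheet.set_index("sample")
    fp_samples = expr.adjusted_footprint_tpm.columns
    group_a = [s for s in fp_samples if meta.at[s, "timepoint"] == baseline]
    group_b = [s for s in fp_samples if meta.at[s, "timepoint"] == aged]
    volcano = differential_translation(
        expr.adjusted_footprint_tpm.loc[expr.expressed],
        group_a, group_b,
        alpha=params.alpha, pseudocount=params.pseudocount,
    )
    r2 = log_tpm_correlation(expr.mrna_condition_mean, baseline, aged, floor=params.tpm_floor)
    mean_te = expr.te.loc[expr.expressed].mean(axis=0)
    return PipelineResults(
        count_matrices=cms,
        footprint_tpm=fp_tpm,
        mrna_tpm=mrna_tpm,
        factors=fp_factors,
        mrna_factors=mrna_factors,
        bulk=bulk,
        mrna_levels=mrna_levels,
        mrna_pvals=mrna_pvals,
        expression=expr,
        volcano=volcano,
        mrna_log_tpm_r2=r2,
        mean_te=mean_te,
        params=params,
    )


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def run_simulate(config: SimulationConfig, outdir) -> dict:
    """Simulate the experiment and write every artifact to ``outdir``.

    Emits focal/spike FASTAs, one FASTQ per sample, a sample sheet CSV with a
    ``file`` column, the ground-truth JSON, and a manifest with the seed,
    package version and per-file checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)

    exp = simulate_experiment(config)
    write_transcriptomes(exp.transcriptomes, outdir / "focal.fasta", outdir / "spike.fasta")
    files = []
    for rs in exp.read_sets:
        path = reads_dir / f"{rs.sample}.fastq"
        write_reads_fastq(rs, path)
        files.append(str(path.relative_to(outdir)))
    sheet = exp.sample_sheet.copy()
    sheet["file"] = files
    sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    write_truth(exp.truth, outdir / "true_state.json")

    tracked = ["focal.fasta", "spike.fasta", "sample_sheet.csv", "true_state.json"] + files
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": len(exp.read_sets),
        "checksums": {f: sha256_of(outdir / f) for f in sorted(tracked)},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_experiment(indir) -> tuple:
    """Load a simulate-output directory back into memory."""
    indir = Path(indir)
    focal = read_fasta(indir / "focal.fasta")
    spike = read_fasta(indir / "spike.fasta")
    transcriptomes = orthologs_from_sequences(focal, spike)
    sheet = pd.read_csv(indir / "sample_sheet.csv")
    read_sets = []
    for _, row in sheet.iterrows():
        frame = read_reads(indir / row["file"])
        read_sets.append(
            ReadSet(
                sample=row["sample"],
                assay=row["assay"],
                timepoint=str(row["timepoint"]),
                replicate=int(row["replicate"]),
                read_length=int(frame["sequence"].str.len().iloc[0]) if len(frame) else 0,
                reads=frame.assign(true_species="", true_gene="", true_start=-1),
            )
        )
    return transcriptomes, read_sets, sheet.drop(columns=["file"])


def write_results(results: PipelineResults, outdir):
    """Write every stage's table under ``outdir`` (TSV, deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for assay, cm in results.count_matrices.items():
        write_count_matrix(cm, outdir / f"counts_{assay}.tsv", outdir / f"totals_{assay}.tsv")
    write_table(results.footprint_tpm, outdir / "tpm_footprint.tsv", index_label="gene")
    write_table(results.mrna_tpm, outdir / "tpm_mrna.tsv", index_label="gene")
    write_table(results.factors.samples, outdir / "factors_footprint.tsv", index_label="sample")
    write_table(results.mrna_factors.samples, outdir / "factors_mrna.tsv", index_label="sample")
    write_table(results.bulk, outdir / "bulk_translation.tsv", index_label="timepoint")
    write_table(results.mrna_levels, outdir / "mrna_levels.tsv", index_label="timepoint")
    write_table(results.mrna_pvals, outdir / "mrna_pairwise_pvalues.tsv", index_label="timepoint")
    write_table(results.expression.te, outdir / "te.tsv", index_label="gene")
    write_table(
        results.expression.adjusted_footprint_tpm,
        outdir / "adjusted_tpm_footprint.tsv",
        index_label="gene",
    )
    write_table(results.volcano, outdir / "volcano.tsv", index_label="gene")
    summary = pd.DataFrame(
        {
            "mean_te": results.mean_te,
            "relative_translation": results.bulk["relative_translation"],
        }
    )
    write_table(summary, outdir / "condition_summary.tsv", index_label="timepoint")
    (outdir / "summary.json").write_text(
        json.dumps(
            {
                "version": __version__,
                "mrna_log_tpm_r2": results.mrna_log_tpm_r2,
                "bulk_translation": results.bulk["relative_translation"].to_dict(),
                "mean_te": results.mean_te.to_dict(),
            },
            indent=2,
            sort_keys=True,
        )
    )


def run_pipeline(indir, outdir, params: PipelineParams) -> PipelineResults:
    """File-to-file pipeline over a simulate-output (or user-data) directory."""
    transcriptomes, read_sets, sheet = load_experiment(indir)
    results = analyze_experiment(transcriptomes, read_sets, sheet, params)
    write_results(results, outdir)
    return results
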