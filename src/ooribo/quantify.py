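"""Spike-in normalization and expression quantification.

The quantitative core: length-normalized TPM over focal coding sequences,
per-sample focal:spike read ratios, scale factors relative to the reference
timepoint (the bulk-translation readout), spike-adjusted footprint TPM, and
per-gene translational efficiency TE = adjusted footprint TPM / mRNA TPM.

Because a constant mass of spike RNA is added to every sample, the focal:
spike unique-read ratio tracks the absolute amount of focal signal; dividing
each sample's ratio by the mean ratio of the reference timepoint gives the
scale factor by which its footprint TPMs are adjusted.  Scale factors are
applied to footprint TPMs only — mRNA TPMs stay unadjusted for TE, while the
mRNA-stability check uses the raw mRNA focal:spike ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assign import CountMatrix


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: tpm_g = 1e6 (c_g/L_g) / sum_j (c_j/L_j).

    ``counts``: genes x samples; ``lengths``: per-gene CDS length in nt.
    A sample with zero counts everywhere yields an all-zero column (with a
    warning) rather than NaNs.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no CDS length for gene(s): {list(missing[:5])}")
    L = lengths.reindex(counts.index)
    if (L <= 0).any():
        bad = L.index[L <= 0][0]
        raise ValueError(f"non-positive CDS length for gene {bad}")
    rate = counts.div(L, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(
            f"sample(s) with zero counts: {list(denom.index[zero])}; TPM set to 0",
            stacklevel=2,
        )
        denom = denom.mask(zero, 1.0)
    return rate.div(denom, axis=1) * 1e6


def spike_ratio(count_matrix: CountMatrix) -> pd.Series:
    """Per-sample focal:spike unique-read ratio."""
    totals = count_matrix.totals
    if (totals["spike_total"] == 0).any():
        bad = totals.index[totals["spike_total"] == 0][0]
        raise ValueError(f"sample {bad} has zero spike reads (spike-in failed)")
    return (totals["focal_total"] / totals["spike_total"]).rename("ratio")


@dataclass
class NormalizationFactors:
    """Per-sample spike ratios and scale factors relative to the reference.

    ``samples``: DataFrame indexed by sample with columns timepoint, ratio,
    scale_factor (ratio / mean reference ratio).  ``condition_factors`` /
    ``condition_sd`` aggregate over replicates per timepoint.
    """

    samples: pd.DataFrame
    reference_timepoint: str
    condition_factors: pd.Series
    condition_sd: pd.Series


def scale_factors(
    ratios: pd.Series, sample_sheet: pd.DataFrame, reference_timepoint: str
) -> NormalizationFactors:
    """Divide each sample's ratio by the arithmetic mean ratio of the
    reference-timepoint replicates.

    The condition-level factor is the mean over replicates, so the reference
    condition's factor is exactly 1.0 by construction.
    """
    meta = sample_sheet.set_index("sample")
    missing = ratios.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"sample(s) missing from sample sheet: {list(missing)}")
    timepoints = meta.loc[ratios.index, "timepoint"]
    ref = ratios[timepoints == reference_timepoint]
    if ref.empty:
        raise ValueError(
            f"reference timepoint {reference_timepoint!r} has no samples among the ratios"
        )
    factors = ratios / ref.mean()
    samples = pd.DataFrame(
        {"timepoint": timepoints, "ratio": ratios, "scale_factor": factors}
    )
    by_tp = samples.groupby("timepoint", sort=False)["scale_factor"]
    return NormalizationFactors(
        samples=samples,
        reference_timepoint=reference_timepoint,
        condition_factors=by_tp.mean(),
        condition_sd=by_tp.std(ddof=1),
    )


def bulk_translation(factors: NormalizationFactors) -> pd.DataFrame:
    """Relative bulk translation per timepoint (reference = 1.0), with
    replicate SD — the spike-normalized total-translation readout."""
    return pd.DataFrame(
        {
            "relative_translation": factors.condition_factors,
            "sd": factors.condition_sd,
        }
    )


@dataclass
class ExpressionTable:
    """Replicate- and condition-level expression with TE.

    ``adjusted_footprint_tpm``: per-sample footprint TPM times its scale
    factor; ``te``: condition-level (adjusted footprint mean + pc) /
    (mRNA mean + pc); ``expressed``: genes whose mRNA TPM clears the floor in
    every condition (TE summaries are restricted to these).
    """

    footprint_tpm: pd.DataFrame
    adjusted_footprint_tpm: pd.DataFrame
    mrna_tpm: pd.DataFrame
    footprint_condition_mean: pd.DataFrame
    mrna_condition_mean: pd.DataFrame
    te: pd.DataFrame
    expressed: pd.Series
    pseudocount: float
    tpm_floor: float


def _condition_mean(table: pd.DataFrame, sample_to_tp: pd.Series) -> pd.DataFrame:
    groups = sample_to_tp.loc[table.columns]
    return table.T.groupby(groups, sort=False).mean().T


def translational_efficiency(
    footprint_tpm: pd.DataFrame,
    mrna_tpm: pd.DataFrame,
    factors: NormalizationFactors,
    sample_sheet: pd.DataFrame,
    pseudocount: float = 1.0,
    tpm_floor: float = 1.0,
) -> ExpressionTable:
    """Per-gene TE per condition: spike-adjusted footprint TPM over mRNA TPM.

    A pseudocount (default 1 TPM) stabilizes low-expression genes; genes
    whose condition-mean mRNA TPM falls below ``tpm_floor`` in any condition
    are flagged unexpressed and excluded from TE summaries downstream.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    genes = footprint_tpm.index.intersection(mrna_tpm.index)
    fp = footprint_tpm.loc[genes]
    mr = mrna_tpm.loc[genes]
    sf = factors.samples["scale_factor"]
    missing = fp.columns.difference(sf.index)
    if len(missing):
        raise ValueError(f"no scale factor for sample(s): {list(missing)}")
    adjusted = fp.mul(sf.reindex(fp.columns), axis=1)

    tp = sample_sheet.set_index("sample")["timepoint"]
    fp_mean = _condition_mean(adjusted, tp)
    mr_mean = _condition_mean(mr, tp)
    common = fp_mean.columns.intersection(mr_mean.columns)
    te = (fp_mean[common] + pseudocount) / (mr_mean[common] + pseudocount)
    expressed = (mr_mean[common] >= tpm_floor).all(axis=1)
    return ExpressionTable(
        footprint_tpm=fp,
        adjusted_footprint_tpm=adjusted,
        mrna_tpm=mr,
        footprint_condition_mean=fp_mean,
        mrna_condition_mean=mr_mean,
        te=te,
        expressed=expressed,
        pseudocount=pseudocount,
        tpm_floor=tpm_floor,
    )


def mrna_stability_check(mrna_factors: NormalizationFactors):
    """Spike-normalized total mRNA per condition plus pairwise t-tests.

    Operates on the *mRNA assay's* focal:spike ratios (scale factors relative
    to the reference), testing whether bulk mRNA levels change between
    timepoints.  Returns (levels DataFrame, pairwise p-value DataFrame).
    Pairs with fewer than two replicates on either side are skipped with a
    warning (p = NaN).
    """
    samples = mrna_factors.samples
    levels = pd.DataFrame(
        {
            "relative_mrna": mrna_factors.condition_factors,
            "sd": mrna_factors.condition_sd,
        }
    )
    tps = list(mrna_factors.condition_factors.index)
    pvals = pd.DataFrame(np.nan, index=tps, columns=tps, dtype=float)
    for i, a in enumerate(tps):
        for b in tps[i + 1 :]:
            xa = samples.loc[samples["timepoint"] == a, "scale_factor"]
            xb = samples.loc[samples["timepoint"] == b, "scale_factor"]
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(
                    f"<2 replicates for {a} vs {b}; t-test skipped", stacklevel=2
                )
                continue
            p = stats.ttest_ind(xa, xb, equal_var=True).pvalue
            pvals.loc[a, b] = pvals.loc[b, a] = p
    return levels, pvals


def log_tpm_correlation(
    condition_mean: pd.DataFrame, cond_a: str, cond_b: str, floor: float = 1.0
) -> float:
    """R^2 of log10 condition-mean TPM between two conditions, over genes
    clearing the floor in both — the mRNA-composition stability readout."""
    a = condition_mean[cond_a]
    b = condition_mean[cond_b]
    keep = (a >= floor) & (b >= floor)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 genes above the floor in both conditions")
    r = np.corrcoef(np.log10(a[keep]), np.log10(b[keep]))[0, 1]
    return float(r**2)
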