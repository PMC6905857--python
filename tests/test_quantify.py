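"""TPM arithmetic, spike ratios, scale factors, TE, and the mRNA-stability
check."""

import numpy as np
import pandas as pd
import pytest

from ooribo.assign import CountMatrix
from ooribo.quantify import (
    bulk_translation,
    compute_tpm,
    log_tpm_correlation,
    mrna_stability_check,
    scale_factors,
    spike_ratio,
    translational_efficiency,
)


def _cm(totals, assay="footprint"):
    genes = pd.Index(["g1"], name="gene")
    counts = pd.DataFrame(
        {s: [f] for s, (f, _) in totals.items()}, index=genes
    )
    t = pd.DataFrame(
        [(s, f, sp) for s, (f, sp) in totals.items()],
        columns=["sample", "focal_total", "spike_total"],
    ).set_index("sample")
    return CountMatrix(assay=assay, counts=counts, totals=t)


def _sheet(sample_to_tp, assay="footprint"):
    return pd.DataFrame(
        {
            "sample": list(sample_to_tp),
            "assay": assay,
            "timepoint": list(sample_to_tp.values()),
            "replicate": 1,
        }
    )


# --- TPM -------------------------------------------------------------------

def test_single_gene_tpm_is_one_million():
    counts = pd.DataFrame({"s": [7]}, index=pd.Index(["g"], name="gene"))
    tpm = compute_tpm(counts, pd.Series({"g": 500.0}))
    assert tpm.loc["g", "s"] == pytest.approx(1e6)


def test_two_gene_hand_example(two_gene_counts):
    # rates 0.1 and 0.05 -> TPM (666666.67, 333333.33)
    counts, lengths = two_gene_counts
    tpm = compute_tpm(counts, lengths)
    assert tpm["s1"].tolist() == pytest.approx([666666.6667, 333333.3333], rel=1e-6)


def test_zero_count_gene_has_zero_tpm():
    counts = pd.DataFrame({"s": [5, 0]}, index=pd.Index(["a", "b"], name="gene"))
    tpm = compute_tpm(counts, pd.Series({"a": 100.0, "b": 100.0}))
    assert tpm.loc["b", "s"] == 0.0


def test_tpm_columns_sum_to_one_million(rng):
    counts = pd.DataFrame(
        rng.integers(0, 500, size=(30, 4)),
        index=pd.Index([f"g{i}" for i in range(30)], name="gene"),
        columns=list("abcd"),
    )
    lengths = pd.Series(rng.integers(100, 2000, 30).astype(float), index=counts.index)
    tpm = compute_tpm(counts, lengths)
    assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)


def test_missing_length_names_the_gene():
    counts = pd.DataFrame({"s": [1]}, index=pd.Index(["orphan"], name="gene"))
    with pytest.raises(KeyError, match="orphan"):
        compute_tpm(counts, pd.Series({"other": 100.0}))


def test_all_zero_sample_warns_and_returns_zeros():
    counts = pd.DataFrame({"s": [0, 0]}, index=pd.Index(["a", "b"], name="gene"))
    with pytest.warns(UserWarning, match="zero counts"):
        tpm = compute_tpm(counts, pd.Series({"a": 100.0, "b": 100.0}))
    assert (tpm["s"] == 0).all()


# --- ratios and factors ----------------------------------------------------

def test_spike_ratio_arithmetic():
    cm = _cm({"s1": (98_000, 2_000), "s2": (5_000, 5_000)})
    r = spike_ratio(cm)
    assert r["s1"] == pytest.approx(49.0)
    assert r["s2"] == pytest.approx(1.0)


def test_zero_spike_total_is_an_error():
    cm = _cm({"s1": (100, 0)})
    with pytest.raises(ValueError, match="spike"):
        spike_ratio(cm)


def test_equal_ratios_give_unit_factors():
    ratios = pd.Series({"a": 3.0, "b": 3.0, "c": 3.0})
    nf = scale_factors(ratios, _sheet({"a": "d2", "b": "d8", "c": "d12"}), "d2")
    assert np.allclose(nf.samples["scale_factor"], 1.0)


def test_day8_factor_reproduced_from_constructed_ratios():
    # reference ratio 49.0 and sample ratio 29.155 give the 0.595 factor
    ratios = pd.Series({"ref": 49.0, "aged": 29.155})
    nf = scale_factors(ratios, _sheet({"ref": "d2", "aged": "d8"}), "d2")
    assert nf.samples.loc["aged", "scale_factor"] == pytest.approx(0.595, abs=1e-4)


def test_reference_condition_mean_factor_is_exactly_one():
    ratios = pd.Series({"r1": 40.0, "r2": 50.0, "r3": 60.0, "x": 20.0})
    nf = scale_factors(ratios, _sheet({"r1": "d2", "r2": "d2", "r3": "d2", "x": "d8"}), "d2")
    ref = nf.samples[nf.samples.timepoint == "d2"]["scale_factor"]
    assert ref.mean() == pytest.approx(1.0)
    assert nf.condition_factors["d2"] == pytest.approx(1.0)


def test_scale_factor_equivariance_under_focal_rescaling():
    """Multiplying one sample's focal counts by c multiplies its factor by c."""
    base = pd.Series({"ref": 49.0, "s": 30.0})
    sheet = _sheet({"ref": "d2", "s": "d8"})
    nf1 = scale_factors(base, sheet, "d2")
    nf2 = scale_factors(base * pd.Series({"ref": 1.0, "s": 2.5}), sheet, "d2")
    assert nf2.samples.loc["s", "scale_factor"] == pytest.approx(
        2.5 * nf1.samples.loc["s", "scale_factor"]
    )
    assert nf2.samples.loc["ref", "scale_factor"] == nf1.samples.loc["ref", "scale_factor"]


def test_missing_reference_timepoint_raises():
    ratios = pd.Series({"a": 1.0})
    with pytest.raises(ValueError, match="reference"):
        scale_factors(ratios, _sheet({"a": "d8"}), "d2")


def test_bulk_translation_reports_condition_means_with_sd():
    ratios = pd.Series(
        {"a1": 48.0, "a2": 50.0, "b1": 28.0, "b2": 30.0}
    )
    sheet = _sheet({"a1": "d2", "a2": "d2", "b1": "d8", "b2": "d8"})
    bulk = bulk_translation(scale_factors(ratios, sheet, "d2"))
    assert bulk.loc["d2", "relative_translation"] == pytest.approx(1.0)
    assert bulk.loc["d8", "relative_translation"] == pytest.approx(29.0 / 49.0)
    assert bulk["sd"].notna().all()


# --- TE --------------------------------------------------------------------

def _te_inputs(factor):
    genes = pd.Index(["g1", "g2"], name="gene")
    fp = pd.DataFrame({"fp_a": [100.0, 300.0]}, index=genes)
    mr = pd.DataFrame({"mr_a": [100.0, 300.0]}, index=genes)
    ratios = pd.Series({"fp_ref": 10.0, "fp_a": 10.0 * factor})
    sheet = pd.DataFrame(
        {
            "sample": ["fp_ref", "fp_a", "mr_a"],
            "assay": ["footprint", "footprint", "mrna"],
            "timepoint": ["ref", "aged", "aged"],
            "replicate": 1,
        }
    )
    nf = scale_factors(ratios, sheet, "ref")
    return fp, mr, nf, sheet


@pytest.mark.parametrize("factor,expected", [(1.0, 1.0), (0.427, 0.427)])
def test_te_equals_scale_factor_for_matched_tpm(factor, expected):
    fp, mr, nf, sheet = _te_inputs(factor)
    fp = fp.rename(columns={"fp_a": "fp_a"})
    expr = translational_efficiency(
        fp[["fp_a"]], mr, nf, sheet, pseudocount=0.0, tpm_floor=0.0
    )
    assert expr.te.loc["g1", "aged"] == pytest.approx(expected)
    assert expr.te.loc["g2", "aged"] == pytest.approx(expected)


def test_negative_pseudocount_rejected():
    fp, mr, nf, sheet = _te_inputs(1.0)
    with pytest.raises(ValueError):
        translational_efficiency(fp[["fp_a"]], mr, nf, sheet, pseudocount=-1.0)


def test_expression_floor_flags_low_mrna_genes():
    fp, mr, nf, sheet = _te_inputs(1.0)
    mr.loc["g2"] = 0.5
    expr = translational_efficiency(fp[["fp_a"]], mr, nf, sheet, tpm_floor=1.0)
    assert bool(expr.expressed["g1"]) and not bool(expr.expressed["g2"])


# --- mRNA stability --------------------------------------------------------

def test_identical_replicate_totals_give_unit_levels_and_insignificance():
    ratios = pd.Series({f"{t}{r}": 8.0 for t in "ab" for r in (1, 2, 3)})
    sheet = _sheet({s: ("d2" if s.startswith("a") else "d12") for s in ratios.index}, assay="mrna")
    levels, pvals = mrna_stability_check(scale_factors(ratios, sheet, "d2"))
    assert np.allclose(levels["relative_mrna"], 1.0)
    # identical values in both groups: no evidence of change
    assert pvals.loc["d2", "d12"] == pytest.approx(1.0) or np.isnan(pvals.loc["d2", "d12"])


def test_single_replicate_condition_warns_and_skips_test():
    ratios = pd.Series({"a1": 8.0, "a2": 8.2, "b1": 7.9})
    sheet = _sheet({"a1": "d2", "a2": "d2", "b1": "d12"}, assay="mrna")
    with pytest.warns(UserWarning, match="replicates"):
        _, pvals = mrna_stability_check(scale_factors(ratios, sheet, "d2"))
    assert np.isnan(pvals.loc["d2", "d12"])


def test_log_tpm_correlation_is_one_for_identical_conditions():
    cm = pd.DataFrame({"d2": [10.0, 100.0, 1000.0], "d12": [10.0, 100.0, 1000.0]})
    assert log_tpm_correlation(cm, "d2", "d12") == pytest.approx(1.0)
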