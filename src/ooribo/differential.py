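"""Per-gene differential translation, pilot-light classification, and
category summaries.

The test throughout is a two-sample Student t-test on log2-transformed
replicate-level spike-adjusted expression (Welch available via
``equal_var=False``), with Benjamini–Hochberg q-values reported alongside.
Pilot-light genes — genes translated at a higher level in the arrested
mature oocyte than in the early embryo, candidates for maintaining oocyte
viability during storage — are classified on the raw p-value threshold
(default p < 0.01) with the direction filter oocyte > embryo; BH q-values
are carried in the output but do not gate the call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


def differential_translation(
    table: pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.01,
    pseudocount: float = 1.0,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Gene-wise comparison of group B against group A.

    ``table``: genes x samples (spike-adjusted TPM).  Per gene: group means,
    log2 fold change (B/A on pseudocounted means), two-sided t-test on
    log2(replicate + pseudocount), BH q-values, and a class label from
    (sign of the fold change, p < alpha).  Genes with zero variance in both
    groups get p = 1 when the means are equal (no evidence) and p = 0
    otherwise (the test degenerates to an exact difference).
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    missing = [s for s in group_a + group_b if s not in table.columns]
    if missing:
        raise ValueError(f"sample(s) not in table: {missing}")

    a = table[group_a].to_numpy(dtype=float)
    b = table[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(lb, la, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(lb.mean(axis=1), la.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0

    q = multipletests(p, method="fdr_bh")[1]
    label = np.where(
        (p < alpha) & (log2fc > 0), UP, np.where((p < alpha) & (log2fc < 0), DOWN, UNCHANGED)
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
            "class": label,
            "neg_log10_p": -np.log10(np.maximum(p, np.finfo(float).tiny)),
        },
        index=table.index.rename("gene"),
    )


@dataclass
class PilotLightResult:
    """Genes preferentially translated in arrested oocytes vs early embryos."""

    genes: list
    n_expressed: int
    count: int
    fraction: float
    table: pd.DataFrame


def classify_pilot_light(
    oocyte_table: pd.DataFrame,
    embryo_table: pd.DataFrame,
    alpha: float = 0.01,
    tpm_floor: float = 1.0,
    pseudocount: float = 1.0,
    equal_var: bool = True,
) -> PilotLightResult:
    """Identify pilot-light genes.

    Both tables are replicate-level spike-adjusted translation (already on a
    common absolute scale).  The expressed universe is oocyte genes whose
    mean clears ``tpm_floor``; within it a gene qualifies iff its adjusted
    translation is significantly higher in the oocyte than in the embryo
    (raw p < alpha, same t-test as elsewhere).  ``fraction`` = count /
    expressed universe.
    """
    genes = oocyte_table.index.intersection(embryo_table.index)
    oo = oocyte_table.loc[genes]
    em = embryo_table.loc[genes]
    expressed = oo.mean(axis=1) >= tpm_floor
    if not expressed.any():
        raise ValueError("no oocyte genes clear the expression floor")
    universe = genes[expressed]
    combined = pd.concat([em.loc[universe], oo.loc[universe]], axis=1)
    res = differential_translation(
        combined,
        group_a=list(em.columns),
        group_b=list(oo.columns),
        alpha=alpha,
        pseudocount=pseudocount,
        equal_var=equal_var,
    )
    hits = res[(res["log2fc"] > 0) & (res["p_value"] < alpha)]
    return PilotLightResult(
        genes=sorted(hits.index),
        n_expressed=int(expressed.sum()),
        count=int(len(hits)),
        fraction=len(hits) / int(expressed.sum()),
        table=res,
    )


def category_summary(
    translation: pd.DataFrame,
    mrna: pd.DataFrame,
    category_map: dict,
    baseline: str,
    aged: str,
    pseudocount: float = 1.0,
):
    """Per-category log2 changes in translation and mRNA between two
    conditions.

    ``translation`` / ``mrna``: genes x conditions (condition means).
    Returns (per_gene DataFrame, summary DataFrame); genes named in a
    category but absent from the tables are reported in the summary's
    ``missing`` column, never dropped silently, and categories with zero
    present genes are flagged.
    """
    for tbl, name in ((translation, "translation"), (mrna, "mrna")):
        for cond in (baseline, aged):
            if cond not in tbl.columns:
                raise ValueError(f"condition {cond!r} missing from {name} table")

    def lfc(tbl, gene):
        return float(
            np.log2(tbl.at[gene, aged] + pseudocount)
            - np.log2(tbl.at[gene, baseline] + pseudocount)
        )

    gene_rows, cat_rows = [], []
    for category, members in category_map.items():
        present = [g for g in members if g in translation.index and g in mrna.index]
        missing = [g for g in members if g not in present]
        for g in present:
            gene_rows.append(
                {
                    "category": category,
                    "gene": g,
                    "log2_translation_change": lfc(translation, g),
                    "log2_mrna_change": lfc(mrna, g),
                }
            )
        tvals = [r["log2_translation_change"] for r in gene_rows if r["category"] == category]
        mvals = [r["log2_mrna_change"] for r in gene_rows if r["category"] == category]
        cat_rows.append(
            {
                "category": category,
                "n_genes": len(present),
                "median_log2_translation_change": float(np.median(tvals)) if tvals else np.nan,
                "median_log2_mrna_change": float(np.median(mvals)) if mvals else np.nan,
                "missing": ";".join(missing),
                "empty": len(present) == 0,
            }
        )
    return pd.DataFrame(gene_rows), pd.DataFrame(cat_rows)


def read_category_map(path) -> dict:
    """Two-column TSV (category, gene_id) -> {category: [genes]}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["category", "gene"], comment="#")
    out: dict = {}
    for cat, gene in zip(df["category"], df["gene"]):
        out.setdefault(str(cat), []).append(str(gene))
    return out
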