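"""Exact cross-species assignment: index construction, the unique-mapping
filter, counting, and window distinguishability."""

import numpy as np
import pandas as pd
import pytest

from ooribo.assign import (
    LENGTH_ERROR,
    MULTI,
    UNIQUE,
    UNMAPPED,
    assign_reads,
    assign_reads_naive,
    build_index,
    count_reads,
    index_from_transcriptomes,
    window_distinguishability,
)
from ooribo.simulate import (
    GenePair,
    OrthologTranscriptomes,
    generate_ortholog_transcriptomes,
    simulate_sample_reads,
)


def test_index_counts_all_windows_of_a_single_transcript():
    seq = "ACGTACGTACGTACGTACGT"  # length 20, k=5 -> 16 positions
    idx = build_index({"g": seq}, {}, read_length=5)
    assert sum(len(v) for v in idx.occurrences.values()) == 16


def test_identical_orthologs_hit_both_species_everywhere():
    seq = "ACGTTGCAACGTTGCA"
    idx = build_index({"g": seq}, {"g": seq}, read_length=6)
    for occ in idx.occurrences.values():
        assert {sp for sp, _, _ in occ} == {"focal", "spike"}
    reads = [("r0", seq[:6])]
    out = assign_reads(idx, reads)
    assert out.loc[0, "status"] == MULTI


def test_short_transcript_error_names_the_transcript():
    with pytest.raises(ValueError, match="tooshort"):
        build_index({"ok": "ACGTACGTAC", "tooshort": "ACG"}, {}, read_length=8)


def test_index_agrees_with_naive_substring_oracle(tiny_transcriptomes, rng):
    """50 random queries (true windows plus mutated ones) resolve identically
    under the k-mer index and a brute-force scan of every transcript."""
    k = 30
    focal = tiny_transcriptomes.sequences("focal")
    spike = tiny_transcriptomes.sequences("spike")
    idx = build_index(focal, spike, k)
    pool = list(focal.items()) + list(spike.items())
    queries = []
    for i in range(50):
        gid, seq = pool[rng.integers(len(pool))]
        s = int(rng.integers(0, len(seq) - k + 1))
        q = seq[s : s + k]
        if i % 3 == 0:  # mutate one base; often unmapped
            pos = int(rng.integers(k))
            q = q[:pos] + "ACGT"[(("ACGT".index(q[pos])) + 1) % 4] + q[pos + 1 :]
        queries.append((f"q{i}", q))
    fast = assign_reads(idx, queries)
    slow = assign_reads_naive(focal, spike, queries)
    pd.testing.assert_frame_equal(fast, slow)


def test_unique_reads_carry_their_true_labels(tiny_transcriptomes):
    """Exact matching admits no mis-assignment: every unique-status read's
    label equals the simulation's ground truth."""
    rs = simulate_sample_reads(
        tiny_transcriptomes,
        np.ones(len(tiny_transcriptomes)),
        n_reads=4000,
        read_length=30,
        seed=21,
        sample="s",
    )
    idx = index_from_transcriptomes(tiny_transcriptomes, 30)
    out = assign_reads(idx, rs)
    merged = out.merge(rs.reads, on="read_id")
    uniq = merged[merged.status == UNIQUE]
    assert len(uniq) > 0
    assert (uniq.species == uniq.true_species).all()
    assert (uniq.gene == uniq.true_gene).all()
    assert set(merged.status) <= {UNIQUE, MULTI}  # error-free reads never unmapped


def test_shared_window_between_orthologs_is_multimapped():
    # orthologs differing only at the last base: the first window is shared
    focal = "ACGGTCATTGCAAGTCC"
    spike = focal[:-1] + "A"
    idx = build_index({"g": focal}, {"g": spike}, read_length=8)
    out = assign_reads(idx, [("shared", focal[:8]), ("diag", focal[-8:])])
    assert out.loc[0, "status"] == MULTI
    assert out.loc[1, "status"] == UNIQUE
    assert out.loc[1, "species"] == "focal"


def test_position_level_uniqueness_is_configurable():
    # one gene containing the same window twice: unique at gene level,
    # multimapped at position level
    seq = "AAAAACGCGAAAAA"
    idx_gene = build_index({"g": seq}, {}, read_length=5, collapse_positions=True)
    idx_pos = build_index({"g": seq}, {}, read_length=5, collapse_positions=False)
    assert assign_reads(idx_gene, [("r", "AAAAA")]).loc[0, "status"] == UNIQUE
    assert assign_reads(idx_pos, [("r", "AAAAA")]).loc[0, "status"] == MULTI


def test_wrong_length_read_is_flagged_not_fatal(tiny_transcriptomes):
    idx = index_from_transcriptomes(tiny_transcriptomes, 30)
    out = assign_reads(idx, [("short", "ACGT")])
    assert out.loc[0, "status"] == LENGTH_ERROR
    with pytest.raises(ValueError):
        assign_reads(idx, [("short", "ACGT")], strict=True)


# --- counting --------------------------------------------------------------

def _sheet(samples, assay="footprint"):
    return pd.DataFrame(
        {
            "sample": samples,
            "assay": assay,
            "timepoint": "t0",
            "replicate": range(1, len(samples) + 1),
        }
    )


def test_all_multimapped_reads_give_a_zero_matrix():
    a = pd.DataFrame(
        {"read_id": ["r1", "r2"], "status": [MULTI, UNMAPPED], "species": "", "gene": ""}
    )
    cms = count_reads({"s1": a}, _sheet(["s1"]), gene_ids=["g1", "g2"])
    cm = cms["footprint"]
    assert (cm.counts.to_numpy() == 0).all()
    assert cm.totals.loc["s1"].tolist() == [0, 0]


def test_counts_match_ground_truth_tallies(tiny_transcriptomes):
    rs = simulate_sample_reads(
        tiny_transcriptomes,
        np.arange(1.0, 11.0),
        n_reads=3000,
        read_length=30,
        seed=31,
        sample="s1",
    )
    idx = index_from_transcriptomes(tiny_transcriptomes, 30)
    out = assign_reads(idx, rs)
    cms = count_reads({"s1": out}, _sheet(["s1"]), gene_ids=tiny_transcriptomes.gene_ids)
    cm = cms["footprint"]
    cm.validate()
    merged = out.merge(rs.reads, on="read_id")
    uniq = merged[merged.status == UNIQUE]
    # totals conserve the unique reads; per-gene counts equal the truth tally
    assert cm.totals.loc["s1"].sum() == len(uniq)
    truth = uniq[uniq.species == "focal"].groupby("true_gene").size()
    expected = truth.reindex(cm.counts.index).fillna(0).astype(int)
    assert (cm.counts["s1"].to_numpy() == expected.to_numpy()).all()


def test_unknown_sample_raises():
    a = pd.DataFrame({"read_id": [], "status": [], "species": [], "gene": []})
    with pytest.raises(ValueError, match="ghost"):
        count_reads({"ghost": a}, _sheet(["s1"]))


# --- window distinguishability --------------------------------------------

def _pair(focal, spike):
    subs = frozenset(i for i, (a, b) in enumerate(zip(focal, spike)) if a != b)
    return OrthologTranscriptomes([GenePair("g0", focal, spike, subs)])


def test_identical_orthologs_have_zero_distinguishable_windows():
    seq = "ACGT" * 20
    per_gene, agg = window_distinguishability(_pair(seq, seq), window_length=30)
    assert agg["fraction"] == 0.0
    assert per_gene.loc[0, "n_windows"] == len(seq) - 29


def test_single_central_substitution_covers_every_window():
    # length 59, one substitution at 0-based position 29: all 30 windows hit
    rng = np.random.default_rng(1)
    focal = "".join("ACGT"[i] for i in rng.integers(0, 4, 59))
    spike = focal[:29] + "ACGT"[("ACGT".index(focal[29]) + 1) % 4] + focal[30:]
    per_gene, agg = window_distinguishability(_pair(focal, spike), window_length=30)
    assert per_gene.loc[0, "n_windows"] == 30
    assert per_gene.loc[0, "n_distinguishable"] == 30
    assert agg["fraction"] == 1.0


def test_window_counts_agree_with_brute_force_enumeration():
    tr = generate_ortholog_transcriptomes(10, (40, 120), 0.08, seed=17)
    per_gene, _ = window_distinguishability(tr, window_length=30)
    for g, row in zip(tr, per_gene.itertuples()):
        expected = sum(
            any(p in g.substituted_positions for p in range(s, s + 30))
            for s in range(g.length - 29)
        )
        assert row.n_distinguishable == expected


def test_short_transcript_contributes_zero_windows_and_is_flagged():
    tr = _pair("ACGTACGT", "ACGTACGA")
    per_gene, agg = window_distinguishability(tr, window_length=30)
    assert per_gene.loc[0, "too_short"]
    assert agg["n_windows"] == 0


def test_distinguishable_fraction_is_monotone_in_nested_substitutions():
    """Adding substitutions to an existing set never removes coverage."""
    rng = np.random.default_rng(5)
    base = generate_ortholog_transcriptomes(20, (80, 160), 0.02, seed=8)
    richer_genes = []
    for g in base:
        extra = set(g.substituted_positions)
        for p in rng.integers(0, g.length, 8):
            extra.add(int(p))
        spike = list(g.focal_sequence)
        for p in extra:
            spike[p] = "ACGT"[("ACGT".index(g.focal_sequence[p]) + 1) % 4]
        richer_genes.append(GenePair(g.gene_id, g.focal_sequence, "".join(spike), frozenset(extra)))
    _, agg_lo = window_distinguishability(base, window_length=30)
    _, agg_hi = window_distinguishability(OrthologTranscriptomes(richer_genes), window_length=30)
    assert agg_hi["fraction"] >= agg_lo["fraction"]
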