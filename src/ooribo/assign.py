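"""Exact cross-species read assignment on a combined two-species reference.

The disambiguation strategy: map every read against the *combined* focal +
spike transcriptome and keep only reads that match a single gene — each
retained read is then attributable to one species and one gene.  With
error-free fixed-length reads, exact k-mer lookup reproduces the
unique/multi-mapped distinction of an aligner's NH:i:1 filter bit-exactly,
which is the property the spike-in normalization depends on.

Also provides the sliding-window polymorphism analysis that quantifies how
distinguishable the two orthologous transcriptomes are at footprint length:
a k-nt window is species-diagnostic iff it covers at least one substituted
site, so under i.i.d. per-site divergence p the expected diagnostic fraction
is 1 - (1-p)**k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FOCAL, SPIKE, OrthologTranscriptomes, ReadSet

UNIQUE = "unique"
MULTI = "multimapped"
UNMAPPED = "unmapped"
LENGTH_ERROR = "length_error"

_MULTI_SENTINEL = ("*", "*")


@dataclass
class CombinedIndex:
    """Exhaustive k-mer index over both species' transcripts.

    ``occurrences`` maps every k-mer to its list of (species, gene, start)
    hits; ``resolution`` pre-collapses each k-mer to its unique
    (species, gene) label, or a multi-map sentinel.  By default occurrences
    are collapsed to distinct (species, gene) pairs — a read hitting one gene
    at two positions is still unique, matching transcript-level NH:i:1
    semantics.  Position-level uniqueness and reverse-complement lookup are
    configurable.
    """

    k: int
    occurrences: dict
    resolution: dict
    collapse_positions: bool = True
    include_revcomp: bool = False
    n_transcripts: int = 0

    def lookup(self, kmer: str):
        return self.occurrences.get(kmer, [])


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def build_index(
    focal_sequences,
    spike_sequences,
    read_length: int,
    collapse_positions: bool = True,
    include_revcomp: bool = False,
) -> CombinedIndex:
    """Index every read_length-mer of every transcript of both species.

    ``focal_sequences`` / ``spike_sequences``: mapping gene_id -> sequence.
    Raises if any transcript is shorter than the read length (it could never
    be counted and would silently distort totals).
    """
    if read_length < 1:
        raise ValueError("read_length must be positive")
    occurrences: dict = {}
    n = 0
    for species, seqs in ((FOCAL, focal_sequences), (SPIKE, spike_sequences)):
        for gene_id, seq in seqs.items():
            if len(seq) < read_length:
                raise ValueError(
                    f"transcript {gene_id} ({species}) has length {len(seq)} "
                    f"< read length {read_length}"
                )
            n += 1
            for start in range(len(seq) - read_length + 1):
                kmer = seq[start : start + read_length]
                occurrences.setdefault(kmer, []).append((species, gene_id, start))
                if include_revcomp:
                    occurrences.setdefault(_revcomp(kmer), []).append(
                        (species, gene_id, start)
                    )

    resolution = {}
    for kmer, occ in occurrences.items():
        if collapse_positions:
            labels = {(sp, g) for sp, g, _ in occ}
        else:
            labels = set(occ)
        if len(labels) == 1:
            sp, g = next(iter(labels))[:2]
            resolution[kmer] = (sp, g)
        else:
            resolution[kmer] = _MULTI_SENTINEL
    return CombinedIndex(
        k=read_length,
        occurrences=occurrences,
        resolution=resolution,
        collapse_positions=collapse_positions,
        include_revcomp=include_revcomp,
        n_transcripts=n,
    )


def index_from_transcriptomes(
    transcriptomes: OrthologTranscriptomes, read_length: int, **kwargs
) -> CombinedIndex:
    return build_index(
        transcriptomes.sequences(FOCAL),
        transcriptomes.sequences(SPIKE),
        read_length,
        **kwargs,
    )


def _reads_frame(reads) -> pd.DataFrame:
    if isinstance(reads, ReadSet):
        return reads.reads[["read_id", "sequence"]]
    if isinstance(reads, pd.DataFrame):
        return reads[["read_id", "sequence"]]
    return pd.DataFrame(reads, columns=["read_id", "sequence"])


def assign_reads(index: CombinedIndex, reads, strict: bool = False) -> pd.DataFrame:
    """Assign each read by exact lookup; order-preserving.

    Returns a DataFrame (read_id, status, species, gene) where status is
    unique / multimapped / unmapped, or length_error for reads that are not
    exactly k long (an exception instead when ``strict``).
    """
    frame = _reads_frame(reads)
    k = index.k
    resolution = index.resolution
    statuses, species, genes = [], [], []
    for seq in frame["sequence"]:
        if len(seq) != k:
            if strict:
                raise ValueError(f"read length {len(seq)} does not match index k={k}")
            statuses.append(LENGTH_ERROR)
            species.append("")
            genes.append("")
            continue
        label = resolution.get(seq)
        if label is None:
            statuses.append(UNMAPPED)
            species.append("")
            genes.append("")
        elif label is _MULTI_SENTINEL:
            statuses.append(MULTI)
            species.append("")
            genes.append("")
        else:
            statuses.append(UNIQUE)
            species.append(label[0])
            genes.append(label[1])
    return pd.DataFrame(
        {
            "read_id": frame["read_id"].to_numpy(),
            "status": statuses,
            "species": species,
            "gene": genes,
        }
    )


def assign_reads_naive(focal_sequences, spike_sequences, reads, collapse_positions=True):
    """Brute-force oracle: scan every read against every transcript.

    Independent of the k-mer index; used to validate it on small inputs.
    """
    frame = _reads_frame(reads)
    rows = []
    for read_id, seq in zip(frame["read_id"], frame["sequence"]):
        labels = set()
        for sp, seqs in ((FOCAL, focal_sequences), (SPIKE, spike_sequences)):
            for gene_id, tx in seqs.items():
                start = tx.find(seq)
                while start != -1:
                    labels.add((sp, gene_id) if collapse_positions else (sp, gene_id, start))
                    start = tx.find(seq, start + 1)
        if not labels:
            rows.append((read_id, UNMAPPED, "", ""))
        elif len(labels) == 1:
            sp, gene = next(iter(labels))[:2]
            rows.append((read_id, UNIQUE, sp, gene))
        else:
            rows.append((read_id, MULTI, "", ""))
    return pd.DataFrame(rows, columns=["read_id", "status", "species", "gene"])


@dataclass
class CountMatrix:
    """Unique-read counts for the focal species plus per-sample species totals."""

    assay: str
    counts: pd.DataFrame  # genes x samples, ints
    totals: pd.DataFrame  # index sample; columns focal_total, spike_total

    def validate(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        col = self.counts.sum(axis=0)
        if not col.equals(self.totals["focal_total"].reindex(col.index)):
            raise ValueError("focal totals do not match gene-count column sums")


def count_reads(assignments, sample_sheet: pd.DataFrame, gene_ids=None) -> dict:
    """Tally unique reads into one CountMatrix per assay.

    ``assignments``: mapping sample -> assignment DataFrame (from
    :func:`assign_reads`).  Multi-mapped and unmapped reads are excluded from
    both the gene matrix and the species totals.  Unknown samples raise.
    """
    known = set(sample_sheet["sample"])
    unknown = set(assignments) - known
    if unknown:
        raise ValueError(f"samples not in sample sheet: {sorted(unknown)}")

    meta = sample_sheet.set_index("sample")
    out = {}
    for assay in sorted(meta.loc[list(assignments), "assay"].unique()):
        # column order follows the sample sheet so reruns are byte-identical
        samples = [
            s for s in sample_sheet["sample"] if s in assignments and meta.at[s, "assay"] == assay
        ]
        per_gene = {}
        totals = []
        universe = set(gene_ids) if gene_ids is not None else set()
        for s in samples:
            a = assignments[s]
            uniq = a[a["status"] == UNIQUE]
            focal = uniq[uniq["species"] == FOCAL]
            per_gene[s] = focal.groupby("gene").size()
            universe.update(per_gene[s].index)
            totals.append(
                {
                    "sample": s,
                    "focal_total": int(len(focal)),
                    "spike_total": int((uniq["species"] == SPIKE).sum()),
                }
            )
        index = sorted(universe) if gene_ids is None else list(gene_ids)
        counts = pd.DataFrame(
            {s: per_gene[s].reindex(index).fillna(0).astype(int) for s in samples},
            index=pd.Index(index, name="gene"),
        )
        out[assay] = CountMatrix(
            assay=assay,
            counts=counts,
            totals=pd.DataFrame(totals).set_index("sample"),
        )
    return out


def window_distinguishability(
    transcriptomes: OrthologTranscriptomes, gene_subset=None, window_length: int = 30
):
    """Fraction of length-k windows that distinguish the two species.

    A window is distinguishable iff it covers >= 1 substituted position.
    Returns (per_gene DataFrame, aggregate dict) where the aggregate sums
    windows over the gene subset; transcripts shorter than the window
    contribute zero windows and are flagged ``too_short``.
    """
    if window_length < 1:
        raise ValueError("window_length must be positive")
    subset = set(gene_subset) if gene_subset is not None else None
    rows = []
    for g in transcriptomes:
        if subset is not None and g.gene_id not in subset:
            continue
        L = g.length
        if L < window_length:
            rows.append((g.gene_id, 0, 0, np.nan, True))
            continue
        n_windows = L - window_length + 1
        covered = np.zeros(n_windows + 1, dtype=int)
        for p in g.substituted_positions:
            lo = max(0, p - window_length + 1)
            hi = min(n_windows - 1, p)
            if hi >= lo:
                covered[lo] += 1
                covered[hi + 1] -= 1
        n_poly = int(np.count_nonzero(np.cumsum(covered[:-1]) > 0))
        rows.append((g.gene_id, n_windows, n_poly, n_poly / n_windows, False))
    per_gene = pd.DataFrame(
        rows, columns=["gene", "n_windows", "n_distinguishable", "fraction", "too_short"]
    )
    total = int(per_gene["n_windows"].sum())
    poly = int(per_gene["n_distinguishable"].sum())
    aggregate = {
        "n_windows": total,
        "n_with_polymorphism": poly,
        "fraction": poly / total if total else float("nan"),
    }
    return per_gene, aggregate
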