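"""Synthetic two-species ribosome-profiling experiment generator.

Emulates the study design this package analyses: mature *D. melanogaster*
oocytes stored in the ovary for 2, 8 or 12 days, profiled in triplicate by
ribosome footprinting (30-nt protected fragments) and mRNA-seq, with a fixed
mass of *D. pseudoobscura* ovary lysate spiked into every sample (1.6 µg into
80 µg, i.e. ~2% of the RNA mass) so that absolute between-sample changes in
translation are measurable from the focal:spike read ratio.

Everything downstream (assignment, normalization, differential statistics,
decay fitting) is tested against the ground truth recorded here.

Two orthologous transcriptomes are generated as length-matched coding
sequences differing by independent per-site substitutions — no indels, so
positions align one-to-one and window distinguishability is exactly
computable.  Reads are error-free sense-strand substrings.  A global
``bulk_factor`` per timepoint scales the focal footprint mass against the
constant spike mass; the mRNA assay keeps bulk factor 1.0 at all timepoints
(stored-oocyte mRNA levels do not change while translation declines).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd

FOCAL = "focal"
SPIKE = "spike"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _rng_for(seed: int, *tokens) -> np.random.Generator:
    """One independent, reproducible stream per (seed, token...) combination.

    Tokens are hashed with crc32 so any sample label yields a stable sub-seed;
    every derived entropy word stays below 2**31.
    """
    words = [int(seed) & 0x7FFFFFFF]
    words += [zlib.crc32(str(t).encode()) & 0x7FFFFFFF for t in tokens]
    return np.random.default_rng(words)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePair:
    """A focal transcript and its spike-species ortholog, positionally aligned."""

    gene_id: str
    focal_sequence: str
    spike_sequence: str
    substituted_positions: frozenset

    def __post_init__(self):
        if len(self.focal_sequence) != len(self.spike_sequence):
            raise ValueError(f"{self.gene_id}: ortholog sequences differ in length")

    @property
    def length(self) -> int:
        return len(self.focal_sequence)


@dataclass
class OrthologTranscriptomes:
    """Paired focal/spike coding sequences with known substitution positions."""

    genes: list

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    @property
    def gene_ids(self):
        return [g.gene_id for g in self.genes]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([g.length for g in self.genes])

    def sequences(self, species: str) -> dict:
        attr = "focal_sequence" if species == FOCAL else "spike_sequence"
        return {g.gene_id: getattr(g, attr) for g in self.genes}


@dataclass
class ReadSet:
    """Simulated reads for one sample, with ground-truth provenance labels.

    ``reads`` columns: read_id, sequence, true_species, true_gene, true_start.
    """

    sample: str
    assay: str
    timepoint: str
    replicate: int
    read_length: int
    reads: pd.DataFrame

    def __len__(self):
        return len(self.reads)


@dataclass
class SimulationConfig:
    """Full experiment design; defaults are the study conditions.

    Three storage timepoints (day 2 reference, day 8, day 12) in triplicate,
    footprint bulk-translation factors 1.0 / 0.595 / 0.427, ~2% spike-in read
    mass at the reference, 30-nt reads, 2e5 reads per sample.
    ``te_profile`` gives per-gene relative translation rates — either one
    vector shared by all timepoints or a mapping timepoint -> vector.
    """

    n_genes: int = 300
    length_range: tuple = (150, 450)
    divergence: float = 0.12
    spike_fraction: float = 0.02
    timepoints: tuple = ("d2", "d8", "d12")
    bulk_factors: tuple = (1.0, 0.595, 0.427)
    n_replicates: int = 3
    reads_per_sample: int = 200_000
    read_length: int = 30
    abundance_shape: float = 1.0
    te_profile: object = None
    seed: int = 0

    def validate(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.length_range
        if lo > hi or lo < self.read_length:
            raise ValueError("length_range must satisfy read_length <= lo <= hi")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if not 0.0 <= self.spike_fraction < 1.0:
            raise ValueError("spike_fraction must lie in [0, 1)")
        if len(self.bulk_factors) != len(self.timepoints):
            raise ValueError(
                "bulk_factors must have one entry per timepoint "
                f"(got {len(self.bulk_factors)} for {len(self.timepoints)} timepoints)"
            )
        if any(b <= 0 for b in self.bulk_factors):
            raise ValueError("bulk_factors must be positive")
        if sum(1 for b in self.bulk_factors if b == 1.0) < 1:
            raise ValueError("exactly one timepoint must carry bulk_factor 1.0 (the reference)")
        if self.n_replicates < 1 or self.reads_per_sample < 1 or self.read_length < 1:
            raise ValueError("n_replicates, reads_per_sample and read_length must be positive")

    @property
    def reference_timepoint(self) -> str:
        return self.timepoints[list(self.bulk_factors).index(1.0)]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_ortholog_transcriptomes(n_genes, length_range, divergence, seed):
    """Draw paired transcriptomes under the uniform-substitution model.

    Each spike ortholog is its focal sequence with every site independently
    replaced (by a uniformly chosen *different* base) with probability
    ``divergence``; substitution positions are recorded exactly.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError(f"invalid length_range {length_range}")
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must lie in [0, 1], got {divergence}")

    rng = _rng_for(seed, "transcriptomes")
    width = len(str(n_genes))
    genes = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        focal = rng.integers(0, 4, size=length)
        subs = np.flatnonzero(rng.random(length) < divergence)
        spike = focal.copy()
        # shift by 1..3 mod 4 => always a different base
        spike[subs] = (focal[subs] + rng.integers(1, 4, size=subs.size)) % 4
        genes.append(
            GenePair(
                gene_id=f"g{i:0{width}d}",
                focal_sequence=_BASES[focal].tobytes().decode(),
                spike_sequence=_BASES[spike].tobytes().decode(),
                substituted_positions=frozenset(int(p) for p in subs),
            )
        )
    return OrthologTranscriptomes(genes)


def simulate_sample_reads(
    transcriptomes: OrthologTranscriptomes,
    abundances,
    te_profile=None,
    bulk_factor: float = 1.0,
    spike_fraction: float = 0.02,
    n_reads: int = 200_000,
    read_length: int = 30,
    assay: str = "footprint",
    seed: int = 0,
    sample: str | None = None,
    timepoint: str = "",
    replicate: int = 0,
) -> ReadSet:
    """Draw one sample's reads.

    The spike RNA mass is held fixed across samples (as pipetted), calibrated
    so that at bulk_factor 1 a read is spike-derived with probability
    ``spike_fraction``.  Scaling focal translational output by ``bulk_factor``
    therefore changes the focal:spike read ratio in proportion — the signal
    the spike-in normalization recovers.  Within a species a gene is chosen
    proportionally to its abundance (times its relative translation rate for
    the footprint assay), and the read start is uniform over valid positions.
    """
    abundances = np.asarray(abundances, dtype=float)
    if abundances.shape != (len(transcriptomes),):
        raise ValueError("abundances must have one entry per gene")
    if np.any(abundances < 0) or not np.any(abundances > 0):
        raise ValueError("abundances must be non-negative and not all zero")
    if not 0.0 <= spike_fraction < 1.0:
        raise ValueError("spike_fraction must lie in [0, 1)")
    if bulk_factor <= 0:
        raise ValueError("bulk_factor must be positive")
    if assay not in ("footprint", "mrna"):
        raise ValueError(f"unknown assay {assay!r}")

    weights = abundances.copy()
    if assay == "footprint" and te_profile is not None:
        te = np.asarray(te_profile, dtype=float)
        if te.shape != weights.shape:
            raise ValueError("te_profile must have one entry per gene")
        weights = weights * te
    if not np.any(weights > 0):
        raise ValueError("gene sampling weights are all zero")

    lengths = transcriptomes.lengths
    selected = np.flatnonzero(weights > 0)
    short = selected[lengths[selected] < read_length]
    if short.size:
        gid = transcriptomes.genes[int(short[0])].gene_id
        raise ValueError(
            f"read_length {read_length} exceeds transcript length "
            f"{int(lengths[short[0]])} of gene {gid}"
        )

    sample = sample or f"{assay}_{timepoint or 't0'}_rep{replicate}"
    rng = _rng_for(seed, sample)

    # species choice: focal mass bulk_factor*1, spike mass r (calibrated at bulk 1)
    r = spike_fraction / (1.0 - spike_fraction)
    p_spike = r / (bulk_factor + r)
    is_spike = rng.random(n_reads) < p_spike

    p_gene = weights / weights.sum()
    gene_idx = rng.choice(len(weights), size=n_reads, p=p_gene)
    n_starts = lengths[gene_idx] - read_length + 1
    starts = np.floor(rng.random(n_reads) * n_starts).astype(np.int64)

    focal_seqs = [g.focal_sequence for g in transcriptomes.genes]
    spike_seqs = [g.spike_sequence for g in transcriptomes.genes]
    ids = transcriptomes.gene_ids
    sequences = [
        (spike_seqs if sp else focal_seqs)[g][s : s + read_length]
        for sp, g, s in zip(is_spike, gene_idx, starts)
    ]
    reads = pd.DataFrame(
        {
            "read_id": [f"{sample}:r{i:07d}" for i in range(n_reads)],
            "sequence": sequences,
            "true_species": np.where(is_spike, SPIKE, FOCAL),
            "true_gene": [ids[g] for g in gene_idx],
            "true_start": starts,
        }
    )
    return ReadSet(
        sample=sample,
        assay=assay,
        timepoint=timepoint,
        replicate=replicate,
        read_length=read_length,
        reads=reads,
    )


def _te_for(config: SimulationConfig, timepoint: str):
    te = config.te_profile
    if te is None:
        return None
    if isinstance(te, Mapping):
        return np.asarray(te[timepoint], dtype=float)
    return np.asarray(te, dtype=float)


@dataclass
class SimulatedExperiment:
    """Everything one run of the design produces, ground truth included."""

    read_sets: list
    sample_sheet: pd.DataFrame
    transcriptomes: OrthologTranscriptomes
    truth: dict

    def __iter__(self):  # (read_sets, sample_sheet, truth) unpacking
        return iter((self.read_sets, self.sample_sheet, self.truth))


def simulate_experiment(config: SimulationConfig) -> "SimulatedExperiment":
    """Run the full design: one footprint and one mRNA sample per
    (timepoint, replicate).

    Bulk factors apply to the footprint assay only; the mRNA assay keeps bulk
    factor 1.0 everywhere.  The returned object carries the read sets, the
    sample sheet, the transcriptomes, and a ``truth`` record of every latent
    parameter for recovery tests.
    """
    config.validate()
    tr = generate_ortholog_transcriptomes(
        config.n_genes, config.length_range, config.divergence, config.seed
    )
    rng = _rng_for(config.seed, "abundances")
    abundances = rng.lognormal(mean=0.0, sigma=config.abundance_shape, size=config.n_genes)

    read_sets, rows = [], []
    for timepoint, bulk in zip(config.timepoints, config.bulk_factors):
        for rep in range(1, config.n_replicates + 1):
            for assay in ("footprint", "mrna"):
                sample = f"{assay}_{timepoint}_rep{rep}"
                rs = simulate_sample_reads(
                    tr,
                    abundances,
                    te_profile=_te_for(config, timepoint) if assay == "footprint" else None,
                    bulk_factor=bulk if assay == "footprint" else 1.0,
                    spike_fraction=config.spike_fraction,
                    n_reads=config.reads_per_sample,
                    read_length=config.read_length,
                    assay=assay,
                    seed=config.seed,
                    sample=sample,
                    timepoint=timepoint,
                    replicate=rep,
                )
                read_sets.append(rs)
                rows.append(
                    {"sample": sample, "assay": assay, "timepoint": timepoint, "replicate": rep}
                )

    sample_sheet = pd.DataFrame(rows)
    truth = {
        "config": {
            k: (list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in asdict(config).items()
            if k != "te_profile"
        },
        "reference_timepoint": config.reference_timepoint,
        "gene_ids": tr.gene_ids,
        "abundances": abundances.tolist(),
        "bulk_factors": {t: b for t, b in zip(config.timepoints, config.bulk_factors)},
        "te_profile": (
            None
            if config.te_profile is None
            else {t: list(map(float, _te_for(config, t))) for t in config.timepoints}
        ),
    }
    return SimulatedExperiment(read_sets, sample_sheet, tr, truth)


# ---------------------------------------------------------------------------
# hatch-rate decay data
# ---------------------------------------------------------------------------

def simulate_hatch_data(h0, slope, t50, days, n_eggs, seed=0) -> pd.DataFrame:
    """Binomial hatch counts along a logistic viability decay.

    Hatch probability p(t) = h0 / (1 + exp(slope*(t - t50))): an initial
    plateau h0 (fresh oocytes hatch at 90–96%, not 100%), a temperature-
    dependent half-life t50 in days, and decay to zero.
    """
    if not 0.0 < h0 <= 1.0:
        raise ValueError("h0 must lie in (0, 1]")
    if slope <= 0 or t50 <= 0:
        raise ValueError("slope and t50 must be positive")
    days = np.asarray(days, dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    if np.any(days < 0):
        raise ValueError("days must be non-negative")
    n_eggs = np.broadcast_to(np.asarray(n_eggs, dtype=int), days.shape)
    if np.any(n_eggs <= 0):
        raise ValueError("n_eggs must be positive")
    rng = _rng_for(seed, "hatch", round(float(t50), 6))
    p = hatch_probability(days, h0, slope, t50)
    return pd.DataFrame(
        {"day": days, "n_eggs": n_eggs, "n_hatched": rng.binomial(n_eggs, p)}
    )


def hatch_probability(t, h0, slope, t50):
    """Three-parameter logistic decay evaluated at storage day(s) t."""
    return h0 / (1.0 + np.exp(np.asarray(slope) * (np.asarray(t, dtype=float) - t50)))


# ---------------------------------------------------------------------------
# count-level replicate generator (for statistics-layer tests)
# ---------------------------------------------------------------------------

def replicate_table(mean_levels, n_replicates, log2_sd, seed, prefix="rep"):
    """Replicate expression table with multiplicative (log-normal) noise.

    Used to exercise the differential-translation statistics directly at the
    table level, where read sampling is not the object under test.  Returns a
    genes x replicates DataFrame whose entries are
    mean * 2**Normal(0, log2_sd).
    """
    mean_levels = pd.Series(mean_levels) if not isinstance(mean_levels, pd.Series) else mean_levels
    rng = _rng_for(seed, "replicates", prefix)
    noise = rng.normal(0.0, log2_sd, size=(len(mean_levels), n_replicates))
    data = mean_levels.values[:, None] * np.exp2(noise)
    return pd.DataFrame(
        data, index=mean_levels.index, columns=[f"{prefix}{i+1}" for i in range(n_replicates)]
    )


def orthologs_from_sequences(focal: Mapping, spike: Mapping) -> OrthologTranscriptomes:
    """Rebuild paired transcriptomes from two id-matched sequence mappings,
    recovering substituted positions from the per-site differences."""
    if set(focal) != set(spike):
        raise ValueError("focal and spike FASTA record ids do not match")
    genes = []
    for gene_id in focal:
        f, s = focal[gene_id], spike[gene_id]
        if len(f) != len(s):
            raise ValueError(f"{gene_id}: ortholog sequences differ in length")
        subs = frozenset(i for i, (a, b) in enumerate(zip(f, s)) if a != b)
        genes.append(GenePair(gene_id, f, s, subs))
    genes.sort(key=lambda g: g.gene_id)
    return OrthologTranscriptomes(genes)


def truth_to_json(truth: dict) -> str:
    return json.dumps(truth, indent=2, sort_keys=True)


def truth_from_json(text: str) -> dict:
    return json.loads(text)
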