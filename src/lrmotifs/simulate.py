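"""Generative machinery: Markov backgrounds and planted-motif datasets.

The planted-motif model mirrors the benchmark's synthetic study: clusters of
background DNA drawn i.i.d. with a fixed GC fraction (0.4 by default, the
yeast-like setting), with one PWM-sampled motif instance overwriting a
uniformly chosen position of every member sequence, on the forward strand.
Ground-truth plant positions are returned so Bayes-optimal bounds and
recovery rates can be computed.

The module also fits and samples r-th order Markov chains (the generative
null models whose shortcomings the diagnostics quantify) and draws disjoint
random clusters from a pool for null-calibration experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .pwm import PositionWeightMatrix
from .seqcore import ClusterCollection, DnaSequence, SequenceCluster, decode

_BASES = np.arange(4, dtype=np.int8)


def _context_index(codes: np.ndarray, r: int) -> np.ndarray:
    """Base-4 integer index of each r-mer context (windows with N -> -1)."""
    if r == 0:
        return np.zeros(max(len(codes), 1), dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, r)
    powers = 4 ** np.arange(r - 1, -1, -1)
    idx = (win * powers).sum(axis=1)
    idx[(win == 4).any(axis=1)] = -1
    return idx


@dataclass
class MarkovModel:
    """An r-th order Markov chain over A/C/G/T with pseudocount smoothing."""

    order: int
    context_counts: np.ndarray  # (4^r, 4) successor counts
    initial_counts: np.ndarray  # (4^r,) sequence-initial r-mer counts
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        k = 4**self.order
        self.context_counts = np.asarray(self.context_counts, dtype=float).reshape(k, 4)
        self.initial_counts = np.asarray(self.initial_counts, dtype=float).reshape(k)

    @property
    def conditional_probs(self) -> np.ndarray:
        aug = self.context_counts + self.pseudocount
        return aug / aug.sum(axis=1, keepdims=True)

    @property
    def initial_probs(self) -> np.ndarray:
        aug = self.initial_counts + self.pseudocount
        return aug / aug.sum()


def fit_markov(
    seqs: Sequence[DnaSequence], r: int, pseudocount: float = 1.0
) -> MarkovModel:
    """Tally all N-free (r+1)-windows into an r-th order Markov model."""
    if r < 0:
        raise ValueError("order must be >= 0")
    if not seqs:
        raise ValueError("no sequences to fit")
    if sum(len(s) for s in seqs) <= r:
        raise ValueError("total sequence length must exceed the order")
    k = 4**r
    counts = np.zeros((k, 4))
    initial = np.zeros(k)
    for s in seqs:
        codes = s.encoded()
        if len(codes) < r + 1:
            continue
        if r == 0:
            ctx = np.zeros(len(codes), dtype=np.int64)
        else:
            ctx = _context_index(codes[:-1], r)[: len(codes) - r]
        succ = codes[r:]
        ok = (ctx >= 0) & (succ < 4)
        np.add.at(counts, (ctx[ok], succ[ok]), 1)
        first = _context_index(codes[: max(r, 1)], r)[0]
        if first >= 0:
            initial[first] += 1
    return MarkovModel(r, counts, initial, pseudocount)


def iid_model(gc_fraction: float, pseudocount: float = 0.0) -> MarkovModel:
    """Order-0 model with P(C)=P(G)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    base = np.array([[at, gc, gc, at]]) * 1e6  # counts proportional to probs
    return MarkovModel(0, base, np.ones(1), pseudocount)


def background_probs(gc_fraction: float) -> np.ndarray:
    """The i.i.d. base distribution (A, C, G, T) at a given GC fraction."""
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    return np.array([at, gc, gc, at])


def sample_markov(
    model: MarkovModel, length: int, rng: np.random.Generator
) -> DnaSequence:
    """Sample one sequence: initial r-mer, then chained conditionals."""
    if length < 1:
        raise ValueError("length must be >= 1")
    r = model.order
    if r == 0:
        p = model.conditional_probs[0]
        codes = rng.choice(4, size=length, p=p).astype(np.int8)
        return DnaSequence("markov", decode(codes))
    init = int(rng.choice(4**r, p=model.initial_probs))
    prefix = [(init >> (2 * (r - 1 - j))) & 3 for j in range(r)]
    codes = np.empty(length, dtype=np.int8)
    m = min(r, length)
    codes[:m] = prefix[:m]
    cond = model.conditional_probs
    ctx = init
    mask = 4**r
    for i in range(r, length):
        b = int(rng.choice(4, p=cond[ctx]))
        codes[i] = b
        ctx = (ctx * 4 + b) % mask
    return DnaSequence("markov", decode(codes))


def sample_iid_background(
    gc_fraction: float, length: int, rng: np.random.Generator
) -> DnaSequence:
    """Independent-nucleotide background at the given GC fraction."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    codes = rng.choice(4, size=length, p=background_probs(gc_fraction)).astype(np.int8)
    return DnaSequence("background", decode(codes))


def sample_pwm_instance(M: PositionWeightMatrix, rng: np.random.Generator) -> str:
    """One motif instance: an independent draw from each PWM column."""
    probs = M.probs
    codes = np.array(
        [rng.choice(4, p=probs[:, j]) for j in range(M.width)], dtype=np.int8
    )
    return decode(codes)


def random_peaked_pfm(
    width: int,
    rng: np.random.Generator,
    dominance: float = 0.9,
    total_count: int = 100,
    name: str = "",
) -> PositionWeightMatrix:
    """A synthetic PFM with one dominant base per column.

    Emulates the shape of curated transcription-factor matrices built from
    on the order of a hundred aligned sites: a random consensus whose base
    carries a ``dominance`` fraction of each column's ``total_count``
    observations, the remainder spread over the other bases.  With the
    defaults the probability view puts ~0.87 on the consensus base
    (~1.1 bits per column), a sharply peaked motif.
    """
    if not 0.25 <= dominance <= 1.0:
        raise ValueError("dominance must lie in [0.25, 1]")
    consensus = rng.integers(0, 4, size=width)
    counts = np.full((4, width), total_count * (1.0 - dominance) / 3.0)
    counts[consensus, np.arange(width)] = total_count * dominance
    return PositionWeightMatrix(counts, pseudocount=1.0, name=name or "synthetic_pfm")


@dataclass
class PlantConfig:
    """Parameters of one planted-motif dataset."""

    pfms: list[PositionWeightMatrix]
    cluster_sizes: list[int]
    sequence_length: int = 800
    gc_fraction: float = 0.4
    seed: int = 0
    reuse_pfms: bool = True  # draw with replacement once the list is exhausted

    def __post_init__(self) -> None:
        if not self.pfms:
            raise ValueError("at least one PFM is required")
        if any(n < 1 for n in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 1")
        too_wide = [m.name for m in self.pfms if m.width > self.sequence_length]
        if too_wide:
            raise ValueError(f"PFM(s) wider than the sequences: {too_wide}")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie in (0, 1)")


@dataclass
class PlantRecord:
    """Ground truth for one planted instance (0-based offset, + strand)."""

    cluster_id: str
    sequence_id: str
    pwm_name: str
    offset: int
    strand: str = "+"


def generate_planted_dataset(
    config: PlantConfig,
) -> tuple[ClusterCollection, list[PlantRecord], dict[str, PositionWeightMatrix]]:
    """Planted-motif clusters with ground truth.

    One PWM is assigned per cluster — without replacement while the list
    lasts, then with replacement.  Every member sequence is i.i.d.
    background with one sampled instance overwriting a uniformly chosen
    offset in [0, L - w] on the forward strand.  Returns the collection, the
    plant records, and the cluster_id -> true PWM map.
    """
    root = np.random.SeedSequence(config.seed)
    rng_assign = np.random.default_rng(root.spawn(1)[0])
    n_clusters = len(config.cluster_sizes)
    order = rng_assign.permutation(len(config.pfms))
    assigned: list[PositionWeightMatrix] = []
    for k in range(n_clusters):
        if k < len(order):
            assigned.append(config.pfms[order[k]])
        elif config.reuse_pfms:
            assigned.append(config.pfms[rng_assign.integers(len(config.pfms))])
        else:
            raise ValueError("more clusters than PFMs with reuse_pfms=False")

    clusters: list[SequenceCluster] = []
    records: list[PlantRecord] = []
    true_pwms: dict[str, PositionWeightMatrix] = {}
    L = config.sequence_length
    streams = root.spawn(1 + n_clusters)[1:]
    for k, (size, pwm, stream) in enumerate(zip(config.cluster_sizes, assigned, streams)):
        rng = np.random.default_rng(stream)
        cid = f"cluster{k + 1:02d}"
        true_pwms[cid] = pwm
        members: list[DnaSequence] = []
        w = pwm.width
        for i in range(size):
            sid = f"{cid}_seq{i + 1:03d}"
            bg = sample_iid_background(config.gc_fraction, L, rng)
            offset = int(rng.integers(0, L - w + 1))
            instance = sample_pwm_instance(pwm, rng)
            residues = bg.residues[:offset] + instance + bg.residues[offset + w :]
            members.append(DnaSequence(sid, residues))
            records.append(PlantRecord(cid, sid, pwm.name, offset, "+"))
        clusters.append(SequenceCluster(cid, members))
    return ClusterCollection(clusters), records, true_pwms


def generate_null_clusters(
    pool: Sequence[DnaSequence], sizes: Sequence[int], rng: np.random.Generator
) -> ClusterCollection:
    """Mutually disjoint random clusters drawn without replacement."""
    total = int(sum(sizes))
    if total > len(pool):
        raise ValueError(f"requested {total} sequences from a pool of {len(pool)}")
    idx = rng.permutation(len(pool))[:total]
    clusters = []
    start = 0
    for k, size in enumerate(sizes):
        members = [pool[i] for i in idx[start : start + size]]
        clusters.append(SequenceCluster(f"null{k + 1:02d}", members))
        start += size
    return ClusterCollection(clusters)


def write_plant_records(records: Sequence[PlantRecord], path) -> None:
    """Plant records as TSV with 1-based offsets."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tcluster_id\tpwm_name\toffset_1based\tstrand\n")
        for r in records:
            fh.write(f"{r.sequence_id}\t{r.cluster_id}\t{r.pwm_name}\t{r.offset + 1}\t{r.strand}\n")
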