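"""Holdout classification benchmark for discovered (or true) motifs.

Protocol, per foreground cluster: split the cluster into equal train and
validation halves; draw 200 background sequences (100 train, 100
validation) from the union of all other clusters, excluding any id present
in the foreground; discover a motif on the training halves (or take the
supplied true PWM); score validation sequences and compute AUROC.  Scoring
the training sequences themselves gives the resubstitution AUROC, whose
excess over holdout measures overfitting.  Summaries also stratify holdout
AUROC by whether the discovered motif was significant at the FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .discovery import alr_discover, discover_multi_width, lr_discover
from .pwm import PositionWeightMatrix, pwm_score_values
from .seqcore import ClusterCollection, DnaSequence, SequenceCluster

METHODS = ("lr", "alr", "true_pwm")


def auroc(positive_scores: Sequence[float], negative_scores: Sequence[float]) -> float:
    """Area under the ROC curve (Mann-Whitney with midrank ties)."""
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(labels, np.concatenate([pos, neg])))


def split_cluster(
    cluster: SequenceCluster, fraction: float, rng: np.random.Generator
) -> tuple[SequenceCluster, SequenceCluster]:
    """Random disjoint, exhaustive split; train takes the ceiling on odd n."""
    n = len(cluster)
    if n < 2:
        raise ValueError("cannot split a singleton cluster")
    n_train = int(np.ceil(n * fraction))
    idx = rng.permutation(n)
    train = [cluster.members[i] for i in sorted(idx[:n_train])]
    test = [cluster.members[i] for i in sorted(idx[n_train:])]
    return (
        SequenceCluster(f"{cluster.cluster_id}_train", train),
        SequenceCluster(f"{cluster.cluster_id}_test", test),
    )


def sample_background(
    collection: ClusterCollection,
    foreground_id: str,
    total: int,
    rng: np.random.Generator,
) -> tuple[SequenceCluster, SequenceCluster]:
    """total/2 + total/2 background sequences from the other clusters.

    Drawn without replacement from the union of non-foreground clusters,
    with any sequence id that also appears in the foreground excluded.
    """
    fg_ids = set(collection.get(foreground_id).member_ids())
    pool: list[DnaSequence] = []
    seen: set[str] = set()
    for cl in collection:
        if cl.cluster_id == foreground_id:
            continue
        for s in cl.members:
            if s.id not in fg_ids and s.id not in seen:
                seen.add(s.id)
                pool.append(s)
    if len(pool) < total:
        raise ValueError(f"background pool of {len(pool)} < requested {total}")
    idx = rng.permutation(len(pool))[:total]
    half = total // 2
    train = [pool[i] for i in idx[:half]]
    test = [pool[i] for i in idx[half:]]
    return (
        SequenceCluster("background_train", train),
        SequenceCluster("background_test", test),
    )


@dataclass
class BenchmarkConfig:
    """Knobs of the holdout benchmark (defaults follow the study protocol)."""

    min_cluster_size: int = 10
    max_cluster_size: int = 200
    background_total: int = 200
    split_fraction: float = 0.5
    widths: tuple[int, ...] = (12,)
    m: int = 5
    stride: int = 1
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_total % 2:
            raise ValueError("background_total must be even (half train, half test)")
        if not self.widths:
            raise ValueError("at least one width is required")


@dataclass
class ClusterResult:
    cluster_id: str
    auroc_holdout: float
    auroc_resub: float
    q_value: float | None
    significant: bool | None
    n_train: int
    n_test: int


@dataclass
class BenchmarkSummary:
    per_cluster: list[ClusterResult]
    mean_auroc_holdout: float
    mean_auroc_resub: float
    mean_auroc_by_significance: tuple[float | None, float | None]
    method: str
    config: BenchmarkConfig = field(repr=False)

    def to_dict(self) -> dict:
        strat = self.mean_auroc_by_significance
        return {
            "method": self.method,
            "n_clusters": len(self.per_cluster),
            "mean_auroc_holdout": self.mean_auroc_holdout,
            "mean_auroc_resub": self.mean_auroc_resub,
            "mean_auroc_nonsignificant": strat[0],
            "mean_auroc_significant": strat[1],
        }


def _subsample(
    cluster: SequenceCluster, max_size: int, rng: np.random.Generator
) -> SequenceCluster:
    if len(cluster) <= max_size:
        return cluster
    idx = sorted(rng.permutation(len(cluster))[:max_size])
    return SequenceCluster(cluster.cluster_id, [cluster.members[i] for i in idx])


def run_benchmark(
    collection: ClusterCollection,
    method: str,
    config: BenchmarkConfig,
    true_pwms: Mapping[str, PositionWeightMatrix] | None = None,
) -> BenchmarkSummary:
    """The full per-cluster holdout benchmark for one scoring method.

    ``method`` is "lr", "alr" (discovery on the training halves) or
    "true_pwm" (the planted PWM, the theoretical upper bound; requires
    ``true_pwms``).  The same root seed drives every split and background
    draw, so methods run with the same config are paired.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if method == "true_pwm" and true_pwms is None:
        raise ValueError("method='true_pwm' requires the true_pwms mapping")

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(collection.clusters))
    results: list[ClusterResult] = []
    for cluster, stream in zip(collection, streams):
        if len(cluster) < config.min_cluster_size:
            continue
        rng = np.random.default_rng(stream)
        fg = _subsample(cluster, config.max_cluster_size, rng)
        fg_train, fg_test = split_cluster(fg, config.split_fraction, rng)
        bg_train, bg_test = sample_background(
            collection, cluster.cluster_id, config.background_total, rng
        )

        q: float | None = None
        if method == "true_pwm":
            pwm = true_pwms[cluster.cluster_id]
            score = lambda seqs: pwm_score_values(pwm, seqs)  # noqa: E731
        else:
            m = config.m if method == "alr" else None
            if len(config.widths) == 1:
                w = config.widths[0]
                res = (
                    lr_discover(fg_train, bg_train, w, config.stride)
                    if method == "lr"
                    else alr_discover(fg_train, bg_train, w, config.m, config.stride)
                )
            else:
                res = discover_multi_width(
                    fg_train, bg_train, config.widths, m=m, stride=config.stride
                )
            q = res.best.q_value
            score = res.score

        hold = auroc(score(fg_test.members), score(bg_test.members))
        resub = auroc(score(fg_train.members), score(bg_train.members))
        results.append(
            ClusterResult(
                cluster_id=cluster.cluster_id,
                auroc_holdout=hold,
                auroc_resub=resub,
                q_value=q,
                significant=None if q is None else bool(q <= config.fdr_threshold),
                n_train=len(fg_train),
                n_test=len(fg_test),
            )
        )
    if not results:
        raise ValueError("no cluster met the minimum size requirement")

    hold_mean = float(np.mean([r.auroc_holdout for r in results]))
    resub_mean = float(np.mean([r.auroc_resub for r in results]))
    nonsig = [r.auroc_holdout for r in results if r.significant is False]
    sig = [r.auroc_holdout for r in results if r.significant is True]
    strat = (
        float(np.mean(nonsig)) if nonsig else None,
        float(np.mean(sig)) if sig else None,
    )
    return BenchmarkSummary(
        per_cluster=results,
        mean_auroc_holdout=hold_mean,
        mean_auroc_resub=resub_mean,
        mean_auroc_by_significance=strat,
        method=method,
        config=config,
    )


def format_summary(summary: BenchmarkSummary) -> str:
    """Tables-style text rendering of a benchmark summary."""
    lines = [
        f"method: {summary.method}   clusters: {len(summary.per_cluster)}",
        f"mean AUROC (holdout):        {summary.mean_auroc_holdout:.3f}",
        f"mean AUROC (resubstitution): {summary.mean_auroc_resub:.3f}",
    ]
    nonsig, sig = summary.mean_auroc_by_significance
    if nonsig is not None or sig is not None:
        fmt = lambda v: "--" if v is None else f"{v:.3f}"  # noqa: E731
        lines.append(
            f"mean holdout AUROC non-significant/significant "
            f"(FDR {summary.config.fdr_threshold:g}): {fmt(nonsig)}/{fmt(sig)}"
        )
    return "\n".join(lines)
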