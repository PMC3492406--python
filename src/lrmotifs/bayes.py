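"""Exact posterior and Bayes-optimal accuracy for the planted-motif model.

Because the simulator generates every background nucleotide independently
and samples the planted instance column-independently, the naive-Bayes
factorization is exact and the classifier below is Bayes optimal: its
accuracy is the ceiling no discovery method can beat on the same data.

The likelihood of a sequence under "cluster k planted its motif somewhere
in S" marginalizes the (uniform) plant position:

    P(S | k) ∝ sum_p  [ prod_j P_k(S[p+j], j) ] * [ prod_{i not in window} b(S[i]) ]

computed in log space via log-sum-exp.  Cluster priors are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .pwm import PositionWeightMatrix, pwm_score
from .seqcore import ClusterCollection, DnaSequence


@dataclass
class BayesModel:
    """True planted PWMs per cluster plus the background base distribution."""

    pwms: Mapping[str, PositionWeightMatrix]
    background: np.ndarray  # P(A), P(C), P(G), P(T)

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,):
            raise ValueError("background must be a 4-vector over A,C,G,T")
        if (self.background <= 0).any():
            raise ValueError("background probabilities must be positive")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")


def _log_background(codes: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-residue log background probability; N contributes log 0.25."""
    table = np.concatenate([np.log(b), [np.log(0.25)]])
    return table[codes]


def planted_log_likelihood(
    S: DnaSequence | str,
    M: PositionWeightMatrix,
    background: np.ndarray,
    both_strands: bool = False,
) -> float:
    """log P(S | motif M planted at a uniform position), up to the prior.

    Sum over plant positions of (motif window probability) x (background
    probability of the remaining residues), in log space.  With
    ``both_strands`` the sum also runs over reverse-complement placements
    (a sensitivity variant; the simulator plants forward-only).
    """
    from .seqcore import encode

    codes = S.encoded() if isinstance(S, DnaSequence) else encode(S)
    w = M.width
    if len(codes) < w:
        raise ValueError(f"sequence length {len(codes)} < motif width {w}")
    b = np.asarray(background, dtype=float)
    log_b = _log_background(codes, b)
    total_bg = log_b.sum()
    table = M.log_prob_lookup()  # 5 x w, N row = log 0.25
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    motif_ll = table[win, np.arange(w)].sum(axis=1)
    bg_in_window = np.lib.stride_tricks.sliding_window_view(log_b, w).sum(axis=1)
    terms = total_bg + motif_ll - bg_in_window
    if both_strands:
        rc_codes = codes[::-1].copy()
        real = rc_codes < 4
        rc_codes[real] = 3 - rc_codes[real]
        log_b_rc = _log_background(rc_codes, b)
        win_rc = np.lib.stride_tricks.sliding_window_view(rc_codes, w)
        motif_rc = table[win_rc, np.arange(w)].sum(axis=1)
        bg_rc = np.lib.stride_tricks.sliding_window_view(log_b_rc, w).sum(axis=1)
        terms = np.concatenate([terms, total_bg + motif_rc - bg_rc]) - np.log(2.0)
    return float(logsumexp(terms))


def planted_likelihood(
    S: DnaSequence | str,
    M: PositionWeightMatrix,
    background: np.ndarray,
    both_strands: bool = False,
) -> float:
    """exp of :func:`planted_log_likelihood` (underflows for long S)."""
    return float(np.exp(planted_log_likelihood(S, M, background, both_strands)))


def _log_posteriors(
    S: DnaSequence, model: BayesModel, both_strands: bool = False
) -> tuple[list[str], np.ndarray]:
    cids = list(model.pwms)
    lls = np.array(
        [
            planted_log_likelihood(S, model.pwms[c], model.background, both_strands)
            for c in cids
        ]
    )
    return cids, lls


def bayes_classify(
    S: DnaSequence,
    model: BayesModel,
    rng: np.random.Generator | None = None,
    both_strands: bool = False,
) -> str:
    """argmax-posterior cluster under equal priors.

    Exact ties are broken uniformly at random when an rng is supplied,
    otherwise toward the first tied cluster in mapping order.
    """
    cids, lls = _log_posteriors(S, model, both_strands)
    tied = np.flatnonzero(lls >= lls.max() - 1e-12)
    if len(tied) > 1 and rng is not None:
        return cids[int(rng.choice(tied))]
    return cids[int(tied[0])]


def multiclass_bayes_accuracy(
    collection: ClusterCollection,
    model: BayesModel,
    both_strands: bool = False,
) -> float:
    """Expected accuracy of the Bayes classifier on labeled sequences.

    A tie among T clusters containing the true one counts 1/T, so the
    result is deterministic.
    """
    correct = 0.0
    n = 0
    for cluster in collection:
        for s in cluster.members:
            cids, lls = _log_posteriors(s, model, both_strands)
            tied = np.flatnonzero(lls >= lls.max() - 1e-12)
            if cluster.cluster_id in {cids[i] for i in tied}:
                correct += 1.0 / len(tied)
            n += 1
    if n == 0:
        raise ValueError("empty collection")
    return correct / n


def write_bayes_report(
    collection: ClusterCollection,
    model: BayesModel,
    tsv_path,
    json_path=None,
    both_strands: bool = False,
) -> float:
    """Per-sequence TSV (true cluster, prediction, log-posterior margin)
    plus an optional JSON summary; returns the expected accuracy."""
    import json

    correct = 0.0
    n = 0
    with open(tsv_path, "w") as fh:
        fh.write("sequence_id\ttrue_cluster\tpredicted_cluster\tlog_posterior_margin\n")
        for cluster in collection:
            for s in cluster.members:
                cids, lls = _log_posteriors(s, model, both_strands)
                order = np.argsort(lls)[::-1]
                margin = float(lls[order[0]] - lls[order[1]]) if len(lls) > 1 else np.inf
                tied = np.flatnonzero(lls >= lls.max() - 1e-12)
                if cluster.cluster_id in {cids[i] for i in tied}:
                    correct += 1.0 / len(tied)
                fh.write(
                    f"{s.id}\t{cluster.cluster_id}\t{cids[int(tied[0])]}\t{margin:.6g}\n"
                )
                n += 1
    accuracy = correct / n
    if json_path is not None:
        payload = {"n_sequences": n, "bayes_accuracy": accuracy}
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    return accuracy


def pwm_argmax_accuracy(
    collection: ClusterCollection, pwms: Mapping[str, PositionWeightMatrix]
) -> float:
    """Baseline: classify by the cluster whose PWM best window score wins.

    A plug-in comparator for the Bayes bound — it scores only the single
    best window instead of marginalizing over plant positions.
    """
    cids = list(pwms)
    correct = 0.0
    n = 0
    for cluster in collection:
        for s in cluster.members:
            scores = np.array([np.log(pwm_score(pwms[c], s).value) for c in cids])
            tied = np.flatnonzero(scores >= scores.max() - 1e-12)
            if cluster.cluster_id in {cids[i] for i in tied}:
                correct += 1.0 / len(tied)
            n += 1
    return correct / n
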