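"""Diagnostics showing that generative background models are "too null".

Two complementary checks:

* The A/T-fraction overdispersion test.  Fit a single Markov model to a
  pool of real sequences, then ask whether the observed A/T fraction of
  each sequence deviates from what the model predicts for a sequence of
  that length, in units of the model's own Monte-Carlo standard deviation.
  If one model truly described all the sequences, the Z-scores would be
  approximately standard normal; heavy tails / inflated spread mean the
  pool is more heterogeneous than any single chain allows.

* The dimer ANOVA.  For each of the 10 reverse-complement-collapsed dimer
  classes, regress per-sequence dimer fractions on cluster membership and
  report the fraction of variance explained (R^2 = SSB/SST) with its
  one-way-ANOVA F-test p-value.  Nonzero R^2 across expression or binding
  clusters means low-order composition itself carries cluster information
  that a homogeneous background model ignores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .seqcore import ClusterCollection, DnaSequence, collapsed_classes, spectrum_profile
from .simulate import MarkovModel, sample_markov


def at_fraction(S: DnaSequence | str) -> float:
    """(#A + #T) / (#non-N residues)."""
    residues = S.residues if isinstance(S, DnaSequence) else S.upper()
    n_valid = sum(1 for b in residues if b != "N")
    if n_valid == 0:
        raise ValueError("all-N sequence: A/T fraction undefined")
    return sum(1 for b in residues if b in "AT") / n_valid


@dataclass
class AtFractionReport:
    """Per-sequence Z-scores of A/T fraction against a fitted Markov model."""

    per_sequence: pd.DataFrame  # sequence_id, length, observed, mean, sd, z, flagged
    replicates: int
    model_order: int

    @property
    def z_scores(self) -> np.ndarray:
        ok = ~self.per_sequence["flagged"]
        return self.per_sequence.loc[ok, "z_score"].to_numpy()

    @property
    def z_mean(self) -> float:
        return float(self.z_scores.mean())

    @property
    def z_sd(self) -> float:
        return float(self.z_scores.std(ddof=1))


def at_overdispersion_test(
    real_seqs: Sequence[DnaSequence],
    model: MarkovModel,
    B: int = 200,
    min_length: int = 100,
    rng: np.random.Generator | None = None,
) -> AtFractionReport:
    """Monte-Carlo Z-scores of observed A/T fraction under a Markov model.

    Sequences shorter than ``min_length`` are dropped.  For each remaining
    length, B synthetic sequences of that length are sampled from the model
    and their A/T fractions give the null mean and sd (shared across real
    sequences of equal length).  Entries with sd = 0 are flagged and
    excluded from the summary.
    """
    if B < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng() if rng is None else rng
    kept = [s for s in real_seqs if len(s) >= min_length]
    if not kept:
        raise ValueError(f"no sequences of length >= {min_length}")
    null_stats: dict[int, tuple[float, float]] = {}
    for L in sorted({len(s) for s in kept}):
        fracs = np.array([at_fraction(sample_markov(model, L, rng)) for _ in range(B)])
        null_stats[L] = (float(fracs.mean()), float(fracs.std(ddof=1)))
    rows = []
    for s in kept:
        mu, sd = null_stats[len(s)]
        obs = at_fraction(s)
        flagged = sd == 0.0
        rows.append(
            {
                "sequence_id": s.id,
                "length": len(s),
                "observed_fraction": obs,
                "model_mean": mu,
                "model_sd": sd,
                "z_score": np.nan if flagged else (obs - mu) / sd,
                "flagged": flagged,
            }
        )
    return AtFractionReport(pd.DataFrame(rows), B, model.order)


@dataclass
class DimerAnovaReport:
    """Variance in dimer fractions explained by cluster membership."""

    per_class: pd.DataFrame  # class, r_squared, f_statistic, p_value

    def as_dict(self) -> dict[str, tuple[float, float, float]]:
        return {
            row["class"]: (row["r_squared"], row["f_statistic"], row["p_value"])
            for _, row in self.per_class.iterrows()
        }


def dimer_variance_explained(collection: ClusterCollection) -> DimerAnovaReport:
    """One-way ANOVA of collapsed dimer fractions across clusters.

    For each of the 10 classes: R^2 = SSB/SST and
    F = (SSB/(K-1)) / (SSW/(n-K)) with its upper-tail p-value.  A class
    with zero total variance reports R^2 = 0, p = 1.
    """
    clusters = collection.clusters
    if len(clusters) < 2 or any(len(c) < 2 for c in clusters):
        raise ValueError("need >= 2 clusters with >= 2 members each")
    classes = collapsed_classes(2)
    values: list[np.ndarray] = []
    groups: list[int] = []
    for k, cl in enumerate(clusters):
        for s in cl.members:
            prof = spectrum_profile(s, 2)
            values.append(np.array([prof.fractions[c] for c in classes]))
            groups.append(k)
    X = np.vstack(values)  # n x 10
    g = np.asarray(groups)
    n, K = X.shape[0], len(clusters)
    grand = X.mean(axis=0)
    sst = ((X - grand) ** 2).sum(axis=0)
    ssb = np.zeros_like(sst)
    for k in range(K):
        sub = X[g == k]
        ssb += len(sub) * (sub.mean(axis=0) - grand) ** 2
    ssw = sst - ssb
    rows = []
    for j, cls in enumerate(classes):
        if sst[j] <= 0:
            rows.append({"class": cls, "r_squared": 0.0, "f_statistic": 0.0, "p_value": 1.0})
            continue
        r2 = float(ssb[j] / sst[j])
        if ssw[j] <= 0:
            fstat, p = np.inf, 0.0
        else:
            fstat = float((ssb[j] / (K - 1)) / (ssw[j] / (n - K)))
            p = float(f_dist.sf(fstat, K - 1, n - K))
        rows.append({"class": cls, "r_squared": r2, "f_statistic": fstat, "p_value": p})
    return DimerAnovaReport(pd.DataFrame(rows))
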