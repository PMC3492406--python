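"""Discriminative motif discovery by logistic-regression likelihood-ratio tests.

The LR algorithm: every N-free width-w window of every foreground sequence is
a candidate core motif c.  For each candidate, label foreground sequences
Y=1 and background sequences Y=0 (the candidate's own source sequence is
left out of the test to avoid selection bias), regress Y on the mismatch
statistic D_c(S), and compare against an intercept-only null by Wilks'
theorem: Lambda = 2(l1 - l0) is asymptotically chi-square with 1 df.  The
family of p-values is converted to q-values by Benjamini-Hochberg, the most
significant core is kept, and a seed PWM is built from the foreground
windows that match it better than the median background sequence does.

The ALR (adjusted LR) variant conditions on low-order bulk composition: the
null model additionally contains the m reverse-complement-collapsed
spectrum-kernel features that are individually most predictive, so a core is
only called significant if it adds information beyond mono/dimer
composition.  Its final decision rule is a logistic model on the spectrum
features plus the seed-PWM score.

All candidate fits run through one vectorized Newton solver; the public
`fit_logistic` is the same algorithm on a single design and is what the
reported fits come from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .mismatch import CoreMotif, batch_min_distances, min_distance_in_sequence
from .pwm import PositionWeightMatrix, build_pwm, pwm_score_values
from .seqcore import (
    SPECTRUM_CLASSES,
    DnaSequence,
    SequenceCluster,
    encode,
    reverse_complement_codes,
    spectrum_feature_matrix,
)

_BETA_CAP = 30.0  # coefficient clamp under perfect separation
_LL_TOL = 1e-8
_MAX_ITER = 100


class DegenerateLabelsError(ValueError):
    """Slope model requested but the labels contain a single class."""


class FitFailureError(RuntimeError):
    """The alternative fit is worse than its nested null beyond tolerance."""


@dataclass
class LogisticFit:
    """A maximum-likelihood logistic fit (intercept always first)."""

    coef: np.ndarray
    feature_names: list[str]
    log_likelihood: float
    converged: bool
    separated: bool
    n_iter: int
    n_obs: int

    @property
    def n_params(self) -> int:
        return len(self.coef)

    def predict_proba(self, X: np.ndarray | None) -> np.ndarray:
        """P(Y=1) for rows of X (X excludes the intercept column)."""
        if X is None:
            X = np.empty((1, 0))
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return expit(self.coef[0] + X @ self.coef[1:])


@dataclass
class CandidateTest:
    core: CoreMotif
    lambda_stat: float
    p_value: float
    q_value: float


@dataclass
class DiscoveryResult:
    """Outcome of one LR discovery run on a foreground/background pair."""

    best: CandidateTest
    seed_sequences: list[str]
    pwm: PositionWeightMatrix
    width: int
    null_fit: LogisticFit
    alt_fit: LogisticFit
    candidates: pd.DataFrame = field(repr=False)

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    def score(self, seqs: Sequence[DnaSequence]) -> np.ndarray:
        """Classifier score per sequence: the seed-PWM window score F(S)."""
        return pwm_score_values(self.pwm, seqs)


@dataclass
class AlrResult(DiscoveryResult):
    """ALR outcome: adds selected bulk features and the combined model."""

    selected_features: list[str] = field(default_factory=list)
    final_model: LogisticFit | None = None

    def score(self, seqs: Sequence[DnaSequence]) -> np.ndarray:
        """Predicted probability of the combined spectrum + PWM-score model."""
        X = _selected_spectrum_matrix(seqs, self.selected_features)
        f = pwm_score_values(self.pwm, seqs)
        return self.final_model.predict_proba(np.column_stack([X, f]))


# ---------------------------------------------------------------------------
# Logistic fitting


def _batch_newton(
    B: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    D: np.ndarray | None = None,
):
    """Newton-Raphson logistic MLE, vectorized over candidates.

    B : (n, p0) shared design (first column must be the intercept).
    y : (n,) binary labels.
    weights : (nc, n) observation weights (0 drops a row for one candidate).
    D : optional (nc, n) per-candidate extra feature column.

    Returns (ll, beta, converged, n_iter): arrays over the nc candidates;
    beta has p0 (+1 if D is given) columns.
    """
    n, p0 = B.shape
    nc = weights.shape[0]
    p = p0 + (D is not None)
    beta = np.zeros((nc, p))

    def loglik_eta(eta):
        return (weights * (y * eta - np.logaddexp(0.0, eta))).sum(axis=1)

    def etas(b):
        eta = b[:, :p0] @ B.T
        if D is not None:
            eta = eta + b[:, p0][:, None] * D
        return eta

    eta = etas(beta)
    ll = loglik_eta(eta)
    converged = np.zeros(nc, dtype=bool)
    it = 0
    for it in range(1, _MAX_ITER + 1):
        mu = expit(eta)
        Wt = weights * mu * (1.0 - mu)
        resid = weights * (y - mu)
        g = np.empty((nc, p))
        g[:, :p0] = resid @ B
        H = np.empty((nc, p, p))
        H[:, :p0, :p0] = np.einsum("cn,ni,nj->cij", Wt, B, B)
        if D is not None:
            g[:, p0] = (resid * D).sum(axis=1)
            cross = (Wt * D) @ B
            H[:, :p0, p0] = cross
            H[:, p0, :p0] = cross
            H[:, p0, p0] = (Wt * D * D).sum(axis=1)
        H[:, np.arange(p), np.arange(p)] += 1e-9  # ridge for near-singular fits
        delta = np.linalg.solve(H, g[:, :, None])[:, :, 0]

        step = np.ones(nc)
        for _ in range(8):  # step-halving safeguard
            prop = np.clip(beta + step[:, None] * delta, -_BETA_CAP, _BETA_CAP)
            eta_prop = etas(prop)
            ll_prop = loglik_eta(eta_prop)
            worse = ll_prop < ll - 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
        improved = ll_prop >= ll
        newly_conv = np.abs(ll_prop - ll) < _LL_TOL
        beta = np.where(improved[:, None], prop, beta)
        ll = np.maximum(ll_prop, ll)
        eta = etas(beta)
        converged |= newly_conv
        if converged.all():
            break
    return ll, beta, converged, it


def fit_logistic(
    features: np.ndarray | None,
    labels: Sequence[int],
    weights: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic regression with an implicit intercept.

    ``features`` is an n x p matrix (or None for an intercept-only model).
    Perfect separation is flagged and coefficients are clamped at +/-30, so
    the log-likelihood approaches its supremum of 0 without divergence.
    """
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if features is None:
        X = np.empty((n, 0))
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if X.shape[0] != n:
            X = X.T
        if X.shape[0] != n:
            raise ValueError("feature matrix and labels disagree on n")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    eff = y[w > 0]
    if X.shape[1] > 0 and (eff.min() == eff.max()):
        raise DegenerateLabelsError("labels contain one class; slopes are undefined")
    B = np.column_stack([np.ones(n), X])
    ll, beta, conv, n_iter = _batch_newton(B, y, w[None, :], D=None)
    coef = beta[0]
    names = ["intercept"] + (
        list(feature_names) if feature_names is not None else [f"x{j}" for j in range(X.shape[1])]
    )
    # perfect separation: the likelihood approaches its supremum of 1 and/or
    # a coefficient runs into the clamp
    separated = bool(
        np.any(np.abs(coef) >= _BETA_CAP - 1e-6)
        or (X.shape[1] > 0 and ll[0] > -1e-4)
    )
    return LogisticFit(
        coef=coef,
        feature_names=names,
        log_likelihood=float(ll[0]),
        converged=bool(conv[0]),
        separated=separated,
        n_iter=n_iter,
        n_obs=int((w > 0).sum()),
    )


def wilks_test(alt: LogisticFit, null: LogisticFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested logistic fits on identical data.

    Lambda = 2(l_alt - l_null), clipped below at 0; p is the upper tail of
    chi-square with df = the difference in parameter count.
    """
    df = alt.n_params - null.n_params
    if df <= 0:
        raise ValueError("alt must have more parameters than null")
    diff = alt.log_likelihood - null.log_likelihood
    if diff < -1e-6:
        raise FitFailureError(
            f"alt log-likelihood {alt.log_likelihood:.6f} below null "
            f"{null.log_likelihood:.6f}: fit failure"
        )
    lam = max(0.0, 2.0 * diff)
    return lam, float(chi2.sf(lam, df))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Candidate enumeration and testing


def enumerate_candidates(
    C1: SequenceCluster, w: int, stride: int = 1
) -> list[CoreMotif]:
    """Every N-free width-w window of every foreground member (at stride)."""
    out: list[CoreMotif] = []
    for s in C1.members:
        if len(s) < w:
            raise ValueError(f"member {s.id!r} shorter than width {w}")
        res = s.residues
        for off in range(0, len(res) - w + 1, stride):
            win = res[off : off + w]
            if "N" not in win:
                out.append(CoreMotif(win, s.id, off))
    return out


def _check_clusters(C1: SequenceCluster, C0: SequenceCluster, w: int) -> None:
    if len(C1) < 2 or len(C0) < 2:
        raise ValueError("both clusters need at least 2 members")
    for s in list(C1.members) + list(C0.members):
        if len(s) < w:
            raise ValueError(f"member {s.id!r} shorter than width {w}")


def _selected_spectrum_matrix(
    seqs: Sequence[DnaSequence], classes: Sequence[str]
) -> np.ndarray:
    full = spectrum_feature_matrix(seqs)
    idx = [SPECTRUM_CLASSES.index(c) for c in classes]
    return full[:, idx]


def _test_all_candidates(
    C1: SequenceCluster,
    C0: SequenceCluster,
    w: int,
    stride: int,
    Phi: np.ndarray | None,
):
    """Fit alt/null models for every candidate and return the test table.

    ``Phi`` is the n x m matrix of conditioning spectrum features (None for
    plain LR).  The candidate's source sequence gets weight 0 in both fits.
    """
    seqs = list(C1.members) + list(C0.members)
    n1 = len(C1)
    y = np.array([1.0] * n1 + [0.0] * len(C0))
    cands = enumerate_candidates(C1, w, stride)
    if not cands:
        raise ValueError("no N-free candidate windows found")
    cand_codes = np.stack([encode(c.core) for c in cands])
    encoded = [s.encoded() for s in seqs]
    D = batch_min_distances(cand_codes, encoded).T.astype(float)  # (nc, n)

    fg_index = {s.id: i for i, s in enumerate(C1.members)}
    excl = np.array([fg_index[c.source_sequence_id] for c in cands])
    nc = len(cands)
    n = len(seqs)
    weights = np.ones((nc, n))
    weights[np.arange(nc), excl] = 0.0

    B = np.ones((n, 1)) if Phi is None else np.column_stack([np.ones(n), Phi])
    ll_alt, beta, _, _ = _batch_newton(B, y, weights, D=D)

    # one null fit per distinct left-out foreground member
    ll_null_by_excl = np.empty(n1)
    wrow = np.ones(n)
    for i in range(n1):
        wvec = wrow.copy()
        wvec[i] = 0.0
        fit = fit_logistic(None if Phi is None else Phi, y, weights=wvec)
        ll_null_by_excl[i] = fit.log_likelihood
    ll_null = ll_null_by_excl[excl]

    lam = np.maximum(0.0, 2.0 * (ll_alt - ll_null))
    pvals = chi2.sf(lam, df=1)
    table = pd.DataFrame(
        {
            "core": [c.core for c in cands],
            "source_sequence_id": [c.source_sequence_id for c in cands],
            "source_offset": [c.source_offset for c in cands],
            "mismatch_slope": beta[:, -1],
            "lambda": lam,
            "p_value": pvals,
        }
    )
    return cands, table


def _pick_best(table: pd.DataFrame) -> int:
    """Index of the most significant over-represented candidate.

    Only cores whose mismatch coefficient is <= 0 (smaller distance raises
    the foreground probability, i.e. the core is enriched in the
    foreground) qualify as motifs; a significantly *under*-represented core
    would build a seed PWM that ranks background above foreground.  If no
    candidate is enriched, the overall minimum-p candidate is returned.
    Ties break to the lexicographically smallest core, then offset.
    """
    idx = np.arange(len(table))
    enriched = table["mismatch_slope"].to_numpy() <= 0.0
    if enriched.any():
        idx = idx[enriched]
    sub = table.iloc[idx]
    order = np.lexsort(
        (
            sub["source_offset"].to_numpy(),
            sub["core"].to_numpy(),
            sub["p_value"].to_numpy(),
        )
    )
    return int(idx[order[0]])


def build_seed_pwm(
    c_star: CoreMotif, C1: SequenceCluster, C0: SequenceCluster
) -> tuple[list[str], PositionWeightMatrix]:
    """Seed PWM from foreground windows that beat the background median.

    Threshold t = median over background sequences of D_{c*}(S); the seed
    set is every foreground window at strand-aware distance strictly below
    t.  If that set is empty, fall back to the single best window of each
    foreground member.  Each selected window enters the PWM in the
    orientation closer to the core, so instances found on opposite strands
    align.  The PWM uses a pseudocount of 1.
    """
    w = c_star.width
    cc = encode(c_star.core)
    rc = reverse_complement_codes(cc)
    t = float(np.median([min_distance_in_sequence(cc, s) for s in C0.members]))

    def member_windows(s: DnaSequence):
        win = np.lib.stride_tricks.sliding_window_view(s.encoded(), w)
        fwd = (win != cc).sum(axis=1)
        rev = (win != rc).sum(axis=1)
        ok = (win != 4).all(axis=1)  # N-free windows only
        return win, np.minimum(fwd, rev), fwd, rev, ok

    def oriented(s: DnaSequence, off: int, fwd_d: int, rev_d: int) -> str:
        win = s.residues[off : off + w]
        if rev_d < fwd_d:
            from .seqcore import reverse_complement

            return reverse_complement(win)
        return win

    seed: list[str] = []
    fallback: list[str] = []
    for s in C1.members:
        if len(s) < w:
            continue
        _, d, fwd, rev, ok = member_windows(s)
        hits = np.flatnonzero(ok & (d < t))
        for off in hits:
            seed.append(oriented(s, int(off), int(fwd[off]), int(rev[off])))
        valid = np.flatnonzero(ok)
        if valid.size:
            best = valid[np.argmin(d[valid])]
            fallback.append(oriented(s, int(best), int(fwd[best]), int(rev[best])))
    chosen = seed if seed else fallback
    if not chosen:
        raise ValueError("no N-free foreground windows available for the seed PWM")
    return chosen, build_pwm(chosen, pseudocount=1.0, name=f"seed_{c_star.core}")


def _finish_discovery(
    C1: SequenceCluster,
    C0: SequenceCluster,
    w: int,
    cands: list[CoreMotif],
    table: pd.DataFrame,
    Phi: np.ndarray | None,
    selected: list[str] | None,
):
    table = table.copy()
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    i_best = _pick_best(table)
    c_star = cands[i_best]
    best = CandidateTest(
        core=c_star,
        lambda_stat=float(table["lambda"].iloc[i_best]),
        p_value=float(table["p_value"].iloc[i_best]),
        q_value=float(table["q_value"].iloc[i_best]),
    )

    # report-quality refit on the winning candidate's leave-out data
    seqs = list(C1.members) + list(C0.members)
    y = [1] * len(C1) + [0] * len(C0)
    wvec = np.ones(len(seqs))
    wvec[[s.id for s in C1.members].index(c_star.source_sequence_id)] = 0.0
    d = np.array([min_distance_in_sequence(c_star.core, s) for s in seqs], dtype=float)
    if Phi is None:
        null_fit = fit_logistic(None, y, weights=wvec)
        alt_fit = fit_logistic(d[:, None], y, weights=wvec, feature_names=["mismatch"])
    else:
        names = list(selected)
        null_fit = fit_logistic(Phi, y, weights=wvec, feature_names=names)
        alt_fit = fit_logistic(
            np.column_stack([Phi, d]), y, weights=wvec, feature_names=names + ["mismatch"]
        )

    seed_sequences, pwm = build_seed_pwm(c_star, C1, C0)
    return best, seed_sequences, pwm, null_fit, alt_fit, table


def lr_discover(
    C1: SequenceCluster, C0: SequenceCluster, w: int, stride: int = 1
) -> DiscoveryResult:
    """Run the LR algorithm at one width and keep the most significant core."""
    _check_clusters(C1, C0, w)
    cands, table = _test_all_candidates(C1, C0, w, stride, Phi=None)
    best, seed, pwm, null_fit, alt_fit, table = _finish_discovery(
        C1, C0, w, cands, table, None, None
    )
    return DiscoveryResult(
        best=best,
        seed_sequences=seed,
        pwm=pwm,
        width=w,
        null_fit=null_fit,
        alt_fit=alt_fit,
        candidates=table,
    )


def alr_select_features(
    C1: SequenceCluster, C0: SequenceCluster, m: int
) -> list[str]:
    """The m collapsed spectrum classes most predictive one at a time.

    Each of the 12 classes (2 monomer + 10 dimer) is scored by the
    log-likelihood of a logistic fit of cluster label on that feature alone;
    numeric ties fall back to lexicographic class order.
    """
    if not 0 <= m <= len(SPECTRUM_CLASSES):
        raise ValueError(f"m must be in [0, {len(SPECTRUM_CLASSES)}]")
    if m == 0:
        return []
    seqs = list(C1.members) + list(C0.members)
    y = [1] * len(C1) + [0] * len(C0)
    full = spectrum_feature_matrix(seqs)
    lls = []
    for j, cls in enumerate(SPECTRUM_CLASSES):
        fit = fit_logistic(full[:, j : j + 1], y, feature_names=[cls])
        lls.append(fit.log_likelihood)
    ranked = sorted(zip(SPECTRUM_CLASSES, lls), key=lambda t: (-round(t[1], 9), t[0]))
    return [cls for cls, _ in ranked[:m]]


def alr_discover(
    C1: SequenceCluster, C0: SequenceCluster, w: int, m: int = 5, stride: int = 1
) -> AlrResult:
    """The ALR algorithm: LR conditioned on m bulk spectrum features.

    The null model carries the intercept plus the m selected features, the
    alternative adds the candidate's mismatch statistic, and the final
    decision rule is a logistic model on the spectrum features plus the
    seed-PWM score (its predicted probability is the classifier score).
    """
    _check_clusters(C1, C0, w)
    selected = alr_select_features(C1, C0, m)
    seqs = list(C1.members) + list(C0.members)
    Phi = _selected_spectrum_matrix(seqs, selected) if selected else None
    cands, table = _test_all_candidates(C1, C0, w, stride, Phi=Phi)
    best, seed, pwm, null_fit, alt_fit, table = _finish_discovery(
        C1, C0, w, cands, table, Phi, selected
    )
    y = [1] * len(C1) + [0] * len(C0)
    f = pwm_score_values(pwm, seqs)
    X = np.column_stack([Phi, f]) if Phi is not None else f[:, None]
    final = fit_logistic(X, y, feature_names=list(selected) + ["pwm_score"])
    return AlrResult(
        best=best,
        seed_sequences=seed,
        pwm=pwm,
        width=w,
        null_fit=null_fit,
        alt_fit=alt_fit,
        candidates=table,
        selected_features=selected,
        final_model=final,
    )


def discover_multi_width(
    C1: SequenceCluster,
    C0: SequenceCluster,
    widths: Sequence[int],
    m: int | None = None,
    stride: int = 1,
) -> DiscoveryResult:
    """Run discovery at several widths and keep the most significant result.

    q-values are recomputed over the candidate family pooled across widths,
    so multi-width search pays its full multiple-testing price.
    """
    if not widths:
        raise ValueError("widths must be non-empty")
    results: list[DiscoveryResult] = []
    for w in widths:
        if m is None:
            results.append(lr_discover(C1, C0, w, stride))
        else:
            results.append(alr_discover(C1, C0, w, m, stride))
    pooled_p = np.concatenate([r.candidates["p_value"].to_numpy() for r in results])
    pooled_q = bh_fdr(pooled_p)
    off = 0
    for r in results:
        k = len(r.candidates)
        r.candidates["q_value"] = pooled_q[off : off + k]
        i = _pick_best(r.candidates)
        r.best.q_value = float(r.candidates["q_value"].iloc[i])
        off += k
    best = min(
        results,
        key=lambda r: (r.best.p_value, r.best.core.core, r.best.core.source_offset),
    )
    return best


def null_fdr_calibration(
    pool: Sequence[DnaSequence],
    cluster_size: int,
    n_runs: int,
    w: int,
    stride: int = 1,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> dict:
    """Empirical FDR honesty check on random clusters from one pool.

    Each run draws two disjoint clusters of ``cluster_size`` sequences from
    the pool, runs LR discovery, and records the best q-value.  Under this
    global null the BH q-value also bounds the family-wise error rate, so
    P(best q <= alpha) should not exceed alpha.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    if 2 * cluster_size > len(pool):
        raise ValueError("pool too small for two disjoint clusters")
    qs = np.empty(n_runs)
    ps = np.empty(n_runs)
    for k, child in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(child)
        idx = rng.permutation(len(pool))
        fg = SequenceCluster("null_fg", [pool[i] for i in idx[:cluster_size]])
        bg = SequenceCluster(
            "null_bg", [pool[i] for i in idx[cluster_size : 2 * cluster_size]]
        )
        res = lr_discover(fg, bg, w, stride)
        qs[k] = res.best.q_value
        ps[k] = res.best.p_value
    return {
        "n_runs": n_runs,
        "alpha": alpha,
        "rejection_rate": float((qs <= alpha).mean()),
        "best_q_values": qs,
        "best_p_values": ps,
    }
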