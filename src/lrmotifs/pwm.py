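"""Position-weight matrices, JASPAR PFM I/O, and the window score F(S).

A PWM is a 4 x w matrix of per-position nucleotide counts; its probability
view adds a pseudocount and normalizes each column.  The benchmark scores a
long sequence by F(S), the maximum likelihood of any width-w window of S or
of its reverse complement.  Likelihoods are accumulated in log space and
exponentiated for reporting; a window position holding N contributes a
neutral factor of 0.25.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .seqcore import DnaSequence, encode

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class PfmFormatError(ValueError):
    """Malformed position-frequency-matrix file."""


@dataclass
class PositionWeightMatrix:
    """4 x w counts (rows A, C, G, T) with a pseudocount and a name."""

    counts: np.ndarray
    pseudocount: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix (rows A,C,G,T)")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probs(self) -> np.ndarray:
        """Probability view: (counts + pc) normalized per column."""
        aug = self.counts + self.pseudocount
        return aug / aug.sum(axis=0, keepdims=True)

    @property
    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)

    def log_prob_lookup(self) -> np.ndarray:
        """5 x w log-probability table; the 5th row (N) is log 0.25."""
        lp = self.log_probs
        return np.vstack([lp, np.full((1, self.width), np.log(0.25))])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


@dataclass
class PwmScore:
    """F(S): the best window likelihood, with where it was found."""

    value: float
    argmax_offset: int
    argmax_strand: str = "+"

    def __post_init__(self) -> None:
        if self.argmax_strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


def build_pwm(
    seqs: Sequence[str], pseudocount: float = 1.0, name: str = ""
) -> PositionWeightMatrix:
    """Tally N-free width-w strings into a PWM, column by column."""
    if not seqs:
        raise ValueError("cannot build a PWM from an empty sequence list")
    w = len(seqs[0])
    if any(len(s) != w for s in seqs):
        raise ValueError("all sequences must share one width")
    counts = np.zeros((4, w))
    for s in seqs:
        s = s.upper()
        for j, b in enumerate(s):
            if b not in _BASE_INDEX:
                raise ValueError(f"sequence {s!r} is not N-free A/C/G/T")
            counts[_BASE_INDEX[b], j] += 1
    return PositionWeightMatrix(counts, pseudocount, name)


def pwm_log_likelihood(M: PositionWeightMatrix, x: str | np.ndarray) -> float:
    """Sum of per-position log column probabilities (N gives log 0.25)."""
    codes = encode(x) if isinstance(x, str) else np.asarray(x)
    if len(codes) != M.width:
        raise ValueError(f"w-mer length {len(codes)} != PWM width {M.width}")
    table = M.log_prob_lookup()
    return float(table[codes, np.arange(M.width)].sum())


def pwm_likelihood(M: PositionWeightMatrix, x: str | np.ndarray) -> float:
    """Likelihood of a w-mer: product of column probabilities."""
    return float(np.exp(pwm_log_likelihood(M, x)))


def _window_log_likelihoods(M: PositionWeightMatrix, codes: np.ndarray) -> np.ndarray:
    w = M.width
    if len(codes) < w:
        raise ValueError(f"sequence length {len(codes)} < PWM width {w}")
    table = M.log_prob_lookup()
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    return table[win, np.arange(w)].sum(axis=1)


def pwm_score(M: PositionWeightMatrix, S: DnaSequence | str) -> PwmScore:
    """F(S): max window likelihood over S and its reverse complement.

    Ties are broken toward the forward strand, then the smaller forward
    offset.  The reported offset is always in forward-strand coordinates.
    """
    codes = S.encoded() if isinstance(S, DnaSequence) else encode(S)
    L = len(codes)
    w = M.width
    fwd = _window_log_likelihoods(M, codes)
    rc_codes = codes[::-1].copy()
    real = rc_codes < 4
    rc_codes[real] = 3 - rc_codes[real]
    rev = _window_log_likelihoods(M, rc_codes)
    best_f, best_r = fwd.max(), rev.max()
    if best_f >= best_r:
        off = int(fwd.argmax())  # argmax returns the first (smallest) offset
        return PwmScore(float(np.exp(best_f)), off, "+")
    off_rc = int(rev.argmax())
    return PwmScore(float(np.exp(best_r)), L - w - off_rc, "-")


def pwm_score_values(M: PositionWeightMatrix, seqs: Sequence[DnaSequence]) -> np.ndarray:
    """F(S) for many sequences (values only)."""
    return np.array([pwm_score(M, s).value for s in seqs])


# ---------------------------------------------------------------------------
# JASPAR PFM I/O (via biopython; both the bracketed dialect and bare
# whitespace-separated 4-row blocks are accepted)


def _from_bio_motif(m) -> PositionWeightMatrix:
    counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
    parts = []
    for x in (getattr(m, "matrix_id", None), m.name):
        if x and x not in parts:
            parts.append(x)
    return PositionWeightMatrix(counts, pseudocount=1.0, name=" ".join(parts))


def read_jaspar_pfm(
    path: str | Path, min_width: int | None = None
) -> list[PositionWeightMatrix]:
    """Read JASPAR-format PFMs, optionally keeping only widths >= min_width.

    Accepts headers ``>ID name`` followed by either labeled bracketed rows
    (``A [ 1 2 ... ]``) or bare whitespace-separated rows in A/C/G/T order.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise PfmFormatError(f"empty PFM file {path}")
    try:
        if "[" in text:
            parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
            out = [_from_bio_motif(m) for m in parsed]
        else:
            out = []
            # split into blocks: optional '>' header + 4 bare rows
            name = ""
            rows: list[str] = []
            for line in text.splitlines() + [">"]:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if rows:
                        if len(rows) != 4:
                            raise PfmFormatError(
                                f"{path}: expected 4 rows per matrix, got {len(rows)}"
                            )
                        m = bio_motifs.read(io.StringIO("\n".join(rows)), "pfm")
                        m.name = name
                        out.append(_from_bio_motif(m))
                        rows = []
                    name = line[1:].strip()
                else:
                    rows.append(line)
    except PfmFormatError:
        raise
    except Exception as exc:  # biopython raises bare ValueError/KeyError
        raise PfmFormatError(f"cannot parse PFM file {path}: {exc}") from exc
    if not out:
        raise PfmFormatError(f"no matrices found in {path}")
    widths = {m.width for m in out}
    if any(m.counts.shape[1] == 0 for m in out):
        raise PfmFormatError(f"zero-width matrix in {path} (widths {widths})")
    if min_width is not None:
        out = [m for m in out if m.width >= min_width]
    return out


def write_jaspar_pfm(pwms: Sequence[PositionWeightMatrix] | PositionWeightMatrix, path: str | Path) -> None:
    """Write PFMs in the bracketed JASPAR dialect."""
    if isinstance(pwms, PositionWeightMatrix):
        pwms = [pwms]
    with open(path, "w") as fh:
        for m in pwms:
            fh.write(f">{m.name or 'motif'}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in m.counts[i])
                fh.write(f"{b} [ {row} ]\n")


def write_probability_tsv(M: PositionWeightMatrix, path: str | Path) -> None:
    """Probability view as TSV: one row per base, one column per position."""
    probs = M.probs
    with open(path, "w") as fh:
        fh.write("base\t" + "\t".join(str(j + 1) for j in range(M.width)) + "\n")
        for i, b in enumerate(BASES):
            fh.write(b + "\t" + "\t".join(f"{p:.6g}" for p in probs[i]) + "\n")
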