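"""Core sequence and cluster data model.

DNA sequences are plain strings over ``{A, C, G, T, N}`` wrapped with an
identifier; clusters group sequences under a label (a foreground cluster of
co-regulated upstream regions, a background cluster of everything else).
The module also provides the reverse-complement-collapsed spectrum-kernel
profiles (monomer and dimer word-class fractions) used as low-order bulk
sequence features by the adjusted discovery algorithm and by the dimer
variance diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Integer encoding: A=0, C=1, G=2, T=3, N=4.  The complement of base i < 4 is
# 3 - i; N maps to itself.  N never equals any query base, so under this
# encoding an N position automatically counts as a mismatch.
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i


class AlphabetError(ValueError):
    """A residue outside the {A,C,G,T,N} alphabet was encountered."""


class FastaFormatError(ValueError):
    """Malformed or empty FASTA input."""


class ClusterTableError(ValueError):
    """Cluster-assignment table references an unknown sequence id."""


def _validate_residues(residues: str) -> str:
    residues = residues.upper()
    if not residues:
        raise AlphabetError("empty sequence")
    arr = np.frombuffer(residues.encode("ascii", "replace"), dtype=np.uint8)
    if (_ENCODE[arr] < 0).any():
        bad = sorted(set(residues) - set(ALPHABET))
        raise AlphabetError(f"non-DNA characters {bad!r}; expected {ALPHABET}")
    return residues


@dataclass
class DnaSequence:
    """An identified DNA string over A/C/G/T/N (upper-cased on ingest)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        self.residues = _validate_residues(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def encoded(self) -> np.ndarray:
        """Residues as int8 codes A=0, C=1, G=2, T=3, N=4."""
        return encode(self.residues)


@dataclass
class SequenceCluster:
    """An ordered set of sequences sharing a label (member ids unique)."""

    cluster_id: str
    members: list[DnaSequence]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate sequence ids in cluster {self.cluster_id!r}")

    def __len__(self) -> int:
        return len(self.members)

    def member_ids(self) -> list[str]:
        return [s.id for s in self.members]


@dataclass
class ClusterCollection:
    """A list of clusters; ``disjoint`` records whether ids are unshared."""

    clusters: list[SequenceCluster]
    disjoint: bool = field(default=True)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        disjoint = True
        for cl in self.clusters:
            for sid in cl.member_ids():
                if sid in seen:
                    disjoint = False
                seen.add(sid)
        self.disjoint = disjoint

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def get(self, cluster_id: str) -> SequenceCluster:
        for cl in self.clusters:
            if cl.cluster_id == cluster_id:
                return cl
        raise KeyError(cluster_id)

    def all_sequences(self) -> list[DnaSequence]:
        """Union of members, deduplicated by id, in first-seen order."""
        seen: set[str] = set()
        out: list[DnaSequence] = []
        for cl in self.clusters:
            for s in cl.members:
                if s.id not in seen:
                    seen.add(s.id)
                    out.append(s)
        return out


def encode(s: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, N=4)."""
    arr = _ENCODE[np.frombuffer(s.upper().encode("ascii", "replace"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted(set(s.upper()) - set(ALPHABET))
        raise AlphabetError(f"non-DNA characters {bad!r}")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


def reverse_complement(s: str) -> str:
    """Reverse complement of a DNA string; the complement of N is N.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    s = s.upper()
    if set(s) - set(ALPHABET):
        bad = sorted(set(s) - set(ALPHABET))
        raise AlphabetError(f"non-DNA characters {bad!r}")
    return s.translate(_COMPLEMENT)[::-1]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in integer-code space (N=4 maps to itself)."""
    out = codes[::-1].copy()
    real = out < 4
    out[real] = 3 - out[real]
    return out


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a FASTA file into DnaSequence records.

    Ids are the first whitespace-delimited token of each header; residues are
    upper-cased.  Duplicate ids and empty files are format errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    seqs = [DnaSequence(r.id, str(r.seq)) for r in records]
    ids = [s.id for s in seqs]
    if len(ids) != len(set(ids)):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise FastaFormatError(f"duplicate sequence ids {dups!r} in {path}")
    return seqs


def write_fasta(seqs: Iterable[DnaSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_cluster_table(path: str | Path, sequences: Sequence[DnaSequence]) -> ClusterCollection:
    """Assemble clusters from a 2-column TSV (sequence_id, cluster_id).

    Clusters appear in file order; sequences absent from the table are
    ignored (a count is logged).  A sequence_id not present among
    ``sequences`` is a reference error.
    """
    by_id = {s.id: s for s in sequences}
    order: list[str] = []
    members: dict[str, list[DnaSequence]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ClusterTableError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            sid, cid = parts
            if sid not in by_id:
                raise ClusterTableError(f"{path}:{lineno}: unknown sequence id {sid!r}")
            if cid not in members:
                members[cid] = []
                order.append(cid)
            members[cid].append(by_id[sid])
            n_rows += 1
    unassigned = len(by_id) - len({s.id for ms in members.values() for s in ms})
    if unassigned:
        logger.info("%d sequence(s) absent from cluster table ignored", unassigned)
    clusters = [SequenceCluster(cid, members[cid]) for cid in order]
    return ClusterCollection(clusters)


def write_cluster_table(collection: ClusterCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cl in collection:
            for sid in cl.member_ids():
                fh.write(f"{sid}\t{cl.cluster_id}\n")


# ---------------------------------------------------------------------------
# Reverse-complement-collapsed spectrum-kernel profiles


def _collapsed_class(word: str) -> str:
    rc = reverse_complement(word)
    lo, hi = sorted((word, rc))
    return lo if lo == hi else f"{lo}/{hi}"


def collapsed_classes(k: int) -> list[str]:
    """The word classes for depth k, with reverse complements identified.

    2 classes for k=1 (A/T, C/G) and 10 for k=2 (AA/TT ... TA), in sorted
    order.
    """
    if k not in (1, 2):
        raise ValueError("only k=1 and k=2 spectrum profiles are supported")
    words = ["".join(p) for p in __import__("itertools").product("ACGT", repeat=k)]
    return sorted({_collapsed_class(w) for w in words})


#: canonical feature ordering used by the adjusted discovery algorithm
SPECTRUM_CLASSES: list[str] = collapsed_classes(1) + collapsed_classes(2)


@dataclass
class SpectrumProfile:
    """Collapsed k-mer class fractions of one sequence (N windows skipped)."""

    k: int
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        expected = collapsed_classes(self.k)
        if set(self.fractions) != set(expected):
            raise ValueError(f"profile must cover exactly the classes {expected}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.fractions[c] for c in collapsed_classes(self.k)])


class UndefinedProfileError(ValueError):
    """Every window of the sequence contains an N."""


def spectrum_profile(s: str | DnaSequence, k: int) -> SpectrumProfile:
    """Fraction of overlapping width-k windows in each collapsed word class.

    A window and its reverse complement count as the same class; windows
    containing N are skipped and excluded from the denominator.
    """
    residues = s.residues if isinstance(s, DnaSequence) else s.upper()
    if len(residues) < k:
        raise ValueError(f"sequence shorter than k={k}")
    classes = collapsed_classes(k)
    counts = dict.fromkeys(classes, 0)
    n_valid = 0
    for i in range(len(residues) - k + 1):
        word = residues[i : i + k]
        if "N" in word:
            continue
        counts[_collapsed_class(word)] += 1
        n_valid += 1
    if n_valid == 0:
        raise UndefinedProfileError("all windows contain N")
    return SpectrumProfile(k, {c: counts[c] / n_valid for c in classes})


def spectrum_feature_matrix(seqs: Sequence[DnaSequence]) -> np.ndarray:
    """n x 12 matrix of monomer (2) and dimer (10) class fractions.

    Column order follows :data:`SPECTRUM_CLASSES`.
    """
    rows = []
    for s in seqs:
        p1 = spectrum_profile(s, 1)
        p2 = spectrum_profile(s, 2)
        rows.append(np.concatenate([p1.as_vector(), p2.as_vector()]))
    return np.asarray(rows)
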