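"""Strand-aware minimum-Hamming-distance "mismatch" statistics.

For a fixed candidate core w-mer c, the distance from c to a width-w window
x is min(H(c, x), H(rc(c), x)); the mismatch statistic of a long sequence S
is the minimum of this over all windows of S.  One such integer per cluster
member is the single regression feature of the discriminative discovery
algorithm.

Three routes compute the same quantity: a naive double loop (the test
oracle), a vectorized numpy scan (the default), and a 4-ary prefix-tree
(trie) with branch-and-bound pruning, which amortizes well when many cores
are queried against the same sequence.  Positions where the subject holds an
N count as mismatches, so an N-containing window can never spuriously match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import DnaSequence, SequenceCluster, encode, reverse_complement_codes


def _as_core_codes(c) -> np.ndarray:
    if isinstance(c, CoreMotif):
        return encode(c.core)
    if isinstance(c, str):
        return encode(c)
    return np.asarray(c, dtype=np.int8)


@dataclass
class CoreMotif:
    """A candidate core w-mer tagged with the window it was taken from."""

    core: str
    source_sequence_id: str = ""
    source_offset: int = 0

    def __post_init__(self) -> None:
        self.core = self.core.upper()
        if len(self.core) < 4:
            raise ValueError("core width must be >= 4")
        if "N" in self.core:
            raise ValueError("core must be N-free")

    @property
    def width(self) -> int:
        return len(self.core)


def core_distance(c, x: str) -> int:
    """min(H(c, x), H(rc(c), x)) for a width-w window x.

    N positions in x mismatch every core base.
    """
    cc = _as_core_codes(c)
    xc = encode(x) if isinstance(x, str) else np.asarray(x, dtype=np.int8)
    if len(xc) != len(cc):
        raise ValueError(f"window width {len(xc)} != core width {len(cc)}")
    fwd = int((cc != xc).sum())
    rev = int((reverse_complement_codes(cc) != xc).sum())
    return min(fwd, rev)


def _window_view(codes: np.ndarray, w: int) -> np.ndarray:
    if len(codes) < w:
        raise ValueError(f"sequence length {len(codes)} < core width {w}")
    return np.lib.stride_tricks.sliding_window_view(codes, w)


def min_distance_in_sequence(c, S: DnaSequence | str) -> int:
    """The mismatch statistic D_c(S): min over windows of core_distance."""
    cc = _as_core_codes(c)
    codes = S.encoded() if isinstance(S, DnaSequence) else encode(S)
    win = _window_view(codes, len(cc))
    fwd = (win != cc).sum(axis=1)
    rev = (win != reverse_complement_codes(cc)).sum(axis=1)
    return int(min(fwd.min(), rev.min()))


def mismatch_features(c, cluster: SequenceCluster) -> list[int]:
    """One mismatch statistic per cluster member, in member order."""
    return [min_distance_in_sequence(c, s) for s in cluster.members]


def batch_min_distances(cores: np.ndarray, encoded_seqs: list[np.ndarray]) -> np.ndarray:
    """Mismatch statistics for many cores against many sequences at once.

    Parameters
    ----------
    cores : (nc, w) int array of N-free core codes.
    encoded_seqs : list of int code arrays, each of length >= w.

    Returns
    -------
    (n_seqs, nc) int16 array with entry [i, j] = D_{core j}(seq i).
    """
    cores = np.asarray(cores, dtype=np.int8)
    nc, w = cores.shape
    rc = np.stack([reverse_complement_codes(c) for c in cores])
    both = np.concatenate([cores, rc], axis=0)  # (2 nc, w)
    out = np.empty((len(encoded_seqs), nc), dtype=np.int16)
    for i, codes in enumerate(encoded_seqs):
        win = _window_view(codes, w)  # (nw, w)
        acc = np.zeros((win.shape[0], 2 * nc), dtype=np.int16)
        for j in range(w):
            acc += win[:, j, None] != both[None, :, j]
        mins = acc.min(axis=0)
        out[i] = np.minimum(mins[:nc], mins[nc:])
    return out


class _TrieNode:
    __slots__ = ("children", "count")

    def __init__(self) -> None:
        self.children: dict[int, _TrieNode] = {}
        self.count = 0


class WindowTrie:
    """All forward-strand width-w windows of one sequence in a prefix tree.

    Only forward windows are stored; querying with both a core and its
    reverse complement and taking the min reproduces the strand-aware
    mismatch statistic at half the memory.  Branch-and-bound: a path is
    abandoned as soon as its accumulated mismatch count reaches the best
    distance found so far.
    """

    def __init__(self, S: DnaSequence | str, w: int):
        codes = S.encoded() if isinstance(S, DnaSequence) else encode(S)
        if len(codes) < w:
            raise ValueError(f"sequence length {len(codes)} < width {w}")
        self.width = w
        self.root = _TrieNode()
        self.n_windows = 0
        for win in _window_view(codes, w):
            node = self.root
            for sym in win:
                node = node.children.setdefault(int(sym), _TrieNode())
            node.count += 1
            self.n_windows += 1

    def query(self, core) -> int:
        """Min Hamming distance from the (single-strand) core to any window."""
        cc = _as_core_codes(core)
        if len(cc) != self.width:
            raise ValueError(f"core width {len(cc)} != trie width {self.width}")
        best = self.width + 1
        # iterative DFS, pruning paths that cannot beat the current best
        stack = [(self.root, 0, 0)]
        while stack:
            node, depth, mm = stack.pop()
            if mm >= best:
                continue
            if depth == self.width:
                best = mm
                if best == 0:
                    return 0
                continue
            q = int(cc[depth])
            for sym, child in node.children.items():
                nm = mm + (sym != q)  # N (sym=4) never equals a query base
                if nm < best:
                    stack.append((child, depth + 1, nm))
        return best

    def min_distance(self, core) -> int:
        """Strand-aware mismatch statistic via forward and rc queries."""
        cc = _as_core_codes(core)
        return min(self.query(cc), self.query(reverse_complement_codes(cc)))


def build_window_trie(S: DnaSequence | str, w: int) -> WindowTrie:
    """Preprocess S into a width-w window trie (build once, query many)."""
    return WindowTrie(S, w)
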