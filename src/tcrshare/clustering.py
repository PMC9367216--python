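"""Antigen-specificity CDR3 clustering by pairwise substitution scoring.

Same-length CDR3 amino-acid sequences are scored pairwise with a gapless
substitution-matrix comparison over their mid-region (the near-invariant
``C(A)SS...`` N-terminal and ``...F`` C-terminal flanks are excluded from
scoring).  The score is the *mean* per-position matrix value, so one
threshold applies across lengths.  Sequences are linked when the score
reaches the threshold, and clusters are the connected components of that
graph; singletons are discarded.  Different lengths (or, optionally,
different V genes) are never compared — a transparent variant of the
local-alignment clustering used for putative specificity grouping.
"""

from __future__ import annotations

import dataclasses
import functools
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ClusterParams:
    """Scoring and linkage parameters.

    ``score_threshold`` is on the mean-per-position scale (default 2.5,
    roughly "mostly conserved residues with a couple of tolerated
    substitutions" under BLOSUM62).
    """

    matrix_name: str = "BLOSUM62"
    score_threshold: float = 2.5
    flank_left: int = 2
    flank_right: int = 2
    require_same_v: bool = False

    def __post_init__(self) -> None:
        if self.flank_left < 0 or self.flank_right < 0:
            raise ValueError("flanks must be non-negative")
        if not np.isfinite(self.score_threshold):
            raise ValueError("score_threshold must be finite")


@dataclasses.dataclass(frozen=True)
class CDR3Cluster:
    cluster_id: int
    members: tuple[str, ...]
    antigen_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster has at least 2 members")
        if len({len(m) for m in self.members}) != 1:
            raise ValueError("cluster members must share one length")


@functools.lru_cache(maxsize=8)
def _matrix_lookup(name: str) -> np.ndarray:
    """Substitution matrix as a 128x128 float lookup over ASCII codes."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(name)
    lut = np.full((128, 128), np.nan)
    for a in mat.alphabet:
        for b in mat.alphabet:
            lut[ord(a), ord(b)] = mat[a, b]
    return lut


def pair_score(
    a: str,
    b: str,
    params: ClusterParams = ClusterParams(),
    v_a: str | None = None,
    v_b: str | None = None,
) -> float | None:
    """Mean mid-region substitution score, or None when incomparable.

    Incomparable pairs: different lengths, different V genes under
    ``require_same_v``, or an empty mid-region.
    """
    if len(a) != len(b):
        return None
    if params.require_same_v and v_a != v_b:
        return None
    lo, hi = params.flank_left, len(a) - params.flank_right
    if hi <= lo:
        logger.warning("CDR3 of length %d has an empty mid-region; incomparable", len(a))
        return None
    lut = _matrix_lookup(params.matrix_name)
    ca = np.frombuffer(a[lo:hi].encode(), dtype=np.uint8)
    cb = np.frombuffer(b[lo:hi].encode(), dtype=np.uint8)
    return float(lut[ca, cb].mean())


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def _group_edges(
    seqs: list[str], params: ClusterParams, block: int = 512
) -> Iterable[tuple[int, int]]:
    """Index pairs with mean mid-region score >= threshold (same-length set)."""
    n = len(seqs)
    length = len(seqs[0])
    lo, hi = params.flank_left, length - params.flank_right
    if hi <= lo:
        logger.warning("length-%d group has an empty mid-region; skipped", length)
        return
    lut = _matrix_lookup(params.matrix_name)
    enc = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, length)
    mid = enc[:, lo:hi]
    width = hi - lo
    min_total = params.score_threshold * width
    for start in range(0, n, block):
        rows = mid[start : start + block]
        scores = np.zeros((rows.shape[0], n))
        for p in range(width):
            scores += lut[rows[:, p][:, None], mid[:, p][None, :]]
        ii, jj = np.nonzero(scores >= min_total - 1e-9)
        for i, j in zip(ii + start, jj):
            if i < j:
                yield int(i), int(j)


def build_clusters(
    cdr3_set: Iterable[str],
    params: ClusterParams = ClusterParams(),
    v_genes: Mapping[str, str] | None = None,
) -> list[CDR3Cluster]:
    """Connected-component clusters over the threshold graph.

    Output is deterministic: clusters sorted by descending size, then by
    lexicographically smallest member; members sorted within a cluster.
    """
    seqs = sorted(set(cdr3_set))
    if not seqs:
        raise ValueError("empty CDR3 set")
    if params.require_same_v:
        if v_genes is None:
            raise ValueError("require_same_v needs a v_genes mapping")
        keyed: dict[tuple, list[str]] = {}
        for s in seqs:
            keyed.setdefault((len(s), v_genes.get(s)), []).append(s)
        groups = list(keyed.values())
    else:
        keyed = {}
        for s in seqs:
            keyed.setdefault((len(s),), []).append(s)
        groups = list(keyed.values())

    member_sets: list[list[str]] = []
    for group in groups:
        if len(group) < 2:
            continue
        uf = _UnionFind(len(group))
        for i, j in _group_edges(group, params):
            uf.union(i, j)
        comps: dict[int, list[str]] = {}
        for i, s in enumerate(group):
            comps.setdefault(uf.find(i), []).append(s)
        member_sets.extend(sorted(c) for c in comps.values() if len(c) >= 2)

    member_sets.sort(key=lambda ms: (-len(ms), ms[0]))
    return [
        CDR3Cluster(cluster_id=k, members=tuple(ms)) for k, ms in enumerate(member_sets)
    ]


@dataclasses.dataclass
class PositionProfile:
    """Per-position residue frequencies and Shannon entropies (nats)."""

    length: int
    frequencies: pd.DataFrame   # positions x 20 residues
    entropy: np.ndarray


def position_profile(members: Iterable[str]) -> PositionProfile:
    """Column residue frequencies and entropies for an aligned (equal
    length) set of CDR3s; members are weighted equally."""
    from .models import AA_ALPHABET

    members = list(members)
    if not members:
        raise ValueError("no members")
    length = len(members[0])
    if any(len(m) != length for m in members):
        raise ValueError("members must share one length")
    enc = np.frombuffer("".join(members).encode(), dtype=np.uint8).reshape(len(members), length)
    freq = np.zeros((length, len(AA_ALPHABET)))
    for k, aa in enumerate(AA_ALPHABET):
        freq[:, k] = (enc == ord(aa)).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log(freq), 0.0)
    entropy = np.maximum(-plogp.sum(axis=1), 0.0)  # avoid -0.0 in output
    return PositionProfile(
        length=length,
        frequencies=pd.DataFrame(freq, columns=list(AA_ALPHABET)),
        entropy=entropy,
    )


def cluster_table(clusters: list[CDR3Cluster]) -> pd.DataFrame:
    """Long-format membership table (cluster_id, cdr3_aa, antigen labels)."""
    rows = [
        (c.cluster_id, m, ";".join(sorted(c.antigen_labels)))
        for c in clusters
        for m in c.members
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "cdr3_aa", "antigen_labels"])
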