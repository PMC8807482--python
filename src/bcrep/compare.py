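"""Cross-repertoire comparison: sharing spectra, Jaccard/Venn overlap,
shared-CDR3 consensus and repertoire-similarity trees.

The sharing universe is always the union of unique CDR3 amino-acid sequences
over the repertoires being compared; "shared by >= k" percentages are fractions
of that union.  The repertoire tree is UPGMA on Jaccard distance (1 - J) by
default — a deterministic, ultrametric display tree; Bray-Curtis on clonotype
frequencies is available to preserve abundance information.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.distance import braycurtis

from .clonotypes import ClonotypeTable


def jaccard(set_a: Set[str], set_b: Set[str]) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


@dataclass
class SharingReport:
    """Occupancy structure of CDR3s across repertoires."""

    n_repertoires: int
    universe_size: int
    occupancy: Dict[str, int]                  # CDR3 -> number of repertoires
    shared_fraction_at_k: Dict[int, float]     # k -> fraction of universe with occ >= k
    top_shared: List[str]                      # occupancy > top_threshold, most-shared first
    top_threshold: int

    def shared_percent(self, k: int = 2) -> float:
        return 100.0 * self.shared_fraction_at_k.get(k, 0.0)


def sharing_spectrum(repertoires: Mapping[str, Set[str]],
                     min_occupancy: int = 2, top_threshold: int = 6) -> SharingReport:
    """Exact membership counting of CDR3s over the union of >= 2 repertoires.

    ``top_shared`` lists CDR3s present in strictly more than ``top_threshold``
    repertoires, ordered by (occupancy desc, sequence).
    """
    if len(repertoires) < 2:
        raise ValueError("sharing requires at least 2 repertoires")
    occupancy: Counter = Counter()
    for s in repertoires.values():
        occupancy.update(set(s))
    universe = len(occupancy)
    n = len(repertoires)
    fractions = {}
    for k in range(1, n + 1):
        fractions[k] = (sum(1 for c in occupancy.values() if c >= k) / universe
                        if universe else 0.0)
    top = sorted((c for c in occupancy.items() if c[1] > top_threshold),
                 key=lambda kv: (-kv[1], kv[0]))
    return SharingReport(
        n_repertoires=n, universe_size=universe, occupancy=dict(occupancy),
        shared_fraction_at_k=fractions, top_shared=[k for k, _ in top],
        top_threshold=top_threshold,
    )


def per_repertoire_shared_fraction(repertoires: Mapping[str, Set[str]],
                                   min_occupancy: int = 2) -> Dict[str, float]:
    """Variant convention: per repertoire, the fraction of its own CDR3s that
    are shared (occupancy >= min_occupancy) — emitted alongside the union-based
    headline numbers for comparison against externally processed tables."""
    report = sharing_spectrum(repertoires)
    out = {}
    for rid, s in repertoires.items():
        if not s:
            out[rid] = 0.0
            continue
        out[rid] = sum(1 for c in s if report.occupancy.get(c, 0) >= min_occupancy) / len(s)
    return out


@dataclass
class Venn3Result:
    """Counts of the 7 exclusive regions of a 3-set Venn partition."""

    labels: Tuple[str, str, str]
    regions: Dict[str, int]    # keys "100","010","001","110","101","011","111"
    pairwise: Dict[Tuple[str, str], int]  # |A n B| regardless of the third set

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())


def venn3(set1: Set[str], set2: Set[str], set3: Set[str],
          labels: Tuple[str, str, str] = ("A", "B", "C")) -> Venn3Result:
    sets = (set1, set2, set3)
    regions = {f"{a}{b}{c}": 0 for a in "01" for b in "01" for c in "01" if a + b + c != "000"}
    for x in set1 | set2 | set3:
        key = "".join("1" if x in s else "0" for s in sets)
        regions[key] += 1
    pairwise = {
        (labels[0], labels[1]): len(set1 & set2),
        (labels[0], labels[2]): len(set1 & set3),
        (labels[1], labels[2]): len(set2 & set3),
    }
    return Venn3Result(labels=labels, regions=regions, pairwise=pairwise)


@dataclass
class ConsensusProfile:
    """Plurality consensus of equal-length CDR3s with per-position conservation."""

    length: int
    consensus: str
    conservation: List[float]
    n_sequences: int


def consensus_profile(sequences: Iterable[str], length: Optional[int] = None) -> ConsensusProfile:
    """Per-position plurality residue (ties -> lexicographically smallest).

    All sequences must share one length; stratify by length upstream (the
    dominant length class is the one analyzed for shared CDR3s).
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("consensus of an empty set is undefined")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(
            f"mixed CDR3 lengths {sorted(lengths)}: stratify by length first "
            "(see modal_length_stratum)")
    L = lengths.pop()
    if length is not None and length != L:
        raise ValueError(f"sequences have length {L}, expected {length}")
    cons = []
    conserv = []
    for i in range(L):
        counts = Counter(s[i] for s in seqs)
        best = min(counts, key=lambda c: (-counts[c], c))
        cons.append(best)
        conserv.append(counts[best] / len(seqs))
    return ConsensusProfile(length=L, consensus="".join(cons),
                            conservation=conserv, n_sequences=len(seqs))


def modal_length_stratum(sequences: Iterable[str]) -> List[str]:
    """Subset of sequences in the most frequent length class (ties -> shorter)."""
    seqs = list(sequences)
    if not seqs:
        return []
    counts = Counter(len(s) for s in seqs)
    L = min(counts, key=lambda k: (-counts[k], k))
    return [s for s in seqs if len(s) == L]


def repertoire_distance(repertoires, metric: str = "jaccard"):
    """Pairwise distance matrix over repertoires.

    ``repertoires`` is an ordered mapping label -> CDR3 set (jaccard) or
    label -> :class:`ClonotypeTable` (either metric; bray_curtis uses clonotype
    frequencies).  Returns (labels, symmetric ndarray with zero diagonal).
    """
    labels = list(repertoires)
    if len(labels) < 2:
        raise ValueError("need at least 2 repertoires for a distance matrix")
    n = len(labels)
    D = np.zeros((n, n))
    if metric == "jaccard":
        sets = [v.keys() if isinstance(v, ClonotypeTable) else set(v)
                for v in repertoires.values()]
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = 1.0 - jaccard(sets[i], sets[j])
    elif metric == "bray_curtis":
        tables = list(repertoires.values())
        if not all(isinstance(t, ClonotypeTable) for t in tables):
            raise ValueError("bray_curtis requires ClonotypeTable inputs")
        vocab = sorted(set().union(*(t.entries for t in tables)))
        idx = {k: i for i, k in enumerate(vocab)}
        mat = np.zeros((n, len(vocab)))
        for r, t in enumerate(tables):
            for k, c in t.frequencies().items():
                mat[r, idx[k]] = c
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = braycurtis(mat[i], mat[j])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return labels, D


@dataclass
class TreeResult:
    """UPGMA repertoire-similarity tree."""

    labels: List[str]
    distance_matrix: np.ndarray
    newick: str
    linkage: np.ndarray = field(repr=False, default=None)  # scipy-style merge table

    @property
    def root_height(self) -> float:
        """Height of the root; every leaf sits at this depth (ultrametric)."""
        return float(self.linkage[-1, 2]) / 2.0

    def to_newick_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick + "\n")


def build_tree(distance_matrix: np.ndarray, labels: Sequence[str]) -> TreeResult:
    """UPGMA agglomeration with deterministic tie-breaking by cluster order.

    The produced tree is ultrametric; the Newick string carries branch lengths
    (merge height = distance / 2).  Raises on an asymmetric matrix.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n < 2:
        raise ValueError("distance matrix must be square with n >= 2")
    if not np.allclose(D, D.T, atol=1e-12) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with a zero diagonal")
    if len(labels) != n:
        raise ValueError("labels do not match the matrix size")
    # active clusters: id -> (newick, size, height); ids 0..n-1 are leaves
    newick = {i: str(labels[i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    dist: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = D[i, j]
    active = list(range(n))
    linkage_rows = []
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dist[(min(i, j), max(i, j))]
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        h = d / 2.0
        newick[next_id] = (
            f"({newick[i]}:{h - height[i]:.10g},{newick[j]}:{h - height[j]:.10g})"
        )
        size[next_id] = size[i] + size[j]
        height[next_id] = h
        linkage_rows.append([i, j, d, size[next_id]])
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (size[i] * dik + size[j] * djk) / (size[i] + size[j])
            dist[(min(k, next_id), max(k, next_id))] = dnew
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return TreeResult(labels=list(labels), distance_matrix=D,
                      newick=newick[active[0]] + ";",
                      linkage=np.array(linkage_rows, dtype=float))
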