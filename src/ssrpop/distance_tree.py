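"""Band-sharing distances, UPGMA clustering with bootstrap support, Evanno ΔK.

The genetic distance between two band profiles is one minus the Dice
(Nei–Li band-sharing) similarity: with a shared presences and b, c bands
unique to each profile,

    d = 1 - 2a / (2a + b + c)

which is the standard convention for dominant fragment data ("Nei's
distance" and "Dice distance" name the same quantity here).

UPGMA merges the closest pair of clusters; the distance from the merged
cluster to any other is the size-weighted mean of its members' distances,
and the merge node sits at height = merge distance / 2, yielding an
ultrametric tree.  Ties in the merge order are broken by the
lexicographically smallest pair of cluster labels so trees are
deterministic.

Bootstrap support resamples fragments (band columns) with replacement —
the only replicable unit for dominant data — rebuilds distance + UPGMA,
and reports for each clade of the original tree the percentage of
replicate trees containing that exact leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .marker_stats import BandMatrix

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "UltrametricTree",
    "DeltaKTable",
    "dice_distance",
    "distance_matrix",
    "upgma",
    "bootstrap_upgma",
    "evanno_delta_k",
]


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal pairwise distances with labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy condensed) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def similarity(self) -> np.ndarray:
        """1 - distance view (unit diagonal)."""
        return 1.0 - self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def dice_distance(profile_a: Sequence[int], profile_b: Sequence[int]) -> float:
    """1 - Dice similarity of two equal-length binary band profiles."""
    a = np.asarray(profile_a)
    b = np.asarray(profile_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("profiles must be non-empty")
    shared = int(np.sum((a == 1) & (b == 1)))
    mism = int(np.sum(a != b))
    denom = 2 * shared + mism
    if denom == 0:  # both all-absent: identical by convention
        return 0.0
    return 1.0 - 2.0 * shared / denom


def _dice_array(X: np.ndarray) -> np.ndarray:
    shared = X @ X.T
    sums = X.sum(axis=1)
    denom = sums[:, None] + sums[None, :]  # 2a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * shared / denom
    d[denom == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def distance_matrix(band_matrix: BandMatrix) -> DistanceMatrix:
    """All-pairs Dice distance over the accessions of a band matrix."""
    X = band_matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 accessions")
    return DistanceMatrix(band_matrix.accessions, _dice_array(X))


@dataclass
class TreeNode:
    """Node of a rooted tree; leaves carry a name, internal nodes a height."""

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None  # percent, internal nodes after bootstrap

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out


@dataclass
class UltrametricTree:
    """Rooted UPGMA tree; node heights are merge distances / 2."""

    root: TreeNode

    @property
    def leaves(self) -> list[str]:
        return self.root.leaf_names()

    def clades(self) -> dict[frozenset, TreeNode]:
        """Leaf-name set of every internal node (root included)."""
        out: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode):
            if not node.is_leaf:
                out[frozenset(node.leaf_names())] = node
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise leaf distances implied by the tree (2 x merge heights)."""
        labels = sorted(self.leaves)
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            groups = [walk(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d[idx[a], idx[b]] = d[idx[b], idx[a]] = 2.0 * node.height
            return [l for g in groups for l in g]

        walk(self.root)
        return DistanceMatrix(labels, d)

    def to_newick(self, support_threshold: float | None = None) -> str:
        """Newick string with branch lengths and supports as internal labels.

        ``support_threshold`` suppresses support labels at or below the
        given percentage in the rendered output (all supports stay on the
        tree object itself).
        """

        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.6g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            label = ""
            if node.support is not None and (
                support_threshold is None or node.support > support_threshold
            ):
                label = f"{node.support:g}"
            return f"({inner}){label}:{bl:.6g}"

        root = self.root
        inner = ",".join(fmt(c, root.height) for c in root.children)
        label = f"{root.support:g}" if root.support is not None else ""
        return f"({inner}){label};"


def upgma(dist: DistanceMatrix) -> UltrametricTree:
    """UPGMA (size-weighted average linkage) tree from a distance matrix."""
    if dist.n < 2:
        raise ValueError("need at least 2 labels")
    if np.isnan(dist.values).any():
        raise ValueError("distance matrix contains NaN")
    d = dist.values.astype(float).copy()
    n = dist.n
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=dist.labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    # cluster key = lexicographically smallest leaf label, for tie-breaking
    keys = {i: dist.labels[i] for i in range(n)}
    active = list(range(n))
    big = np.inf
    while len(active) > 1:
        sub = d[np.ix_(active, active)]
        np.fill_diagonal(sub, big)
        dmin = sub.min()
        ties = np.argwhere(sub == dmin)
        best = None
        for ai, aj in ties:
            if ai >= aj:
                continue
            i, j = active[ai], active[aj]
            pair = tuple(sorted((keys[i], keys[j])))
            if best is None or pair < best[0]:
                best = (pair, i, j)
        _, i, j = best
        merged = TreeNode(height=dmin / 2.0, children=[nodes[i], nodes[j]])
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (si * d[i, k] + sj * d[j, k]) / (si + sj)
        nodes[i] = merged
        sizes[i] = si + sj
        keys[i] = min(keys[i], keys[j])
        active.remove(j)
    return UltrametricTree(root=nodes[active[0]])


def bootstrap_upgma(
    band_matrix: BandMatrix, n_reps: int = 1000, seed: int | None = None
) -> UltrametricTree:
    """UPGMA tree of the band matrix with fragment-bootstrap clade supports."""
    n_acc = len(band_matrix.accessions)
    n_frag = len(band_matrix.fragments)
    if n_acc < 3:
        raise ValueError("need at least 3 accessions for bootstrap support")
    if n_frag < 2:
        raise ValueError("need at least 2 fragments to resample")
    tree = upgma(distance_matrix(band_matrix))
    clades = tree.clades()
    counts = {cl: 0 for cl in clades}
    rng = np.random.default_rng(seed)
    X = band_matrix.values.to_numpy(dtype=float)
    labels = band_matrix.accessions
    for _ in range(n_reps):
        cols = rng.integers(0, n_frag, size=n_frag)
        rep_tree = upgma(DistanceMatrix(labels, _dice_array(X[:, cols])))
        rep_clades = set()

        def collect(node: TreeNode):
            if not node.is_leaf:
                rep_clades.add(frozenset(node.leaf_names()))
                for c in node.children:
                    collect(c)

        collect(rep_tree.root)
        for cl in counts:
            if cl in rep_clades:
                counts[cl] += 1
    for cl, node in clades.items():
        node.support = 100.0 * counts[cl] / n_reps
    return tree


@dataclass
class DeltaKTable:
    """Evanno ΔK table: per K the mean/sd ln-likelihood, |L''| and ΔK."""

    table: pd.DataFrame  # index K; columns mean_lnP, sd_lnP, abs_l2, delta_k

    @property
    def best_k(self) -> int:
        return int(self.table["delta_k"].idxmax())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="K")


def evanno_delta_k(lnp_runs: Mapping[int, Iterable[float]]) -> DeltaKTable:
    """ΔK = |L''(K)| / sd(L(K)) over replicate STRUCTURE-style ln-likelihoods.

    ``lnp_runs`` maps each K to its per-run mean ln-probabilities; at least
    three consecutive K values with >=2 runs each are required.  ΔK is
    defined only for interior K.
    """
    ks = sorted(lnp_runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >=3 consecutive K values")
    means, sds = {}, {}
    for k in ks:
        runs = np.asarray(list(lnp_runs[k]), dtype=float)
        if runs.size < 2:
            raise ValueError(f"K={k}: need >=2 runs")
        means[k] = runs.mean()
        sds[k] = runs.std(ddof=1)
    rows = []
    for k in ks:
        l2 = dk = np.nan
        if ks[0] < k < ks[-1]:
            lp_next = means[k + 1] - means[k]
            lp_here = means[k] - means[k - 1]
            l2 = abs(lp_next - lp_here)
            if sds[k] == 0.0:
                raise ValueError(f"K={k}: sd of ln-likelihood is 0, ΔK undefined")
            dk = l2 / sds[k]
        rows.append(
            {"K": k, "mean_lnP": means[k], "sd_lnP": sds[k], "abs_l2": l2, "delta_k": dk}
        )
    return DeltaKTable(pd.DataFrame(rows).set_index("K"))
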