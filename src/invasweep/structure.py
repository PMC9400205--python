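"""Population-structure summaries: allele-sharing (IBS) distances,
neighbor-joining tree with Newick output, and PCA of the genotype matrix.

The distance between two individuals is 1 minus the proportion of alleles
identical by state over sites where both are called.  NJ follows the
Saitou-Nei agglomeration with the standard Q-criterion; on an additive
distance matrix it reconstructs the generating tree exactly.  PCA uses the
Patterson (smartpca) normalization: mean-imputed dosages centered by 2p and
scaled by sqrt(2p(1-p)).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray       # symmetric, zero diagonal, values in [0, 1]
    pair_sites: np.ndarray   # usable (both-called) site count per pair

    def validate(self) -> None:
        d = self.matrix
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if np.diag(d).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (d < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    """Node of an (unrooted) NJ tree; ``length`` is the output branch length
    to the parent (negative NJ estimates clamped to 0) and ``raw_length``
    the unclamped estimate."""

    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    raw_length: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree represented with a trifurcating root."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    def leaf_path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distance matrix (raw, pre-clamp lengths);
        on an additive input matrix this reproduces it exactly."""
        names = self.leaf_names
        index = {n: i for i, n in enumerate(names)}
        k = len(names)
        dist = np.zeros((k, k))

        def below(node):
            """[(leaf index, raw path length to `node`)]"""
            if node.is_leaf:
                return [(index[node.name], 0.0)]
            out = []
            for c in node.children:
                out.extend((i, d + c.raw_length) for i, d in below(c))
            return out

        def walk(node):
            groups = [below(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i, di in groups[gi]:
                        for j, dj in groups[gj]:
                            d = (di + node.children[gi].raw_length
                                 + dj + node.children[gj].raw_length)
                            dist[i, j] = dist[j, i] = d
            for c in node.children:
                walk(c)

        walk(self.root)
        return names, dist


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, length = n_samples
    coordinates: np.ndarray        # (n_samples, k) scores
    variance_explained: np.ndarray  # fractions for the k components
    sample_ids: list[str]


# ---------------------------------------------------------------------------

def ibs_distance(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None
                 ) -> DistanceMatrix:
    """1 - IBS allele-sharing distance over pairwise-complete sites.

    For a pair with genotypes g_i, g_j at m shared called sites the shared
    fraction is sum(2 - |g_i - g_j|) / (2 m); a pair with no shared called
    site is an error (the matrix would be undefined).
    """
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    ids = [gm.samples[i] for i in sample_idx]
    if len(ids) < 2:
        raise ValueError("need at least two samples for a distance matrix")
    d = gm.dosage[:, sample_idx].astype(np.float64)
    d[d == MISSING] = np.nan
    n = len(ids)
    dist = np.zeros((n, n))
    pair_sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        pair_sites[i, i] = int(np.isfinite(d[:, i]).sum())
        for j in range(i + 1, n):
            both = np.isfinite(d[:, i]) & np.isfinite(d[:, j])
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"samples {ids[i]!r} and {ids[j]!r} share "
                                 "no called sites")
            diff = np.abs(d[both, i] - d[both, j]).sum()
            share = (2.0 * m - diff) / (2.0 * m)
            dist[i, j] = dist[j, i] = 1.0 - share
            pair_sites[i, j] = pair_sites[j, i] = m
    out = DistanceMatrix(ids, dist, pair_sites)
    out.validate()
    if (dist > 1.0).any():  # allele-sharing distances are proportions
        raise AssertionError("IBS distance exceeded 1")
    return out


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by the smallest (i, j) pair in current node order
    (deterministic across runs).  Negative branch-length estimates are
    clamped to zero in ``length`` with the raw value kept in ``raw_length``.
    """
    dm.validate()
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    nodes = [TreeNode(name=s) for s in dm.ids]
    d = dm.matrix.astype(float).copy()

    def set_len(node, raw):
        node.raw_length = float(raw)
        node.length = float(max(raw, 0.0))

    while len(nodes) > 3:
        k = len(nodes)
        r = d.sum(axis=1)
        # Q_ij = (k-2) d_ij - r_i - r_j; pick the minimum, first pair wins ties
        q = (k - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.inf
        bi = bj = -1
        for i in range(k):
            for j in range(i + 1, k):
                if q[i, j] < best - 1e-12:
                    best, bi, bj = q[i, j], i, j
        li = 0.5 * d[bi, bj] + (r[bi] - r[bj]) / (2.0 * (k - 2))
        lj = d[bi, bj] - li
        parent = TreeNode()
        set_len(nodes[bi], li)
        set_len(nodes[bj], lj)
        parent.children = [nodes[bi], nodes[bj]]
        d_new = 0.5 * (d[bi] + d[bj] - d[bi, bj])
        keep = [x for x in range(k) if x not in (bi, bj)]
        d2 = np.empty((k - 1, k - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = d_new[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[x] for x in keep] + [parent]

    # join the final three nodes at a trifurcating root (three-point formulas)
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, ln in ((a, la), (b, lb), (c, lc)):
        set_len(node, ln)
    root = TreeNode(children=[a, b, c])
    return PhyloTree(root)


def _quote(name: str) -> str:
    if any(ch in name for ch in " ()[]:;,'\t\n"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths; names needing it are quoted."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{_quote(node.name)}:{node.length:.10g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length:.10g}"

    inner = ",".join(render(c) for c in tree.root.children)
    return f"({inner});"


def pca(gm: GenotypeMatrix, sample_idx: np.ndarray | None = None, k: int = 2
        ) -> PCAResult:
    """PCA of the dosage matrix under the Patterson normalization.

    Missing dosages are mean-imputed per site; each site is centered by 2p
    and scaled by sqrt(2p(1-p)) with p the alt-allele frequency among called
    genotypes; monomorphic sites (p in {0, 1}) drop out.  Coordinates are
    eigenvector loadings scaled by sqrt(eigenvalue) (principal-component
    scores); their sign is arbitrary.
    """
    if sample_idx is None:
        sample_idx = np.arange(gm.n_samples)
    ids = [gm.samples[i] for i in sample_idx]
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two samples")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds the {n - 1} informative components")
    x = gm.dosage[:, sample_idx].astype(float).T  # samples x sites
    x[x == MISSING] = np.nan
    p = np.nanmean(x, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    x = x[:, keep]
    p = p[keep]
    if x.shape[1] == 0:
        raise ValueError("no polymorphic sites left for PCA")
    col_mean = 2.0 * p
    x = np.where(np.isnan(x), col_mean, x)
    x = (x - col_mean) / np.sqrt(2.0 * p * (1.0 - p))
    cov = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])[None, :]
    total = eigval.sum()
    frac = eigval[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(eigval, coords, frac, ids)
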