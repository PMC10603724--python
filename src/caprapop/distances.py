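"""Genetic distances, neighbor-joining trees with bootstrap support, and MDS.

Individual-level structure uses allele-sharing (identity-by-state) distances;
breed-level structure uses Reynolds' coancestry distance, with the
multi-locus theta computed as a ratio of sums over loci and
D = -ln(1 - theta).  Dendrograms are built by Saitou-Nei neighbor joining,
with branch support from bootstrap resampling of SNP columns, and the
distance geometry is visualized through classical multidimensional scaling
(principal coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import dendropy

from .genotypes import MISSING, DataError, GenotypeMatrix, allele_freq

THETA_CAP = 1.0 - 1e-12


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=np.float64)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DataError("distance matrix shape must match labels")
        if not np.all(np.isfinite(self.d)):
            raise DataError("distances must be finite")
        if not np.allclose(self.d, self.d.T):
            raise DataError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise DataError("distance matrix diagonal must be zero")
        if (self.d < -1e-12).any():
            raise DataError("distances must be nonnegative")

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


@dataclass
class MDSResult:
    coordinates: np.ndarray  # samples x k
    eigenvalues: np.ndarray  # length k, non-increasing
    labels: list

    def to_tsv(self, path):
        k = self.coordinates.shape[1]
        with open(path, "w") as fh:
            fh.write("label\t" + "\t".join(f"C{i + 1}" for i in range(k)) + "\n")
            for lab, row in zip(self.labels, self.coordinates):
                fh.write(lab + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean allele-sharing over jointly called SNPs, for every pair.

    Per SNP the similarity between genotypes g_i, g_j is (2 - |g_i - g_j|)/2,
    so identical genotypes share 1, opposite homozygotes share 0.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 samples")
    called = (gm.calls != MISSING).astype(np.float64)
    ind = [(gm.calls == k).astype(np.float64) for k in (0, 1, 2)]
    absdiff = (
        ind[0] @ ind[1].T + ind[1] @ ind[0].T
        + 2.0 * (ind[0] @ ind[2].T + ind[2] @ ind[0].T)
        + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    )
    n_joint = called @ called.T
    no_overlap = np.argwhere(n_joint == 0)
    if no_overlap.size:
        i, j = no_overlap[0]
        raise DataError(
            f"samples {gm.samples[i].sample_id!r} and {gm.samples[j].sample_id!r} "
            "share no called SNP"
        )
    d = absdiff / (2.0 * n_joint)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(labels=gm.sample_ids, d=d)


def _reynolds_from_freqs(p: np.ndarray, q: np.ndarray):
    """Reynolds theta and D from two frequency vectors (NaN entries skipped)."""
    ok = ~(np.isnan(p) | np.isnan(q))
    p, q = p[ok], q[ok]
    num = 2.0 * (p - q) ** 2
    den = 2.0 * (1.0 - (p * q + (1.0 - p) * (1.0 - q)))
    pos = den > 0
    if not pos.any():
        raise DataError("no SNP with positive Reynolds denominator")
    theta = float(num[pos].sum() / den[pos].sum())
    theta_c = min(theta, THETA_CAP)
    return theta, float(-np.log(1.0 - theta_c))


def reynolds_distance(gm: GenotypeMatrix, breed_a: str, breed_b: str):
    """Reynolds coancestry distance between two breeds: ``(theta, D)``."""
    ids = gm.sample_ids
    p = allele_freq(gm, [ids[i] for i in gm.breed_index(breed_a)])
    q = allele_freq(gm, [ids[i] for i in gm.breed_index(breed_b)])
    return _reynolds_from_freqs(p, q)


def breed_freq_matrix(gm: GenotypeMatrix):
    """Per-breed alternate-allele frequencies: ``(breeds, breeds x SNPs array)``."""
    breeds = gm.breeds
    ids = gm.sample_ids
    freqs = np.stack(
        [allele_freq(gm, [ids[i] for i in gm.breed_index(b)]) for b in breeds]
    )
    return breeds, freqs


def reynolds_matrix(gm: GenotypeMatrix, use_theta: bool = False) -> DistanceMatrix:
    """Pairwise Reynolds D (or theta) among all breeds."""
    breeds, freqs = breed_freq_matrix(gm)
    return _reynolds_matrix_from_freqs(breeds, freqs, use_theta=use_theta)


def _reynolds_matrix_from_freqs(breeds, freqs, use_theta=False) -> DistanceMatrix:
    n = len(breeds)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            theta, D = _reynolds_from_freqs(freqs[i], freqs[j])
            d[i, j] = d[j, i] = theta if use_theta else D
    return DistanceMatrix(labels=list(breeds), d=d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; negative branch lengths are clamped to
    zero with the deficit moved to the sibling edge."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 labels")
    taxa = dendropy.TaxonNamespace(dm.labels)
    nodes = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    D = dm.d.astype(np.float64).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)  # first (i,j) on ties
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = d_new[keep]
        D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    lengths = [
        (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0,
        (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0,
        (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0,
    ]
    center = dendropy.Node()
    for nd, ln in zip(nodes, lengths):
        center.add_child(nd)
        nd.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions as frozensets of the side excluding the
    lexicographically smallest leaf label."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    full = set(labels)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(full - below) if ref in below else below
        if 2 <= len(side) <= len(full) - 2:
            splits.add(side)
    return splits


def tree_path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity oracle)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels=labels, d=d)


def bootstrap_breed_tree(gm: GenotypeMatrix, B: int = 100, seed: int = 0) -> dendropy.Tree:
    """Reynolds-distance NJ tree over breeds with bootstrap split supports.

    Supports = fraction of ``B`` SNP-column bootstrap replicates whose NJ tree
    contains each bipartition of the full-data tree; stored as internal-node
    labels.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    breeds, freqs = breed_freq_matrix(gm)
    if len(breeds) < 3:
        raise ValueError("need >= 3 breeds")
    full = neighbor_joining(_reynolds_matrix_from_freqs(breeds, freqs))
    target = tree_splits(full)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    n_snps = freqs.shape[1]
    for _ in range(B):
        cols = rng.integers(0, n_snps, size=n_snps)
        rep = neighbor_joining(_reynolds_matrix_from_freqs(breeds, freqs[:, cols]))
        rep_splits = tree_splits(rep)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    full_labels = sorted(t.label for t in full.taxon_namespace)
    ref = full_labels[0]
    all_set = set(full_labels)
    for node in full.preorder_node_iter():
        if node is full.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(all_set - below) if ref in below else below
        if side in counts:
            node.label = f"{counts[side] / B:.2f}"
    return full


# ---------------------------------------------------------------------------
# Classical MDS (principal coordinates)
# ---------------------------------------------------------------------------


def classical_mds(dm: DistanceMatrix, k: int) -> MDSResult:
    """Torgerson double-centering of squared distances + eigendecomposition.

    Coordinates are top-k eigenvectors scaled by sqrt(eigenvalue); dimensions
    with non-positive eigenvalues are zero-filled (with a warning when
    substantially negative eigenvalues indicate a non-Euclidean input).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(dm.labels)
    D2 = dm.d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((Bmat + Bmat.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0)
    if (evals < -1e-8 * scale).any():
        warnings.warn(
            "distance matrix is not Euclidean: negative eigenvalues zero-filled",
            stacklevel=2,
        )
    coords = np.zeros((n, k))
    out_evals = np.zeros(k)
    kk = min(k, n)
    pos = np.maximum(evals[:kk], 0.0)
    coords[:, :kk] = evecs[:, :kk] * np.sqrt(pos)[None, :]
    out_evals[:kk] = np.where(evals[:kk] > 0, evals[:kk], 0.0)
    return MDSResult(coordinates=coords, eigenvalues=out_evals, labels=list(dm.labels))
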