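"""Distance phylogenetics: K2P matrices, neighbor-joining with bootstrap,
and Robinson–Foulds congruence between transposase and viral-gene trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .divergence import SaturationError

#: fixed concatenation order for the viral-gene tree
CONCAT_ORDER = ("pol", "hel", "ter", "mcp", "mem")

_CHAR = np.full(128, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CHAR[ord(_b)] = _i


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if np.diag(self.d).any():
            raise ValueError("diagonal must be zero")
        if (self.d < 0).any() or not np.isfinite(self.d).all():
            raise ValueError("distances must be finite and non-negative")

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


@dataclass
class CongruenceResult:
    rf: int
    rf_normalized: float
    shared_leaf_set: list[str]


def _encode_alignment(aligned: dict[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(aligned)
    L = {len(s) for s in aligned.values()}
    if len(L) != 1:
        raise ValueError("alignment is not rectangular")
    mat = np.stack(
        [_CHAR[np.frombuffer(aligned[k].upper().encode("ascii"), dtype=np.uint8)] for k in labels]
    )
    return labels, mat


def _k2p_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    mask = (a < 4) & (b < 4)
    n = int(mask.sum())
    if n == 0:
        raise SaturationError("no comparable columns")
    diff = (a != b) & mask
    purine_a = (a == 0) | (a == 2)
    purine_b = (b == 0) | (b == 2)
    ts = int((diff & (purine_a == purine_b)).sum())
    tv = int(diff.sum()) - ts
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"saturated pair (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def distance_matrix(
    aligned: dict[str, str], on_saturation: str = "raise", cap: float = 5.0
) -> DistanceMatrix:
    """Pairwise K2P distances with pairwise deletion of gap/N columns.

    Saturated pairs raise by default (naming the pair); with
    ``on_saturation='cap'`` they are clamped to ``cap`` substitutions/site
    (used inside bootstrap replicates, where an occasional saturated
    resample should not abort the run).
    """
    labels, mat = _encode_alignment(aligned)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = _k2p_from_codes(mat[i], mat[j])
            except SaturationError:
                if on_saturation != "cap":
                    raise SaturationError(
                        f"saturated pair ({labels[i]}, {labels[j]})"
                    ) from None
                dij = cap
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; ties broken by the lowest index pair.

    Negative branch-length estimates are clamped to zero. For three leaves
    this reduces to the closed-form star tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    D = dm.d.astype(float).copy()
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        best = (math.inf, -1, -1)
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
    a, b = nodes
    final = max(D[0, 1], 0.0)
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    b.edge.length = final
    a.add_child(b)
    tree.seed_node = a
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# splits, RF distance, bootstrap


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _splits(tree: dendropy.Tree, leaves: set[str] | None = None) -> set[frozenset[str]]:
    """Non-trivial bipartitions, restricted to ``leaves``, orientation-normalized.

    Each split is represented by the side not containing the smallest leaf
    label, so rooted placement of the dendropy seed node is irrelevant.
    """
    leaves = leaves or leaf_labels(tree)
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = {
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label in leaves
        }
        if ref in below:
            below = leaves - below
        if 2 <= len(below) <= len(leaves) - 2:
            out.add(frozenset(below))
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> CongruenceResult:
    """Symmetric-difference (RF) distance over the shared leaf set."""
    shared = leaf_labels(t1) & leaf_labels(t2)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared leaves")
    s1 = _splits(t1, shared)
    s2 = _splits(t2, shared)
    rf = len(s1 ^ s2)
    denom = 2 * (len(shared) - 3)
    return CongruenceResult(rf, rf / denom, sorted(shared))


def bootstrap_support(
    aligned: dict[str, str], n_replicates: int = 1000, seed: int = 0
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ point tree with split supports from column-resampled replicates.

    Support is the percentage of replicate NJ trees containing each
    non-trivial split of the point tree, written onto internal node labels.
    """
    labels, mat = _encode_alignment(aligned)
    if mat.shape[1] < 2:
        raise ValueError("alignment must have at least 2 columns")
    point = neighbor_joining(distance_matrix(aligned, on_saturation="cap"))
    leaves = set(labels)
    target_splits = _splits(point, leaves)
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    L = mat.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        resampled = mat[:, cols]
        dm = _distance_matrix_from_codes(labels, resampled)
        rep_tree = neighbor_joining(dm)
        rep_splits = _splits(rep_tree, leaves)
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1
    supports = {s: 100.0 * c / n_replicates for s, c in counts.items()}
    # annotate internal nodes of the point tree
    ref = min(leaves)
    for node in point.postorder_internal_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if ref in below:
            below = leaves - below
        key = frozenset(below)
        if key in supports:
            node.label = f"{supports[key]:.0f}"
    return point, supports


def _distance_matrix_from_codes(labels: list[str], mat: np.ndarray) -> DistanceMatrix:
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = _k2p_from_codes(mat[i], mat[j])
            except SaturationError:
                dij = 5.0
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d)


def concatenate_alignments(
    gene_alignments: dict[str, dict[str, str]],
    taxa: list[str],
    order: tuple[str, ...] = CONCAT_ORDER,
) -> dict[str, str]:
    """Column-wise join of per-gene alignments in the fixed gene order."""
    genes = [g for g in order if g in gene_alignments]
    if not genes:
        raise ValueError("no genes from the concatenation order are present")
    for g in genes:
        missing = [t for t in taxa if t not in gene_alignments[g]]
        if missing:
            raise KeyError(f"taxon {missing[0]!r} missing from alignment of gene {g!r}")
    return {t: "".join(gene_alignments[g][t] for g in genes) for t in taxa}


def congruence_test(
    transposase_aligned: dict[str, str],
    viral_gene_alignments: dict[str, dict[str, str]],
    shared_taxa: list[str],
) -> tuple[CongruenceResult, dendropy.Tree, dendropy.Tree]:
    """RF congruence between the transposase tree and the concatenated
    viral-gene tree over the shared taxa."""
    missing = [t for t in shared_taxa if t not in transposase_aligned]
    if missing:
        raise KeyError(f"taxon {missing[0]!r} missing from the transposase alignment")
    tp_aln = {t: transposase_aligned[t] for t in shared_taxa}
    viral_aln = concatenate_alignments(viral_gene_alignments, shared_taxa)
    t_tree = neighbor_joining(distance_matrix(tp_aln, on_saturation="cap"))
    v_tree = neighbor_joining(distance_matrix(viral_aln, on_saturation="cap"))
    return robinson_foulds(t_tree, v_tree), t_tree, v_tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
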