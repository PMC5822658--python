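"""Subtype clustering of element copies by pairwise nucleotide identity.

Copies with pairwise identity above 0.90 belong to one subtype
(single-linkage over the thresholded identity graph); one representative
per subtype is kept for phylogenetics, and a within-subtype identity check
(> 0.95 expected) flags suspicious clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import edlib
import numpy as np

from .divergence import global_align_nt, pairwise_identity

SAME_SUBTYPE_IDENTITY = 0.90
MIN_WITHIN_IDENTITY = 0.95

#: above this length, identity comes from edlib edit distance instead of
#: full affine DP (quadratic memory); for substitution-dominated copies the
#: two agree
_LONG_SEQ = 2000


@dataclass
class SubtypeClustering:
    labels: list[str]  # member ids, input order preserved after sorting
    clusters: dict[str, list[str]]  # subtype label -> member ids
    representatives: dict[str, str]  # subtype label -> member id
    identity_matrix: np.ndarray  # symmetric, aligned to ``labels`` order

    def subtype_of(self, member_id: str) -> str:
        for label, members in self.clusters.items():
            if member_id in members:
                return label
        raise KeyError(member_id)

    @property
    def n_subtypes(self) -> int:
        return len(self.clusters)


def _identity(a: str, b: str) -> float:
    if min(len(a), len(b)) > _LONG_SEQ:
        res = edlib.align(a, b, task="distance")
        return max(0.0, 1.0 - res["editDistance"] / ((len(a) + len(b)) / 2.0))
    ident = pairwise_identity(global_align_nt(a, b))
    return 0.0 if ident is None else ident


def identity_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    ids = sorted(seqs)
    n = len(ids)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = _identity(seqs[ids[i]], seqs[ids[j]])
    return ids, mat


def cluster_subtypes(
    seqs: dict[str, str], same_subtype_threshold: float = SAME_SUBTYPE_IDENTITY
) -> SubtypeClustering:
    """Single-linkage connected components of the identity > threshold graph.

    Labels are ``subtype_1, subtype_2, ...`` ordered by each cluster's
    smallest member id, so the outcome is independent of input order.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    ids, mat = identity_matrix(seqs)
    n = len(ids)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if mat[i, j] > same_subtype_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for k, mid in enumerate(ids):
        groups.setdefault(find(k), []).append(mid)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    clusters = {f"subtype_{i + 1}": sorted(g) for i, g in enumerate(ordered)}
    reps = {label: select_representative(members, seqs) for label, members in clusters.items()}
    return SubtypeClustering(ids, clusters, reps, mat)


def select_representative(cluster: list[str], seqs: dict[str, str]) -> str:
    """Longest ungapped sequence; ties broken lexicographically by id."""
    if not cluster:
        raise ValueError("empty cluster")
    return min(cluster, key=lambda mid: (-len(seqs[mid].replace("-", "")), mid))


def validate_within_subtype(
    clustering: SubtypeClustering, min_within_identity: float = MIN_WITHIN_IDENTITY
) -> list[str]:
    """Warn for every within-subtype pair below the expected identity floor."""
    idx = {mid: i for i, mid in enumerate(clustering.labels)}
    warnings = []
    for label, members in clustering.clusters.items():
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                a, b = members[a_i], members[b_i]
                ident = clustering.identity_matrix[idx[a], idx[b]]
                if ident < min_within_identity:
                    warnings.append(
                        f"{label}: pair ({a}, {b}) identity {ident:.3f} "
                        f"< {min_within_identity:.2f}"
                    )
    return warnings


def write_subtypes_tsv(clustering: SubtypeClustering, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("member_id\tsubtype_label\trepresentative\n")
        for label, members in clustering.clusters.items():
            for mid in members:
                rep = int(clustering.representatives[label] == mid)
                fh.write(f"{mid}\t{label}\t{rep}\n")


def write_identity_matrix_tsv(clustering: SubtypeClustering, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(clustering.labels) + "\n")
        for i, mid in enumerate(clustering.labels):
            row = "\t".join(f"{v:.4f}" for v in clustering.identity_matrix[i])
            fh.write(f"{mid}\t{row}\n")
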