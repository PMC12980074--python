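"""Eigenvalue-weighted distances and k-nearest-neighbor selection.

The geometric engine of the method: samples are points in the space of
the first M principal (or haplotype) components, and the distance between
query sample i and reference sample j is the Euclidean distance with each
component's squared difference weighted by that component's eigenvalue,

    d(i, j) = sqrt( sum_m  lam_m (x_{i,m} - x_{j,m})^2 ),

where the M eigenvalues in use are first normalized to sum to one.
Normalization happens *after* truncating to the top-M components, so the
distances do not depend on how many extra components the input file
happens to carry, nor on the overall scale of the eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io import ComponentMatrix

__all__ = [
    "NeighborSet",
    "standardize",
    "normalize_eigenvalues",
    "pairwise_distances",
    "nearest_neighbors",
]


@dataclass(frozen=True)
class NeighborSet:
    """The k nearest reference rows of one query sample.

    ``neighbor_distances`` are sorted nondecreasing; ties are broken by
    ascending reference row index, so the selection is a deterministic
    truncation of a stable sort of (distance, index) pairs.
    """

    query_index: int
    neighbor_indices: np.ndarray
    neighbor_distances: np.ndarray


def standardize(
    components: ComponentMatrix,
    stats_source: ComponentMatrix | None = None,
) -> ComponentMatrix:
    """Transform each score column to zero mean / unit variance.

    Statistics (per-column mean and population SD, i.e. divide-by-n) come
    from ``stats_source`` when given, otherwise from ``components``
    itself.  Standardizing with external statistics is how query samples
    that arrive after the reference panel are placed on the same scale.
    Eigenvalues are carried through unchanged.
    """
    src = components if stats_source is None else stats_source
    if src.n_components != components.n_components:
        raise ValueError(
            f"stats source has {src.n_components} components, "
            f"matrix has {components.n_components}"
        )
    mean = src.scores.mean(axis=0)
    sd = src.scores.std(axis=0)  # population SD (ddof=0)
    zero = np.flatnonzero(sd <= 0)
    if zero.size:
        raise ValueError(
            f"cannot standardize: column(s) {list(zero + 1)} have zero SD"
        )
    return ComponentMatrix(
        components.sample_ids,
        (components.scores - mean) / sd,
        components.eigenvalues,
        standardized=True,
    )


def joint_standardize(
    query: ComponentMatrix, reference: ComponentMatrix
) -> tuple[ComponentMatrix, ComponentMatrix]:
    """Standardize query and reference with pooled column statistics.

    Mirrors standardizing all samples together before splitting into
    reference and query sets.  Samples present in both matrices are
    counted twice in the pooled statistics; callers with overlapping sets
    should deduplicate first.
    """
    pooled = ComponentMatrix(
        tuple(f"q:{s}" for s in query.sample_ids)
        + tuple(f"r:{s}" for s in reference.sample_ids),
        np.vstack([query.scores, reference.scores]),
        reference.eigenvalues,
    )
    return standardize(query, pooled), standardize(reference, pooled)


def normalize_eigenvalues(eigenvalues: np.ndarray) -> np.ndarray:
    """Scale nonnegative eigenvalues to sum to one.

    Called after subsetting to the top-M components in use; all-zero
    input is an error.
    """
    eig = np.asarray(eigenvalues, dtype=float).ravel()
    if eig.size == 0:
        raise ValueError("empty eigenvalue vector")
    if np.any(eig < 0):
        raise ValueError("eigenvalues must be nonnegative")
    total = eig.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero; cannot normalize")
    return eig / total


def pairwise_distances(
    query: ComponentMatrix, reference: ComponentMatrix, m: int
) -> np.ndarray:
    """Eigenvalue-weighted Euclidean distance matrix (n_Q x n_R).

    Uses the top ``m`` components with their eigenvalues normalized to
    sum to one.  O(n_Q n_R m) time.
    """
    shared = min(query.n_components, reference.n_components)
    if not (1 <= m <= shared):
        raise ValueError(
            f"m={m} out of range; query/reference share {shared} components"
        )
    if query.n_components != reference.n_components or not np.allclose(
        query.eigenvalues, reference.eigenvalues
    ):
        raise ValueError(
            "query and reference must share the same eigenvalues "
            "(same decomposition)"
        )
    if query.standardized != reference.standardized:
        raise ValueError(
            "query and reference have mismatched standardization provenance"
        )
    lam = normalize_eigenvalues(reference.eigenvalues[:m])
    w = np.sqrt(lam)
    return cdist(query.scores[:, :m] * w, reference.scores[:, :m] * w)


def nearest_neighbors(
    distances_row: np.ndarray,
    k: int,
    exclude: frozenset | set = frozenset(),
    query_index: int = 0,
) -> NeighborSet:
    """The k smallest admissible entries of one distance row.

    Equivalent to a full stable sort of (distance, reference index) pairs
    truncated at k: ties at the cutoff go to the smaller reference index.
    ``exclude`` removes reference rows (e.g. the query itself) from
    consideration.
    """
    d = np.asarray(distances_row, dtype=float).ravel()
    n_r = d.size
    if exclude:
        admissible = np.array(
            [i for i in range(n_r) if i not in exclude], dtype=int
        )
    else:
        admissible = np.arange(n_r)
    if not (1 <= k <= admissible.size):
        raise ValueError(
            f"k={k} out of range; at most {admissible.size} reference "
            f"samples admissible after exclusion"
        )
    sub = d[admissible]
    order = np.argsort(sub, kind="stable")[:k]
    idx = admissible[order]
    return NeighborSet(query_index, idx, d[idx])
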