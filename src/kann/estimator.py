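"""The KANN ancestry estimator.

Each query sample's ancestry profile is a convex combination of the
profiles of its k nearest reference samples in eigenvalue-weighted
component space:

* ``p = 0`` — plain arithmetic mean over the k neighbors,
  q_{i,s} = (1/k) sum_{j in J} r_{j,s};
* ``p > 0`` — inverse-distance weighting with weights w(i,j) = d'(i,j)^-p,
  where d' = max(d, epsilon) floors tiny distances so that a reference
  essentially coincident with the query cannot receive an unbounded
  weight.

With one-hot reference profiles and p = 0 the estimate reduces to the
fraction of the k neighbors carrying each label — the conventional
discrete-reference mode comparable to PCA-regression tools such as Rye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ComponentMatrix, ProfileMatrix
from .knn_core import pairwise_distances

__all__ = ["KannParams", "estimate_profiles"]


@dataclass(frozen=True)
class KannParams:
    """Estimator parameters.

    k
        Number of nearest reference samples averaged per query.
    p
        Inverse-distance-weighting exponent (0 disables weighting).
        Default 3: a robust choice across reference-panel sizes when no
        dataset-specific optimization is possible.
    epsilon
        Minimum distance substituted for smaller distances before
        exponentiation; default 0.1.
    n_components
        Number of top components M used for distances; default 10.
    """

    k: int
    p: float = 3.0
    epsilon: float = 0.1
    n_components: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.p < 0:
            raise ValueError("p must be >= 0")
        if self.p > 0 and not self.epsilon > 0:
            raise ValueError("epsilon must be > 0 when p > 0")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def _align_profiles(
    reference: ComponentMatrix, ref_profiles: ProfileMatrix
) -> ProfileMatrix:
    ref_ids = set(reference.sample_ids)
    prof_ids = set(ref_profiles.sample_ids)
    if ref_ids != prof_ids:
        only_ref = sorted(ref_ids - prof_ids)[:10]
        only_prof = sorted(prof_ids - ref_ids)[:10]
        raise ValueError(
            "reference components and reference profiles do not cover the "
            f"same samples; components-only: {only_ref}, "
            f"profiles-only: {only_prof}"
        )
    return ref_profiles.reindex(list(reference.sample_ids))


def estimate_profiles(
    query: ComponentMatrix,
    reference: ComponentMatrix,
    ref_profiles: ProfileMatrix,
    params: KannParams,
    exclude_self: bool = True,
) -> ProfileMatrix:
    """Estimate an ancestry profile for every query sample.

    Parameters
    ----------
    query, reference
        Component matrices sharing the same decomposition (eigenvalues
        and standardization provenance).
    ref_profiles
        Known ancestry profiles of the reference samples; joined to
        ``reference`` by sample ID.
    params
        k, p, epsilon and the number of top components to use.
    exclude_self
        When a query sample ID also occurs in the reference set, leave
        that reference row out of its own neighbor search (leave-one-out
        semantics, as used in cross-validation). Keyed by sample ID.

    Returns
    -------
    ProfileMatrix
        One simplex row per query sample, population labels copied from
        ``ref_profiles``.
    """
    profiles = _align_profiles(reference, ref_profiles)
    r = profiles.proportions  # (n_R, S), row-aligned with reference
    n_r = reference.n_samples

    dist = pairwise_distances(query, reference, params.n_components)

    self_col = np.full(query.n_samples, -1, dtype=int)
    if exclude_self:
        ref_index = {s: j for j, s in enumerate(reference.sample_ids)}
        for i, sid in enumerate(query.sample_ids):
            j = ref_index.get(sid, -1)
            self_col[i] = j
            if j >= 0:
                dist[i, j] = np.inf

    admissible = np.where(self_col >= 0, n_r - 1, n_r)
    feasible = int(admissible.min())
    if params.k > feasible:
        raise ValueError(
            f"k={params.k} infeasible: at most {feasible} reference "
            "samples admissible per query after self-exclusion"
        )

    # Stable sort matches the (distance, reference index) tie-break rule.
    order = np.argsort(dist, axis=1, kind="stable")[:, : params.k]
    d = np.take_along_axis(dist, order, axis=1)  # (n_Q, k)
    neigh = r[order]  # (n_Q, k, S)

    if params.k == 1:
        est = neigh[:, 0, :]  # verbatim copy for any p
    elif params.p == 0:
        est = neigh.mean(axis=1)
    else:
        w = np.maximum(d, params.epsilon) ** (-params.p)
        if not np.all(np.isfinite(w)):
            raise ValueError(
                "non-finite neighbor weight (d^-p overflow); "
                "increase epsilon or decrease p"
            )
        totals = w.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError(
                "all neighbor weights underflowed to zero; "
                "decrease p or rescale the component space"
            )
        est = (w[:, :, None] * neigh).sum(axis=1) / totals[:, None]

    # Guard rounding drift: estimates are convex combinations of simplex rows.
    est = np.clip(est, 0.0, 1.0)
    return ProfileMatrix(query.sample_ids, profiles.population_labels, est)
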