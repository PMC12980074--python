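"""Synthetic admixture data in component space with known ground truth.

The generator encodes the modeling assumption that makes nearest-neighbor
ancestry regression sensible in the first place: each source population
is a cluster in component space, and an admixed individual with ancestry
profile pi sits, to first order, at the profile-weighted average of the
population centroids plus isotropic noise,

    x_i = sum_s pi_{i,s} * c_s + Normal(0, noise_sd * scale_m)  per component m,

with pi drawn from a Dirichlet (or forced one-hot for a configurable
fraction of the reference panel, assigned round-robin over populations).
Per-component noise scales decay geometrically (``eigenvalue_decay``),
mimicking the decaying variance spectrum of a real decomposition.  The
eigenvalues attached to the output are the *theoretical* per-component
variances of this sampling model (closed form from the Dirichlet first
and second moments), so runs are exactly reproducible and do not depend
on empirical column variances.

No genotypes are simulated: the generator works directly in component
space, which is the method's input contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import pdist

from .io import ComponentMatrix, ProfileMatrix

__all__ = ["SimConfig", "SimData", "simulate", "threshold_to_discrete"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings.

    Defaults describe a moderately hard recovery problem: 4 populations
    in 6 components, 800 reference / 200 query samples, centroids at
    least 8 noise-SDs apart, and sparse Dirichlet(0.5) admixture.

    n_populations : S, number of source populations.
    n_components : M, dimensionality of the component space.
    centroid_separation : minimum pairwise centroid distance, raw units.
    noise_sd : per-component isotropic noise SD before decay scaling.
    dirichlet_alpha : Dirichlet concentration; scalar = symmetric.
    eigenvalue_decay : noise variance of component m scales by decay^(m-1).
    frac_pure : fraction of reference samples forced one-hot (round-robin).
    frac_pure_query : same for query samples (default 0).
    n_structured : centroids differ only in the first n_structured
        components (None = all M); later components are pure noise.
    """

    n_populations: int = 4
    n_components: int = 6
    n_reference: int = 800
    n_query: int = 200
    centroid_separation: float = 8.0
    noise_sd: float = 1.0
    dirichlet_alpha: float | tuple = 0.5
    eigenvalue_decay: float = 0.7
    frac_pure: float = 0.0
    frac_pure_query: float = 0.0
    n_structured: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_populations, self.n_components,
               self.n_reference, self.n_query) < 1:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.centroid_separation > 0:
            raise ValueError("centroid_separation must be > 0")
        if not 0 < self.eigenvalue_decay <= 1:
            raise ValueError("eigenvalue_decay must be in (0, 1]")
        for name in ("frac_pure", "frac_pure_query"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_structured is not None and not (
            1 <= self.n_structured <= self.n_components
        ):
            raise ValueError("n_structured out of range")
        alpha = self.alpha_vector()
        if np.any(alpha <= 0):
            raise ValueError("dirichlet_alpha entries must be > 0")

    def alpha_vector(self) -> np.ndarray:
        a = np.asarray(self.dirichlet_alpha, dtype=float).ravel()
        if a.size == 1:
            a = np.full(self.n_populations, float(a[0]))
        if a.size != self.n_populations:
            raise ValueError(
                f"dirichlet_alpha has {a.size} entries for "
                f"{self.n_populations} populations"
            )
        return a


class SimData(NamedTuple):
    reference: ComponentMatrix
    reference_profiles: ProfileMatrix
    query: ComponentMatrix
    query_profiles: ProfileMatrix


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # Per-purpose substreams: adding draws to one stage never shifts another.
    return np.random.default_rng([config.seed, stream])


_MAX_PLACEMENT_TRIES = 1000


def _place_centroids(config: SimConfig) -> np.ndarray:
    s, m = config.n_populations, config.n_components
    dim = config.n_structured if config.n_structured is not None else m
    sep = config.centroid_separation
    rng = _rng(config, 0)
    for _ in range(_MAX_PLACEMENT_TRIES):
        pts = rng.normal(0.0, sep, size=(s, dim))
        if s == 1 or pdist(pts).min() >= sep:
            out = np.zeros((s, m))
            out[:, :dim] = pts
            return out
    raise RuntimeError(
        f"could not place {s} centroids at separation {sep} in {dim} "
        f"dimensions after {_MAX_PLACEMENT_TRIES} attempts"
    )


def _draw_profiles(
    config: SimConfig, n: int, frac_pure: float, rng: np.random.Generator
) -> np.ndarray:
    s = config.n_populations
    n_pure = int(round(frac_pure * n))
    profiles = np.zeros((n, s))
    for i in range(n_pure):  # round-robin pure assignment
        profiles[i, i % s] = 1.0
    if n > n_pure:
        profiles[n_pure:] = rng.dirichlet(config.alpha_vector(), n - n_pure)
    return profiles


def _noise_scales(config: SimConfig) -> np.ndarray:
    m = np.arange(config.n_components)
    return config.eigenvalue_decay ** (m / 2.0)


def _theoretical_eigenvalues(
    config: SimConfig, centroids: np.ndarray
) -> np.ndarray:
    """Closed-form per-component variance of the sampling model.

    The profile distribution is a mixture of the round-robin one-hot
    assignment (pure fraction) and the Dirichlet; the variance of the
    mixture of c_m-projections plus the noise variance gives each
    component's theoretical eigenvalue.
    """
    s = config.n_populations
    n_pure = int(round(config.frac_pure * config.n_reference)) + int(
        round(config.frac_pure_query * config.n_query)
    )
    n_total = config.n_reference + config.n_query
    f_pure = n_pure / n_total

    alpha = config.alpha_vector()
    a0 = alpha.sum()
    mu = alpha / a0
    second = (np.diag(alpha) + np.outer(alpha, alpha)) / (a0 * (a0 + 1))

    # Round-robin pure counts are deterministic; weight populations exactly.
    pure_w = np.zeros(s)
    n_pure_ref = int(round(config.frac_pure * config.n_reference))
    n_pure_qry = int(round(config.frac_pure_query * config.n_query))
    for n_p in (n_pure_ref, n_pure_qry):
        for i in range(n_p):
            pure_w[i % s] += 1
    if pure_w.sum() > 0:
        pure_w /= pure_w.sum()

    c = centroids  # (S, M)
    e_dir = c.T @ mu
    e2_dir = np.einsum("sm,st,tm->m", c, second, c)
    e_pure = c.T @ pure_w
    e2_pure = (c**2).T @ pure_w

    e1 = f_pure * e_pure + (1 - f_pure) * e_dir
    e2 = f_pure * e2_pure + (1 - f_pure) * e2_dir
    var_mix = np.maximum(e2 - e1**2, 0.0)
    noise_var = (config.noise_sd * _noise_scales(config)) ** 2
    return var_mix + noise_var


def simulate(config: SimConfig) -> SimData:
    """Generate reference and query component/profile matrices.

    Deterministic given ``config.seed``.  Reference IDs are ``ref_%06d``
    and query IDs ``query_%06d``, so the two sets never collide and
    self-exclusion in the estimator is inert.
    """
    centroids = _place_centroids(config)
    scales = config.noise_sd * _noise_scales(config)
    eigenvalues = _theoretical_eigenvalues(config, centroids)

    ref_profiles = _draw_profiles(
        config, config.n_reference, config.frac_pure, _rng(config, 1)
    )
    query_profiles = _draw_profiles(
        config, config.n_query, config.frac_pure_query, _rng(config, 2)
    )

    ref_scores = ref_profiles @ centroids
    query_scores = query_profiles @ centroids
    if config.noise_sd > 0:
        ref_scores = ref_scores + _rng(config, 3).normal(
            0.0, 1.0, size=ref_scores.shape
        ) * scales
        query_scores = query_scores + _rng(config, 4).normal(
            0.0, 1.0, size=query_scores.shape
        ) * scales

    ref_ids = tuple(f"ref_{i:06d}" for i in range(config.n_reference))
    query_ids = tuple(f"query_{i:06d}" for i in range(config.n_query))
    labels = tuple(f"POP{s + 1}" for s in range(config.n_populations))
    return SimData(
        ComponentMatrix(ref_ids, ref_scores, eigenvalues),
        ProfileMatrix(ref_ids, labels, ref_profiles),
        ComponentMatrix(query_ids, query_scores, eigenvalues),
        ProfileMatrix(query_ids, labels, query_profiles),
    )


def threshold_to_discrete(profiles: ProfileMatrix) -> ProfileMatrix:
    """One-hot each row at its majority population (ties: first label).

    Turns a continuous reference panel into the discrete labeling that
    conventional discrete-reference methods require; used to contrast the
    two reference styles on identical samples.
    """
    props = profiles.proportions
    out = np.zeros_like(props)
    if props.size:
        out[np.arange(props.shape[0]), props.argmax(axis=1)] = 1.0
    return ProfileMatrix(profiles.sample_ids, profiles.population_labels, out)
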