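"""Parameter-selection protocols: (k, p) grid search and cross-validation.

Three reference-panel scenarios are supported:

* DISCRETE — the reference set carries one-hot population assignments
  and the remaining samples are queries;
* CONTINUOUS — same reference/query split, but the reference samples
  carry continuous ancestry profiles;
* CONTINUOUSALL — every sample in the model-building set is a reference,
  and estimates are obtained out-of-fold under F-fold cross-validation
  (default F = 10) so no sample is ever its own reference.

The optimal (k, p) pair is the one minimizing the mean TVD between the
estimated and the known query profiles; the mean Pearson correlation per
ancestry component is recorded alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .estimator import KannParams, estimate_profiles
from .evaluation import EvaluationSummary, evaluate
from .io import ComponentMatrix, ProfileMatrix

__all__ = [
    "Scenario",
    "GridCell",
    "GridResult",
    "FoldAssignment",
    "make_folds",
    "cross_validate",
    "grid_search",
    "component_sweep",
    "DEFAULT_P_GRID",
    "DEFAULT_K_GRID_SMALL",
    "DEFAULT_K_GRID_LARGE",
]

# Default search grids: p over small integers; k over a coarse ladder
# whose top rung is the full reference count (small panels) or extends
# into the tens of thousands (cross-validated full-panel search).
DEFAULT_P_GRID: tuple[float, ...] = tuple(float(p) for p in range(11))
DEFAULT_K_GRID_SMALL: tuple[int, ...] = (1, 10, 25, 50, 100, 250, 500, 1000)
DEFAULT_K_GRID_LARGE: tuple[int, ...] = (
    1, 3, 5, 10, 25, 50, 100, 250, 1000, 5000, 10000, 15000,
)

_SCENARIOS = ("DISCRETE", "CONTINUOUS", "CONTINUOUSALL")


@dataclass(frozen=True)
class Scenario:
    """A reference-panel configuration for parameter optimization.

    ``profile_source`` supplies the reference profiles (one-hot rows for
    DISCRETE).  For CONTINUOUSALL the query set is empty — queries are
    derived from cross-validation folds over the reference set.
    """

    name: str
    reference_ids: tuple[str, ...]
    query_ids: tuple[str, ...]
    profile_source: ProfileMatrix

    def __post_init__(self) -> None:
        if self.name not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        object.__setattr__(self, "reference_ids", tuple(self.reference_ids))
        object.__setattr__(self, "query_ids", tuple(self.query_ids))
        overlap = set(self.reference_ids) & set(self.query_ids)
        if self.name != "CONTINUOUSALL" and overlap:
            raise ValueError(
                f"reference and query IDs overlap: {sorted(overlap)[:10]}"
            )
        if self.name == "CONTINUOUSALL" and self.query_ids:
            raise ValueError(
                "CONTINUOUSALL derives queries from folds; query_ids must "
                "be empty"
            )
        if self.name == "DISCRETE":
            rows = self.profile_source.reindex(
                list(self.reference_ids)
            ).proportions
            if rows.size:
                one_hot = (np.count_nonzero(rows, axis=1) == 1) & (
                    rows.max(axis=1) == 1
                )
                if not one_hot.all():
                    raise ValueError(
                        "DISCRETE scenario requires one-hot reference profiles"
                    )


@dataclass(frozen=True)
class GridCell:
    k: int
    p: float
    mean_tvd: float | None
    mean_correlation: float | None
    skipped: bool = False
    reason: str = ""


@dataclass(frozen=True)
class GridResult:
    """All evaluated (k, p) cells plus the mean-TVD argmin."""

    cells: tuple[GridCell, ...]
    best: tuple[int, float]
    n_components: int

    @property
    def best_cell(self) -> GridCell:
        for c in self.cells:
            if (c.k, c.p) == self.best:
                return c
        raise RuntimeError("best cell missing from grid")


@dataclass(frozen=True)
class FoldAssignment:
    """A random partition of sample IDs into F folds of near-equal size."""

    fold_of: dict
    n_folds: int
    seed: int

    def members(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_of.items() if f == fold]


def make_folds(sample_ids, n_folds: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniform random fold assignment, reproducible from ``seed``.

    Shuffled-index modulo-F rule: fold sizes differ by at most 1.
    """
    ids = list(sample_ids)
    n = len(ids)
    if not (2 <= n_folds <= n):
        raise ValueError(f"n_folds={n_folds} out of range [2, {n}]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = {ids[int(j)]: int(i % n_folds) for i, j in enumerate(perm)}
    return FoldAssignment(fold_of, n_folds, seed)


def cross_validate(
    components: ComponentMatrix,
    profiles: ProfileMatrix,
    folds: FoldAssignment,
    params: KannParams,
) -> EvaluationSummary:
    """Out-of-fold estimates for every sample, evaluated against truth.

    Each fold in turn is the query set and the union of the remaining
    folds is the reference set, so a sample never appears among its own
    references.  The summary covers the combined out-of-fold estimates.
    """
    all_ids = list(profiles.sample_ids)
    if set(folds.fold_of) != set(all_ids):
        raise ValueError("fold assignment does not partition the sample IDs")

    est_ids: list[str] = []
    est_rows: list[np.ndarray] = []
    for f in range(folds.n_folds):
        query_ids = [s for s in all_ids if folds.fold_of[s] == f]
        ref_ids = [s for s in all_ids if folds.fold_of[s] != f]
        if params.k > len(ref_ids):
            raise ValueError(
                f"k={params.k} infeasible for fold {f}: only "
                f"{len(ref_ids)} reference samples outside the fold"
            )
        est = estimate_profiles(
            components.subset(query_ids),
            components.subset(ref_ids),
            profiles.reindex(ref_ids),
            params,
            exclude_self=True,  # no-op: folds are disjoint by construction
        )
        est_ids.extend(est.sample_ids)
        est_rows.append(est.proportions)
    combined = ProfileMatrix(
        tuple(est_ids), profiles.population_labels, np.vstack(est_rows)
    )
    return evaluate(combined, profiles)


def _dedupe_grid(k_grid, p_grid) -> list[tuple[int, float]]:
    pairs = [(int(k), float(p)) for k in k_grid for p in p_grid]
    if not pairs:
        raise ValueError("empty parameter grid")
    seen: set[tuple[int, float]] = set()
    out = []
    for pair in pairs:
        if pair in seen:
            continue
        seen.add(pair)
        out.append(pair)
    if len(out) < len(pairs):
        warnings.warn(
            f"{len(pairs) - len(out)} duplicate (k, p) cell(s) removed "
            "from the grid",
            stacklevel=3,
        )
    return out


def grid_search(
    scenario: Scenario,
    components: ComponentMatrix,
    truth: ProfileMatrix,
    k_grid,
    p_grid,
    params_base: KannParams,
    folds: FoldAssignment | None = None,
) -> GridResult:
    """Evaluate every (k, p) cell and return the mean-TVD argmin.

    DISCRETE / CONTINUOUS estimate the scenario's query samples from its
    reference panel; CONTINUOUSALL cross-validates over ``folds`` (which
    must partition the reference IDs).  Infeasible k values are recorded
    as skipped cells rather than aborting the search.  Argmin ties break
    toward smaller k, then smaller p.
    """
    pairs = _dedupe_grid(k_grid, p_grid)

    if scenario.name == "CONTINUOUSALL":
        if folds is None:
            raise ValueError("CONTINUOUSALL grid search requires folds")
        ref_comp = components.subset(list(scenario.reference_ids))
        ref_prof = scenario.profile_source.reindex(list(scenario.reference_ids))
        min_train = min(
            len(ref_comp.sample_ids) - len(folds.members(f))
            for f in range(folds.n_folds)
        )

        def run(k: int, p: float) -> EvaluationSummary:
            params = KannParams(
                k, p, params_base.epsilon, params_base.n_components
            )
            return cross_validate(ref_comp, ref_prof, folds, params)

        k_max = min_train
    else:
        ref_comp = components.subset(list(scenario.reference_ids))
        query_comp = components.subset(list(scenario.query_ids))
        ref_prof = scenario.profile_source.reindex(list(scenario.reference_ids))
        query_truth = truth.reindex(list(scenario.query_ids))

        def run(k: int, p: float) -> EvaluationSummary:
            params = KannParams(
                k, p, params_base.epsilon, params_base.n_components
            )
            est = estimate_profiles(
                query_comp, ref_comp, ref_prof, params, exclude_self=True
            )
            return evaluate(est, query_truth)

        k_max = ref_comp.n_samples

    cells: list[GridCell] = []
    for k, p in pairs:
        if k > k_max:
            cells.append(
                GridCell(
                    k, p, None, None, skipped=True,
                    reason=f"k={k} exceeds admissible reference count {k_max}",
                )
            )
            continue
        summary = run(k, p)
        cells.append(GridCell(k, p, summary.mean_tvd, summary.mean_correlation))

    usable = [c for c in cells if not c.skipped]
    if not usable:
        raise ValueError("every grid cell was infeasible")
    best = min(usable, key=lambda c: (c.mean_tvd, c.k, c.p))
    return GridResult(tuple(cells), (best.k, best.p), params_base.n_components)


def component_sweep(
    scenario: Scenario,
    components: ComponentMatrix,
    truth: ProfileMatrix,
    m_values,
    k_grid,
    p_grid,
    params_base: KannParams,
    folds: FoldAssignment | None = None,
) -> list[tuple[int, float]]:
    """Optimal mean TVD as a function of the number of top components.

    Re-runs the (k, p) grid search for each M in ``m_values`` and
    returns (M, best mean TVD) pairs; used to locate the point where
    adding components stops improving the estimates.
    """
    out: list[tuple[int, float]] = []
    for m in m_values:
        m = int(m)
        if not (1 <= m <= components.n_components):
            raise ValueError(
                f"m={m} out of range [1, {components.n_components}]"
            )
        base = KannParams(
            params_base.k, params_base.p, params_base.epsilon, m
        )
        result = grid_search(
            scenario, components, truth, k_grid, p_grid, base, folds
        )
        out.append((m, float(result.best_cell.mean_tvd)))
    return out
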