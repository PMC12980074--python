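"""Agreement metrics between two sets of ancestry profiles.

The headline metric is the total variation distance (TVD) between two
S-dimensional profiles,

    TVD(q1, q2) = (1/2) sum_s |q1_s - q2_s|,

i.e. the fraction of ancestry mass the two profiles assign differently;
0 for identical profiles, 1 for disjoint support.  For simplex rows it
equals 1 - sum_s min(q1_s, q2_s).  A profile set is summarized by the
mean TVD over samples (with a normal-approximation 95% CI) and by the
mean Pearson correlation of each ancestry component across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ProfileMatrix

__all__ = ["EvaluationSummary", "tvd", "evaluate"]


@dataclass(frozen=True)
class EvaluationSummary:
    """Per-sample TVDs plus summary statistics.

    ``per_component_correlation`` holds NaN for components whose Pearson
    correlation is undefined (zero variance on either side); those are
    excluded from ``mean_correlation``.
    """

    sample_ids: tuple[str, ...]
    per_sample_tvd: np.ndarray
    mean_tvd: float
    mean_tvd_ci95: tuple[float, float]
    population_labels: tuple[str, ...]
    per_component_correlation: np.ndarray
    mean_correlation: float

    def to_dict(self) -> dict:
        return {
            "n_samples": len(self.sample_ids),
            "mean_tvd": self.mean_tvd,
            "mean_tvd_ci95": list(self.mean_tvd_ci95),
            "mean_correlation": self.mean_correlation,
            "per_component_correlation": {
                lab: (None if np.isnan(c) else float(c))
                for lab, c in zip(
                    self.population_labels, self.per_component_correlation
                )
            },
        }


def tvd(q1, q2) -> float:
    """Total variation distance between two profile rows."""
    a = np.asarray(q1, dtype=float).ravel()
    b = np.asarray(q2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"profile lengths differ: {a.size} vs {b.size}")
    return 0.5 * float(np.abs(a - b).sum())


def evaluate(estimated: ProfileMatrix, truth: ProfileMatrix) -> EvaluationSummary:
    """Compare two profile sets covering the same samples and populations.

    Rows are joined by sample ID and columns by population label, so the
    two inputs may list them in different orders.
    """
    est_ids = set(estimated.sample_ids)
    tru_ids = set(truth.sample_ids)
    if est_ids != tru_ids:
        diff = sorted(est_ids ^ tru_ids)[:10]
        raise ValueError(f"sample ID sets differ; symmetric difference: {diff}")
    if set(estimated.population_labels) != set(truth.population_labels):
        diff = sorted(
            set(estimated.population_labels) ^ set(truth.population_labels)
        )
        raise ValueError(f"population label sets differ: {diff}")

    aligned = truth.reindex(list(estimated.sample_ids)).reorder_populations(
        list(estimated.population_labels)
    )
    e = estimated.proportions
    t = aligned.proportions
    per_sample = 0.5 * np.abs(e - t).sum(axis=1)
    n = per_sample.size
    mean = float(per_sample.mean()) if n else float("nan")
    if n >= 2:
        se = float(per_sample.std(ddof=1)) / np.sqrt(n)
        ci = (mean - 1.96 * se, mean + 1.96 * se)
    else:
        ci = (mean, mean)

    s = e.shape[1]
    corr = np.full(s, np.nan)
    for j in range(s):
        ve, vt = e[:, j], t[:, j]
        if n >= 2 and ve.std() > 0 and vt.std() > 0:
            corr[j] = float(np.corrcoef(ve, vt)[0, 1])
    defined = corr[~np.isnan(corr)]
    if defined.size < s:
        warnings.warn(
            f"{s - defined.size} component(s) have undefined Pearson "
            "correlation (zero variance); excluded from the mean",
            stacklevel=2,
        )
    mean_corr = float(defined.mean()) if defined.size else float("nan")
    return EvaluationSummary(
        sample_ids=estimated.sample_ids,
        per_sample_tvd=per_sample,
        mean_tvd=mean,
        mean_tvd_ci95=ci,
        population_labels=estimated.population_labels,
        per_component_correlation=corr,
        mean_correlation=mean_corr,
    )
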