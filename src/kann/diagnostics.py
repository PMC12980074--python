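"""Population mix-up diagnostics from per-sample marginal differences.

Mean TVD summarizes disagreement between two profile sets but not *which*
populations absorb it.  This module follows the disagreement: for every
target population, take the samples whose marginal difference
(estimated − truth) in that population is large (|diff| >= threshold,
default 0.05), split them by sign, and, within each group, average the
differences of all other populations.  Populations whose group mean runs
in the opposite direction to the target's difference are where the
misassigned ancestry went; their absolute means, normalized to sum to 1,
form the attribution vector.  Same-direction populations contribute 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProfileMatrix

__all__ = ["MixupGroup", "MixupReport", "marginal_differences", "mixup_analysis"]


@dataclass(frozen=True)
class MixupGroup:
    """Samples with a high same-sign difference in one target population."""

    target: str
    sign: str  # "positive" | "negative"
    group_size: int
    attribution: dict  # other population -> fraction (sums to 1), or empty


@dataclass(frozen=True)
class MixupReport:
    groups: tuple[MixupGroup, ...]
    threshold: float

    def group(self, target: str, sign: str) -> MixupGroup:
        for g in self.groups:
            if g.target == target and g.sign == sign:
                return g
        raise KeyError((target, sign))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: target, sign, group_size, other_population,
        attribution."""
        rows = []
        for g in self.groups:
            if g.attribution:
                for pop, frac in g.attribution.items():
                    rows.append((g.target, g.sign, g.group_size, pop, frac))
            else:
                rows.append((g.target, g.sign, g.group_size, None, None))
        return pd.DataFrame(
            rows,
            columns=[
                "target", "sign", "group_size", "other_population",
                "attribution",
            ],
        )


def marginal_differences(
    estimated: ProfileMatrix, truth: ProfileMatrix
) -> pd.DataFrame:
    """Signed per-population differences estimated − truth (n x S).

    Rows are joined by sample ID and columns by population label.  Since
    both inputs live on the simplex, every row sums to 0.
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
    return pd.DataFrame(
        estimated.proportions - aligned.proportions,
        index=pd.Index(estimated.sample_ids, name="sample_id"),
        columns=list(estimated.population_labels),
    )


def mixup_analysis(
    differences: pd.DataFrame, threshold: float = 0.05
) -> MixupReport:
    """Attribute each population's high marginal differences to the others.

    For target population s and sign g, the group holds the samples whose
    difference in s has sign g and magnitude >= ``threshold`` (zeros
    belong to neither group).  Over the group's samples, the arithmetic
    mean difference of every other population is computed; only
    populations whose mean is in the opposite direction to g enter the
    attribution (normalized absolute means); same-sign populations get 0.
    An empty group yields size 0 with empty attribution, as does a group
    where no other population runs opposite.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    diffs = differences.to_numpy(dtype=float)
    labels = [str(c) for c in differences.columns]
    groups: list[MixupGroup] = []
    for j, target in enumerate(labels):
        col = diffs[:, j]
        for sign_name, mask in (
            ("positive", col >= threshold),
            ("negative", col <= -threshold),
        ):
            size = int(mask.sum())
            attribution: dict = {}
            if size:
                means = diffs[mask].mean(axis=0)
                # opposite direction to the group's sign
                opposite = means < 0 if sign_name == "positive" else means > 0
                opposite[j] = False
                weights = np.where(opposite, np.abs(means), 0.0)
                total = weights.sum()
                if total > 0:
                    attribution = {
                        labels[s]: float(weights[s] / total)
                        for s in range(len(labels))
                        if s != j
                    }
                else:
                    warnings.warn(
                        f"target {target!r} ({sign_name}): every other "
                        "population's mean difference has the same sign; "
                        "attribution left empty",
                        stacklevel=2,
                    )
            groups.append(MixupGroup(target, sign_name, size, attribution))
    return MixupReport(tuple(groups), float(threshold))
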