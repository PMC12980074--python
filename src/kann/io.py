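"""Readers and writers for component-score and ancestry-profile tables.

Two container types are shared across the package:

* :class:`ComponentMatrix` — sample scores on M principal (or haplotype)
  components together with the per-component eigenvalues.  This is the
  geometric space in which neighbors are found.
* :class:`ProfileMatrix` — per-sample ancestry proportions over S source
  populations; rows live on the probability simplex.  Both the reference
  input and the estimator output use this type.

Supported on-disk dialects are PLINK ``.eigenvec``/``.eigenval`` pairs
(with or without the ``#FID IID`` header), a generic TSV component table,
and a tab/whitespace-delimited profile table with a header row of
population labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Maximum tolerated deviation of a profile row sum from 1 before the row
#: is rejected as malformed.  Deviations within the tolerance (rounding in
#: upstream tools such as SOURCEFIND or ADMIXTURE output) are renormalized
#: with a warning.
ROW_SUM_TOL = 1e-3


class KannIOError(ValueError):
    """Raised for malformed input tables."""


def _check_unique(ids: tuple[str, ...], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise KannIOError(f"duplicate {what}: {dups[:10]}")


@dataclass(frozen=True)
class ComponentMatrix:
    """Sample scores on M components plus the M eigenvalues.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``scores``.
    scores
        ``(n, M)`` array of component scores (unitless).
    eigenvalues
        ``(M,)`` nonnegative array, in the same order as the score columns
        (variance units of the decomposition).
    standardized
        Whether the score columns have zero mean / unit variance.
    """

    sample_ids: tuple[str, ...]
    scores: np.ndarray
    eigenvalues: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        object.__setattr__(self, "sample_ids", ids)
        _check_unique(ids, "sample IDs")
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2:
            raise ValueError("scores must be a 2-D array")
        eig = np.asarray(self.eigenvalues, dtype=float).ravel()
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "eigenvalues", eig)
        if scores.shape[0] != len(ids):
            raise ValueError(
                f"{len(ids)} sample IDs but {scores.shape[0]} score rows"
            )
        if scores.shape[1] != eig.size:
            raise ValueError(
                f"{scores.shape[1]} score columns but {eig.size} eigenvalues"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite score values")
        if np.any(eig < 0) or not np.all(np.isfinite(eig)):
            raise ValueError("eigenvalues must be finite and nonnegative")

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def index_of(self, ids) -> np.ndarray:
        """Row indices of the given sample IDs (error on unknown IDs)."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:10]}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def subset(self, ids) -> "ComponentMatrix":
        """Row subset (in the given ID order) sharing eigenvalues."""
        rows = self.index_of(ids)
        return ComponentMatrix(
            tuple(self.sample_ids[i] for i in rows),
            self.scores[rows],
            self.eigenvalues,
            self.standardized,
        )


@dataclass(frozen=True)
class ProfileMatrix:
    """Ancestry proportions of n samples over S source populations.

    Every row lies on the probability simplex: entries in [0, 1] summing
    to 1 (within ``ROW_SUM_TOL``).  A *discrete* profile is the special
    case where every row is one-hot.
    """

    sample_ids: tuple[str, ...]
    population_labels: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        labels = tuple(str(s) for s in self.population_labels)
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "population_labels", labels)
        _check_unique(ids, "sample IDs")
        _check_unique(labels, "population labels")
        props = np.asarray(self.proportions, dtype=float)
        if props.ndim != 2:
            props = props.reshape(len(ids), len(labels))
        object.__setattr__(self, "proportions", props)
        if props.shape != (len(ids), len(labels)):
            raise ValueError(
                f"proportions shape {props.shape} does not match "
                f"{len(ids)} samples x {len(labels)} populations"
            )
        if not np.all(np.isfinite(props)):
            raise ValueError("non-finite proportions")
        if np.any(props < -1e-12) or np.any(props > 1 + 1e-9):
            raise ValueError("proportions must lie in [0, 1]")
        if props.shape[0]:
            sums = props.sum(axis=1)
            bad = np.abs(sums - 1.0) > ROW_SUM_TOL
            if np.any(bad):
                culprit = ids[int(np.argmax(bad))]
                raise ValueError(
                    f"profile row for sample {culprit!r} sums to "
                    f"{sums[np.argmax(bad)]:.6g}, outside 1 +/- {ROW_SUM_TOL}"
                )

    @property
    def n_samples(self) -> int:
        return self.proportions.shape[0]

    @property
    def n_populations(self) -> int:
        return self.proportions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=list(self.population_labels),
        )

    def reindex(self, ids) -> "ProfileMatrix":
        """Row subset/reordering by sample ID."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:10]}")
        rows = np.array([lookup[s] for s in ids], dtype=int)
        return ProfileMatrix(
            tuple(ids), self.population_labels, self.proportions[rows]
        )

    def reorder_populations(self, labels) -> "ProfileMatrix":
        """Column reordering by population label."""
        lookup = {s: i for i, s in enumerate(self.population_labels)}
        missing = [s for s in labels if s not in lookup]
        if missing:
            raise KeyError(f"unknown population labels: {missing}")
        cols = np.array([lookup[s] for s in labels], dtype=int)
        return ProfileMatrix(
            self.sample_ids, tuple(labels), self.proportions[:, cols]
        )


def _read_eigenvalues(path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                v = float(line)
            except ValueError as exc:
                raise KannIOError(
                    f"{path}: line {lineno}: non-numeric eigenvalue {line!r}"
                ) from exc
            if v < 0:
                raise KannIOError(
                    f"{path}: line {lineno}: negative eigenvalue {v}"
                )
            values.append(v)
    return np.asarray(values, dtype=float)


def read_component_matrix(
    scores_path, eigenval_path, dialect: str = "plink-eigenvec"
) -> ComponentMatrix:
    """Read a component-score table and its eigenvalue file.

    ``dialect='plink-eigenvec'`` accepts PLINK output, whitespace- or
    tab-delimited, with an optional header line starting with ``#``.  If a
    family-ID column is present (``#FID IID ...`` header, or no header at
    all, in which case the classic two-ID layout is assumed) the sample ID
    is ``FID_IID``; a header without FID means the first column is the
    sample ID.  ``dialect='generic-tsv'`` expects a header row whose first
    column is the sample ID.
    """
    if dialect not in ("plink-eigenvec", "generic-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    eigenvalues = _read_eigenvalues(eigenval_path)

    with open(scores_path) as fh:
        first = fh.readline()
    if not first:
        raise KannIOError(f"{scores_path}: empty file")

    if dialect == "generic-tsv":
        table = pd.read_csv(scores_path, sep=r"\s+", header=0, dtype=str)
        id_cols = 1
    else:
        has_header = first.lstrip().startswith("#")
        if has_header:
            header = first.lstrip("#").split()
            table = pd.read_csv(
                scores_path, sep=r"\s+", header=None, skiprows=1, dtype=str
            )
            table.columns = header[: table.shape[1]]
            id_cols = 2 if header[0].upper() == "FID" else 1
        else:
            table = pd.read_csv(scores_path, sep=r"\s+", header=None, dtype=str)
            id_cols = 2  # classic PLINK layout: FID IID PC1 ...

    if table.shape[1] <= id_cols:
        raise KannIOError(f"{scores_path}: no score columns found")
    if id_cols == 2:
        ids = tuple(
            f"{a}_{b}"
            for a, b in zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str))
        )
    else:
        ids = tuple(table.iloc[:, 0].astype(str))

    raw = table.iloc[:, id_cols:]
    n_score_cols = raw.shape[1]
    if n_score_cols != eigenvalues.size:
        raise KannIOError(
            f"{scores_path} has {n_score_cols} score columns but "
            f"{eigenval_path} has {eigenvalues.size} eigenvalues"
        )
    scores = np.empty((raw.shape[0], n_score_cols), dtype=float)
    for j in range(n_score_cols):
        col = pd.to_numeric(raw.iloc[:, j], errors="coerce")
        if col.isna().any():
            i = int(col.isna().to_numpy().argmax())
            raise KannIOError(
                f"{scores_path}: non-numeric score at row {i + 1}, "
                f"score column {j + 1}: {raw.iloc[i, j]!r}"
            )
        scores[:, j] = col.to_numpy()
    return ComponentMatrix(ids, scores, eigenvalues)


def read_profile_matrix(path) -> ProfileMatrix:
    """Read an ancestry-profile table (header: sample_id + S labels).

    Rows whose sum deviates from 1 by at most ``ROW_SUM_TOL`` are
    renormalized with a warning; larger deviations and negative entries
    are hard errors.
    """
    table = pd.read_csv(path, sep=r"\s+", header=0)
    if table.shape[1] < 3:
        raise KannIOError(
            f"{path}: need one ID column and at least 2 population columns"
        )
    ids = tuple(table.iloc[:, 0].astype(str))
    labels = tuple(str(c) for c in table.columns[1:])
    raw = table.iloc[:, 1:]
    props = np.empty(raw.shape, dtype=float)
    for j in range(raw.shape[1]):
        col = pd.to_numeric(raw.iloc[:, j], errors="coerce")
        if col.isna().any():
            i = int(col.isna().to_numpy().argmax())
            raise KannIOError(
                f"{path}: non-numeric proportion at row {i + 1}, "
                f"column {labels[j]!r}"
            )
        props[:, j] = col.to_numpy()
    if np.any(props < 0):
        i, j = np.unravel_index(int(np.argmin(props)), props.shape)
        raise KannIOError(
            f"{path}: negative proportion for sample {ids[i]!r}, "
            f"population {labels[j]!r}"
        )
    sums = props.sum(axis=1)
    bad = np.abs(sums - 1.0) > ROW_SUM_TOL
    if np.any(bad):
        i = int(np.argmax(bad))
        raise KannIOError(
            f"{path}: profile of sample {ids[i]!r} sums to {sums[i]:.6g}, "
            f"outside 1 +/- {ROW_SUM_TOL}"
        )
    off = np.abs(sums - 1.0) > 1e-12
    if np.any(off):
        warnings.warn(
            f"{np.count_nonzero(off)} profile row(s) renormalized "
            f"(row sums within {ROW_SUM_TOL} of 1)",
            stacklevel=2,
        )
        props = props / sums[:, None]
    return ProfileMatrix(ids, labels, props)


def write_profile_matrix(profiles: ProfileMatrix, path) -> None:
    """Write a profile table (tab-delimited, fixed 6-decimal formatting).

    Round-trips through :func:`read_profile_matrix` to within 1e-6 per
    entry.
    """
    for label in profiles.population_labels:
        if "\t" in label or any(c.isspace() for c in label):
            raise ValueError(
                f"population label {label!r} contains whitespace; "
                "cannot be written to a delimited table"
            )
    for sid in profiles.sample_ids:
        if any(c.isspace() for c in sid):
            raise ValueError(f"sample ID {sid!r} contains whitespace")
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(profiles.population_labels) + "\n")
        for sid, row in zip(profiles.sample_ids, profiles.proportions):
            cells = _round_simplex_row(row)
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def _round_simplex_row(row: np.ndarray, decimals: int = 6) -> list[str]:
    # Largest-remainder rounding: each cell is within one decimal unit of
    # the true value and the printed row sums to exactly 1, so the reader
    # never renormalizes round-trip output.
    unit = 10**decimals
    scaled = np.asarray(row, dtype=float) * unit
    floors = np.floor(scaled + 1e-9).astype(np.int64)
    deficit = int(unit - floors.sum())
    if deficit > 0:
        order = np.argsort(-(scaled - floors), kind="stable")
        floors[order[:deficit]] += 1
    elif deficit < 0:  # only via accumulated fp error; trim largest cells
        order = np.argsort(-floors, kind="stable")
        floors[order[:-deficit]] -= 1
    return [f"{v / unit:.{decimals}f}" for v in floors]


def write_component_matrix(
    components: ComponentMatrix, scores_path, eigenval_path
) -> None:
    """Write a component matrix in the generic-tsv dialect (6 decimals)."""
    m = components.n_components
    with open(scores_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(f"c{j + 1}" for j in range(m)) + "\n")
        for sid, row in zip(components.sample_ids, components.scores):
            fh.write(sid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    with open(eigenval_path, "w") as fh:
        for v in components.eigenvalues:
            fh.write(f"{v:.6f}\n")
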