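"""Radiomics feature tables: loading, validation, cohort splitting, batch check.

The on-disk exchange format is a comma-separated text file with a header row;
the first column holds sample identifiers, the remaining columns are feature
values plus the reserved columns ``grade`` (0 = low, 1 = high WHO/ISUP grade),
``time_months`` (progression-free survival in months) and ``event``
(1 = progression observed, 0 = censored).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split

from .schema import FeatureSchema

__all__ = [
    "FeatureTable",
    "CohortSplit",
    "ValidationError",
    "load_feature_table",
    "save_feature_table",
    "stratified_split",
    "batch_check",
]

#: non-feature columns understood by the table
RESERVED_COLUMNS = ("grade", "time_months", "event")

GRADE_ALIASES = {"low": 0, "high": 1, "0": 0, "1": 1, 0: 0, 1: 1, 0.0: 0, 1.0: 1}


class ValidationError(ValueError):
    """A feature table violates the format contract (missing cells, bad labels...)."""


@dataclass
class FeatureTable:
    """Samples x features with optional grade label and survival columns.

    ``data`` holds one row per sample (index = sample id) and one column per
    feature plus any of the reserved columns.  Feature values are real-valued
    with no missing entries.
    """

    data: pd.DataFrame
    schema: FeatureSchema | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in RESERVED_COLUMNS]

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def grade(self) -> pd.Series:
        if "grade" not in self.data.columns:
            raise ValidationError("table has no 'grade' column")
        return self.data["grade"]

    @property
    def has_survival(self) -> bool:
        return {"time_months", "event"} <= set(self.data.columns)

    def phases(self) -> list[str]:
        """Distinct phase prefixes among the feature columns.

        Columns are expected to follow the ``<phase>X<index>`` convention;
        columns that do not are ignored here (the table is then single-block
        and addressed via phase ``'ALL'``).
        """
        seen: list[str] = []
        for c in self.feature_columns:
            m = re.match(r"^([A-Z])X\d+$", c)
            if m and m.group(1) not in seen:
                seen.append(m.group(1))
        return seen

    def phase_columns(self, phase: str) -> list[str]:
        """Feature columns of one phase; ``'ALL'`` returns every feature column."""
        if phase == "ALL":
            return self.feature_columns
        if self.schema is not None:
            return [c for c in self.feature_columns if self.schema.parse_column(c)[0] == phase]
        return [c for c in self.feature_columns if c.startswith(phase)]

    def subset(self, rows=None, columns: list[str] | None = None) -> "FeatureTable":
        """New table restricted to the given sample positions / feature columns."""
        df = self.data
        if rows is not None:
            df = df.iloc[np.asarray(rows)]
        if columns is not None:
            keep = list(columns) + [c for c in RESERVED_COLUMNS if c in df.columns]
            df = df[keep]
        return FeatureTable(df.copy(), schema=self.schema)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        df.index.name = "sample_id"
        if df.columns.duplicated().any():
            dupes = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate column names: {dupes}")
        feat = self.feature_columns
        if not feat:
            raise ValidationError("table has no feature columns")
        missing = df[feat].isna()
        if missing.to_numpy().any():
            cells = [
                f"(row {df.index[i]!r}, column {feat[j]!r})"
                for i, j in zip(*np.nonzero(missing.to_numpy()))
            ]
            shown = ", ".join(cells[:10])
            more = "" if len(cells) <= 10 else f" and {len(cells) - 10} more"
            raise ValidationError(f"missing values at {shown}{more}")
        bad = [c for c in feat if not np.issubdtype(df[c].dtype, np.number)]
        if bad:
            raise ValidationError(f"non-numeric feature columns: {bad}")
        if "grade" in df.columns:
            try:
                mapped = df["grade"].map(GRADE_ALIASES)
            except TypeError as exc:  # unhashable values
                raise ValidationError("grade labels must be binary") from exc
            if mapped.isna().any():
                raise ValidationError(
                    "grade labels must be binary (0/low vs 1/high); got "
                    f"{sorted(set(df['grade'].dropna()) - set(GRADE_ALIASES))}"
                )
            self.data["grade"] = mapped.astype(int)
        if "time_months" in df.columns:
            t = df["time_months"]
            if t.isna().any() or (t <= 0).any():
                raise ValidationError("survival time_months must be positive")
        if "event" in df.columns:
            ev = df["event"]
            if not set(ev.dropna().unique()) <= {0, 1}:
                raise ValidationError("event indicator must be 0/1")
        if self.schema is not None:
            for c in feat:
                self.schema.parse_column(c)  # raises SchemaError

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="sample_id")


def load_feature_table(path, schema: FeatureSchema | None = None) -> FeatureTable:
    """Read a CSV feature table (first column = sample id) and validate it.

    With a ``schema``, every feature column name must parse as
    ``<phase>X<index>`` with the index within the registry.
    """
    df = pd.read_csv(path, index_col=0)
    return FeatureTable(df, schema=schema)


def save_feature_table(table: FeatureTable, path) -> None:
    table.to_csv(path)


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint training/test positional index sets, stratified by a label."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    stratify_label: str
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValidationError("train/test index sets overlap")


def stratified_split(table: FeatureTable, test_fraction: float, seed: int) -> CohortSplit:
    """Split samples into train/test preserving the grade proportions.

    Per-label proportions in each part stay within one sample of the global
    proportion; the split is deterministic given ``seed``.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    y = table.grade.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("both grade classes must be present to stratify")
    if counts.min() < 2:
        raise ValidationError("each grade class needs at least 2 samples")
    idx = np.arange(table.n_samples)
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return CohortSplit(
        train_idx=np.sort(train),
        test_idx=np.sort(test),
        stratify_label="grade",
        seed=seed,
    )


def batch_check(table: FeatureTable, batch_labels) -> dict:
    """PCA-based batch-effect check across acquisition batches (e.g. scanners).

    Features are z-scored, projected on the first two principal components,
    and the per-batch PC-score distributions are compared with the
    Kruskal-Wallis test.  Small p-values indicate batch structure.

    Returns ``{'pc1_p', 'pc2_p', 'scores'}`` where ``scores`` is the
    n x 2 PC-score matrix.
    """
    batches = np.asarray(batch_labels)
    if batches.shape[0] != table.n_samples:
        raise ValueError("batch_labels length must equal the number of samples")
    uniq, counts = np.unique(batches, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 batches")
    if counts.min() < 3:
        raise ValueError("each batch needs at least 3 samples")
    X = table.X.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("feature matrix is constant; no principal directions")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    scores = PCA(n_components=2).fit_transform(Z)
    pvals = []
    for j in range(2):
        groups = [scores[batches == b, j] for b in uniq]
        pvals.append(stats.kruskal(*groups).pvalue)
    return {"pc1_p": float(pvals[0]), "pc2_p": float(pvals[1]), "scores": scores}
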