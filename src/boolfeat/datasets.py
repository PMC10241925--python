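"""Loading, validation, preprocessing, and splitting of subject-level tables.

Input tables are plain CSV (header row required) with one row per subject, one
numeric column per summarized feature, and a binary outcome column.  The
preprocessing mirrors the usual cleanup applied to summarized EHR feature
tables: near-constant and mostly-zero columns are dropped, and remaining
missing values are median-imputed.  Every transform is recorded in a
JSON-serializable preprocessing log.

Note on pipeline order: column filters and imputation medians are computed on
the full input table, before the internal train/validation split.  This keeps
the pipeline deterministic and matches the typical phenotyping workflow, at
the cost of a small information leak from validation rows into the imputation
constants; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .exceptions import ConfigError, DegenerateDataError, ParseError

_NA_STRINGS = {"", "na", "nan", "null", "none"}


@dataclass
class Dataset:
    """An N x d feature matrix with binary labels and column/row names."""

    X: np.ndarray
    y: np.ndarray | None
    feature_names: list[str]
    subject_ids: list[str]
    preprocessing_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError("feature matrix must be 2-D with N >= 1 and d >= 1")
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length must equal number of columns")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if len(self.subject_ids) != self.X.shape[0]:
            raise ValueError("subject_ids length must equal number of rows")
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape != (self.X.shape[0],):
                raise ValueError("labels must be a length-N vector")
            uniq = set(np.unique(self.y).tolist())
            if not uniq <= {0, 1}:
                raise ValueError(f"labels must be binary 0/1, got values {sorted(uniq)}")
            self.y = self.y.astype(int)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            feature_names=list(self.feature_names),
            subject_ids=[self.subject_ids[i] for i in idx],
            preprocessing_log=list(self.preprocessing_log),
        )

    def to_frame(self, label_column: str | None = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "subject_id", self.subject_ids)
        if self.y is not None and label_column is not None:
            df[label_column] = self.y
        return df


def load_table(
    path,
    label_column: str | None,
    id_column: str | None = "subject_id",
) -> Dataset:
    """Read a CSV into a raw (unpreprocessed) :class:`Dataset`.

    Missing feature values may be encoded as empty strings or NA; any other
    non-numeric cell raises a :class:`ParseError` naming the row and column.
    """
    df = pd.read_csv(path, dtype=object, keep_default_na=False)
    if label_column is not None and label_column not in df.columns:
        raise ConfigError(f"label column {label_column!r} not found in {path}")

    if id_column is not None and id_column in df.columns:
        subject_ids = [str(v) for v in df[id_column]]
        df = df.drop(columns=[id_column])
    else:
        subject_ids = [str(i) for i in range(len(df))]

    y = None
    if label_column is not None:
        raw = df[label_column]
        try:
            y = pd.to_numeric(raw).to_numpy()
        except (ValueError, TypeError) as exc:
            raise ParseError(f"label column {label_column!r} is not numeric") from exc
        if not set(np.unique(y)) <= {0, 1}:
            raise ParseError(
                f"label column {label_column!r} must contain only 0 and 1"
            )
        df = df.drop(columns=[label_column])

    feature_names = [str(c) for c in df.columns]
    X = np.empty((len(df), len(feature_names)), dtype=float)
    for j, col in enumerate(df.columns):
        # parse with Python's correctly-rounded float() so written tables
        # round-trip bit-exactly
        for i, v in enumerate(df[col].to_numpy()):
            s = str(v).strip()
            if s.lower() in _NA_STRINGS:
                X[i, j] = np.nan
                continue
            try:
                X[i, j] = float(s)
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric value {v!r} in column {col!r}, row {i}"
                ) from exc

    return Dataset(X=X, y=y, feature_names=feature_names, subject_ids=subject_ids)


def write_table(ds: Dataset, path, label_column: str = "label") -> None:
    df = ds.to_frame(label_column if ds.y is not None else None)
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round-trip


def preprocess(
    ds: Dataset,
    min_nonzero_frac: float = 0.05,
    min_variance: float = 0.05,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> Dataset:
    """Drop near-empty / near-constant columns, then median-impute.

    Columns with fewer than ``min_nonzero_frac`` non-zero (observed) entries or
    with variance below ``min_variance`` (over observed values) are excluded;
    both filters are evaluated on the raw columns before imputation.
    ``ranges`` optionally maps column names to physiologically plausible
    ``(low, high)`` bounds; values outside their range are treated as missing.
    """
    if not (0 <= min_nonzero_frac < 1):
        raise ConfigError("min_nonzero_frac must be in [0, 1)")
    if min_variance < 0:
        raise ConfigError("min_variance must be >= 0")

    X = ds.X
    range_log: list[dict] = []
    if ranges:
        X = X.copy()
        for name, (low, high) in ranges.items():
            if name not in ds.feature_names:
                continue
            j = ds.feature_names.index(name)
            bad = (X[:, j] < low) | (X[:, j] > high)
            if bad.any():
                X[bad, j] = np.nan
                range_log.append(
                    {"transform": "range_filter", "column": name,
                     "low": low, "high": high, "count": int(bad.sum())}
                )
    n = ds.n
    observed = ~np.isnan(X)
    nonzero_frac = np.sum(observed & (X != 0), axis=0) / n
    with np.errstate(invalid="ignore"):
        variance = np.array(
            [np.nanvar(X[:, j]) if observed[:, j].any() else 0.0 for j in range(ds.d)]
        )
    keep = (nonzero_frac >= min_nonzero_frac) & (variance >= min_variance)
    if not keep.any():
        raise DegenerateDataError("preprocessing dropped every column")

    log = list(ds.preprocessing_log) + range_log
    for j in np.nonzero(~keep)[0]:
        reasons = []
        if nonzero_frac[j] < min_nonzero_frac:
            reasons.append(f"nonzero fraction {nonzero_frac[j]:.4g} < {min_nonzero_frac}")
        if variance[j] < min_variance:
            reasons.append(f"variance {variance[j]:.4g} < {min_variance}")
        log.append(
            {"transform": "drop_column", "column": ds.feature_names[j], "reason": "; ".join(reasons)}
        )

    Xk = X[:, keep].copy()
    names = [ds.feature_names[j] for j in np.nonzero(keep)[0]]
    n_imputed = 0
    for j in range(Xk.shape[1]):
        miss = np.isnan(Xk[:, j])
        if miss.any():
            med = float(np.nanmedian(Xk[:, j]))
            Xk[miss, j] = med
            n_imputed += int(miss.sum())
            log.append(
                {
                    "transform": "median_impute",
                    "column": names[j],
                    "count": int(miss.sum()),
                    "median": med,
                }
            )
    log.append(
        {
            "transform": "preprocess_summary",
            "columns_in": ds.d,
            "columns_kept": int(keep.sum()),
            "values_imputed": n_imputed,
        }
    )
    return Dataset(
        X=Xk, y=ds.y, feature_names=names, subject_ids=list(ds.subject_ids),
        preprocessing_log=log,
    )


def split_train_validation(
    ds: Dataset,
    validation_frac: float = 0.20,
    seed: int = 0,
) -> tuple[Dataset, Dataset]:
    """Deterministic stratified split into internal training and validation sets."""
    if ds.n < 5:
        raise DegenerateDataError("need at least 5 subjects to split")
    if ds.y is None:
        raise DegenerateDataError("cannot stratify an unlabeled dataset")
    counts = np.bincount(ds.y, minlength=2)
    if counts.min() < 2:
        raise DegenerateDataError(
            f"class counts {counts.tolist()} too small for a stratified split; "
            "each class needs at least 2 subjects"
        )
    idx = np.arange(ds.n)
    train_idx, val_idx = train_test_split(
        idx, test_size=validation_frac, stratify=ds.y, random_state=int(seed) % (2**31)
    )
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(val_idx))
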