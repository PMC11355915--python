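"""Normalized bilateral-asymmetry estimates, top-decile flags and overlap counts.

For each bilateral trait the signed residual is left minus right; its
absolute value measures the extent of asymmetry; division by the per-trait
maximum over subjects puts every trait on a common unitless [0, 1] scale.
Normalized values are averaged within body-part groups (retina — the two
topological asymmetry magnitudes —, ophthalmic, ankle-brachial pressure,
audiometry), subjects in the top decile of a group are flagged, and the
overlap of flags across groups is summarized as a 4-set Venn partition.
Under fluctuating asymmetry the signed residuals average to zero across a
population; with independent group asymmetries the expected fraction of
subjects flagged in two or more groups is 1 - 0.9^4 - 4*0.1*0.9^3 ~ 5.2%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GROUPS",
    "OverlapSummary",
    "signed_residual",
    "normalize_trait",
    "asymmetry_table",
    "group_asymmetry",
    "top_decile_flags",
    "align_flags",
    "overlap",
    "TraitMaxNormalizer",
    "TopDecileFlagger",
]

#: the four body-part groups whose flags are overlapped
GROUPS = ("retina", "ophthalmic", "abpi", "audiometry")


def signed_residual(left, right):
    """Signed left-right difference; NaN if either side is missing."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    return left - right


def normalize_trait(absolute_residuals) -> np.ndarray:
    """Divide a trait's absolute residuals by their maximum (NaNs ignored).

    Maps onto [0, 1] with the most asymmetric subject at exactly 1.  An
    all-zero trait returns zeros with a warning (max-0 guard).
    """
    arr = np.asarray(absolute_residuals, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("absolute residuals must be non-negative")
    if not np.any(~np.isnan(arr)):
        raise ValueError("no non-missing residuals to normalize")
    peak = np.nanmax(arr)
    if peak == 0:
        warnings.warn("all residuals are zero; normalized values set to 0", stacklevel=2)
        return arr.copy()
    return arr / peak


def asymmetry_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Signed, absolute and max-normalized residuals per (subject, trait).

    Expects columns subject_id, trait, group, left, right; appends columns
    signed, absolute, normalized.  Rows with a missing side get missing
    residuals and are excluded from the per-trait maximum.
    """
    required = {"subject_id", "trait", "group", "left", "right"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements table lacks columns: {sorted(missing)}")
    out = measurements.copy()
    out["signed"] = signed_residual(out["left"], out["right"])
    out["absolute"] = out["signed"].abs()
    out["normalized"] = np.nan
    for trait, idx in out.groupby("trait", sort=False).groups.items():
        vals = out.loc[idx, "absolute"]
        if vals.notna().any():
            out.loc[idx, "normalized"] = normalize_trait(vals.to_numpy())
    return out


def group_asymmetry(asymmetry: pd.DataFrame, group: str | None = None) -> pd.DataFrame:
    """Per-subject mean of normalized asymmetries within each body-part group.

    The retina group should be supplied as two traits (the dimension-0 and
    dimension-1 topological asymmetry magnitudes) in the same long format.
    Subjects with no non-missing trait in a group are missing for that group.
    Returns a subject x group table of means in [0, 1].
    """
    df = asymmetry
    if group is not None:
        df = df[df["group"] == group]
        if df.empty:
            raise ValueError(f"no measurements in group {group!r}")
    wide = df.pivot_table(
        index="subject_id", columns="group", values="normalized", aggfunc="mean"
    )
    wide.columns.name = None
    return wide


def top_decile_flags(values, fraction: float = 0.10) -> pd.Series | np.ndarray:
    """Flag the most-asymmetric ``fraction`` of subjects.

    The threshold is the empirical (1 - fraction) quantile (linear
    interpolation); values at or above it are flagged, so threshold ties are
    all flagged.  Missing values get a missing flag.  Requires >= 10
    non-missing values; an all-equal input flags everyone with a warning.
    """
    ser = pd.Series(values, dtype=float)
    ok = ser.dropna()
    if ok.size < 10:
        raise ValueError(f"need >= 10 non-missing values to flag a top decile, got {ok.size}")
    threshold = float(np.quantile(ok.to_numpy(), 1.0 - fraction))
    if ok.nunique() == 1:
        warnings.warn("all group means equal; every subject is flagged", stacklevel=2)
    flags = pd.Series(np.where(ser.isna(), np.nan, (ser >= threshold).astype(float)),
                      index=ser.index)
    if isinstance(values, (pd.Series,)):
        return flags
    return flags.to_numpy()


def align_flags(flag_vectors: dict[str, pd.Series]) -> pd.DataFrame:
    """Join per-group flag vectors on subject_id, rejecting mismatched sets.

    Every vector must cover the same subjects; offenders (subjects present in
    some groups but not all) are listed in the error.  Missing values *within*
    a shared index (e.g. excluded audiometry subjects) are allowed and flow
    through to :func:`overlap`'s complete-case handling.
    """
    indexes = {name: set(ser.index) for name, ser in flag_vectors.items()}
    union = set().union(*indexes.values())
    offenders = sorted(
        {subj for idx in indexes.values() for subj in union - idx}, key=str
    )
    if offenders:
        raise ValueError(
            f"flag vectors cover different subject sets; offenders: {offenders[:10]}"
            + (" ..." if len(offenders) > 10 else "")
        )
    return pd.DataFrame(flag_vectors)


@dataclass(frozen=True)
class OverlapSummary:
    """4-set Venn partition of top-decile flags plus the multi-asymmetry call."""

    flags: pd.DataFrame                  # subject x group binary flags (complete cases)
    n_flags: pd.Series                   # flags per subject
    count_by_n: dict[int, int]           # subjects with exactly 0..4 flags
    venn: dict[tuple[int, int, int, int], int]  # pattern over GROUPS -> count
    multi_asymmetry: pd.Series           # >= 2 flags, per subject

    @property
    def n_multi(self) -> int:
        return int(self.multi_asymmetry.sum())

    @property
    def fraction_multi(self) -> float:
        return float(self.multi_asymmetry.mean())


def overlap(flags: pd.DataFrame, groups: tuple[str, ...] = GROUPS) -> OverlapSummary:
    """Exact Venn partition of per-subject flags over the body-part groups.

    ``flags`` is a subject-indexed table with one binary column per group.
    Subjects with a missing flag in any group are dropped (complete-case
    overlap); the partition counts sum to the number retained.
    """
    missing_cols = [g for g in groups if g not in flags.columns]
    if missing_cols:
        raise ValueError(f"flag table lacks group columns: {missing_cols}")
    sub = flags[list(groups)].dropna().astype(int)
    bad = sub[(sub.lt(0) | sub.gt(1)).any(axis=1)]
    if not bad.empty:
        raise ValueError(f"non-binary flags for subjects: {list(bad.index[:5])}")
    n_flags = sub.sum(axis=1)
    count_by_n = {k: int((n_flags == k).sum()) for k in range(len(groups) + 1)}
    venn = {}
    for pattern in product((0, 1), repeat=len(groups)):
        mask = np.ones(len(sub), dtype=bool)
        for col, bit in zip(groups, pattern):
            mask &= sub[col].to_numpy() == bit
        venn[pattern] = int(mask.sum())
    return OverlapSummary(
        flags=sub,
        n_flags=n_flags,
        count_by_n=count_by_n,
        venn=venn,
        multi_asymmetry=n_flags >= 2,
    )


class TraitMaxNormalizer(TransformerMixin, BaseEstimator):
    """Per-column max-normalization of absolute residuals onto [0, 1].

    ``fit`` learns each column's maximum absolute value over subjects
    (NaN-aware); ``transform`` returns |x| / max.  Columns with maximum 0
    pass through as zeros with a warning.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of residuals")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            self.max_abs_ = np.nanmax(np.abs(X), axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "max_abs_")
        X = np.abs(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        zero = self.max_abs_ == 0
        if np.any(zero):
            warnings.warn("columns with zero maximum left as zeros", stacklevel=2)
        denom = np.where(zero, 1.0, self.max_abs_)
        return X / denom


class TopDecileFlagger(TransformerMixin, BaseEstimator):
    """Binary flags for values at or above a per-column empirical quantile.

    Parameters
    ----------
    fraction : float, default=0.10
        Tail mass to flag; the threshold is the (1 - fraction) quantile
        learned per column during ``fit``.
    """

    def __init__(self, fraction: float = 0.10):
        self.fraction = fraction

    def fit(self, X, y=None):
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array of group means")
        n_ok = np.sum(~np.isnan(X), axis=0)
        if np.any(n_ok < 10):
            raise ValueError("need >= 10 non-missing values per column")
        self.threshold_ = np.nanquantile(X, 1.0 - self.fraction, axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        X = np.asarray(X, dtype=float)
        out = (X >= self.threshold_).astype(float)
        out[np.isnan(X)] = np.nan
        return out
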