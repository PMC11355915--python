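"""Accumulative persistence functions and the signed-supremum asymmetry measure.

A persistence diagram is re-expressed as mean-age/lifetime points
(``m = (b + d)/2``, ``l = d - b``); the accumulative persistence function
(APF) is the step function ``APF(m) = sum of l_i over points with m_i <= m``.
The asymmetry between a right and a left image in homology dimension ``k``
is the value of ``APFk_R - APFk_L`` at the mean age where the absolute
difference is largest — a signed supremum distance between the two curves.
Identical images give exactly 0; the sign records which side dominates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .persistence import (
    GreyscaleImage,
    PersistenceDiagram,
    compute_persistence,
    unit_transform,
    z_transform,
)

__all__ = [
    "RRPD",
    "APFCurve",
    "ReVAResult",
    "rrpd",
    "apf_curve",
    "reva",
    "compute_reva_pair",
    "ReVAExtractor",
]


@dataclass(frozen=True)
class RRPD:
    """Rotated/rescaled persistence diagram: (mean age, lifetime) per point."""

    mean_ages: np.ndarray
    lifetimes: np.ndarray
    dim: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_ages, dtype=float)
        l = np.asarray(self.lifetimes, dtype=float)
        if m.shape != l.shape or m.ndim != 1:
            raise ValueError("mean_ages and lifetimes must be equal-length 1-D arrays")
        if np.any(l < 0):
            raise ValueError("negative lifetime in RRPD")
        object.__setattr__(self, "mean_ages", m)
        object.__setattr__(self, "lifetimes", l)

    def __len__(self) -> int:
        return self.mean_ages.size


@dataclass(frozen=True)
class APFCurve:
    """Right-continuous non-decreasing step function of mean age.

    ``breakpoints`` are the distinct mean ages; ``cumulative`` the lifetime
    sums at/after each breakpoint.  The curve is 0 before the first
    breakpoint and equals the total lifetime sum after the last.
    """

    breakpoints: np.ndarray
    cumulative: np.ndarray
    dim: int
    side: str = ""
    transform: str = ""

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        cum = np.asarray(self.cumulative, dtype=float)
        if bp.shape != cum.shape or bp.ndim != 1:
            raise ValueError("breakpoints and cumulative must be equal-length 1-D arrays")
        if bp.size > 1 and (np.any(np.diff(bp) <= 0) or np.any(np.diff(cum) < 0)):
            raise ValueError("breakpoints must be strictly increasing and cumulative non-decreasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "cumulative", cum)

    def __call__(self, m) -> np.ndarray | float:
        """Evaluate the step function at mean age(s) ``m``."""
        m_arr = np.asarray(m, dtype=float)
        idx = np.searchsorted(self.breakpoints, m_arr, side="right")
        padded = np.concatenate([[0.0], self.cumulative])
        out = padded[idx]
        return float(out) if np.isscalar(m) or m_arr.ndim == 0 else out

    @property
    def total(self) -> float:
        """Sum of all lifetimes (the curve's terminal value)."""
        return float(self.cumulative[-1]) if self.cumulative.size else 0.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"m": self.breakpoints, "value": self.cumulative})


@dataclass(frozen=True)
class ReVAResult:
    """Signed-supremum APF differences for dimensions 0 and 1 of one image pair."""

    reva0: float
    reva1: float
    m0_max: float
    m1_max: float
    transform: str
    normalized: bool = False


def rrpd(pd: PersistenceDiagram) -> RRPD:
    """Mean-age/lifetime representation of a diagram (m = (b+d)/2, l = d-b)."""
    if not np.all(np.isfinite(pd.deaths)):
        raise ValueError("infinite death in diagram; apply the essential-death policy first")
    return RRPD((pd.births + pd.deaths) / 2.0, pd.deaths - pd.births, dim=pd.dim)


def apf_curve(r: RRPD, side: str = "", transform: str = "") -> APFCurve:
    """Accumulative persistence function: cumulative lifetime sum over mean age.

    Points sharing a mean age merge into a single step of summed height.
    """
    if len(r) == 0:
        return APFCurve(np.array([]), np.array([]), dim=r.dim, side=side, transform=transform)
    order = np.argsort(r.mean_ages, kind="stable")
    m_sorted = r.mean_ages[order]
    l_sorted = r.lifetimes[order]
    uniq, inverse = np.unique(m_sorted, return_inverse=True)
    heights = np.zeros(uniq.size)
    np.add.at(heights, inverse, l_sorted)
    return APFCurve(uniq, np.cumsum(heights), dim=r.dim, side=side, transform=transform)


def reva(apf_left: APFCurve, apf_right: APFCurve) -> tuple[float, float]:
    """Signed supremum difference between two APF curves.

    Evaluates ``D(m) = APF_R(m) - APF_L(m)`` on the union of both curves'
    breakpoints (where the piecewise-constant difference attains its
    supremum), locates the ``m`` with the largest ``|D(m)|`` (ties broken
    toward the smallest ``m``), and returns the signed value there together
    with that location.
    """
    if apf_left.dim != apf_right.dim:
        raise ValueError(f"dimension mismatch: {apf_left.dim} vs {apf_right.dim}")
    if apf_left.transform and apf_right.transform and apf_left.transform != apf_right.transform:
        raise ValueError(f"transform mismatch: {apf_left.transform!r} vs {apf_right.transform!r}")
    grid = np.union1d(apf_left.breakpoints, apf_right.breakpoints)
    if grid.size == 0:
        return 0.0, 0.0
    diff = apf_right(grid) - apf_left(grid)
    k = int(np.argmax(np.abs(diff)))  # first occurrence = smallest m on a sorted grid
    return float(diff[k]), float(grid[k])


def compute_reva_pair(
    left: GreyscaleImage | np.ndarray,
    right: GreyscaleImage | np.ndarray,
    transform: str = "unit",
) -> ReVAResult:
    """Full asymmetry chain for one aligned left/right image pair.

    Both images are intensity-transformed (``unit``: min-max rescale to
    [0, 1]; ``z``: global standardization), filtered, and summarized as APF
    curves in dimensions 0 and 1; the signed supremum difference
    (right minus left) is returned per dimension with its argmax location.
    """
    import warnings as _warnings

    if transform not in ("unit", "z"):
        raise ValueError(f"transform must be 'unit' or 'z', got {transform!r}")
    tf = unit_transform if transform == "unit" else z_transform

    left_g = left if isinstance(left, GreyscaleImage) else GreyscaleImage(np.asarray(left, dtype=float))
    right_g = right if isinstance(right, GreyscaleImage) else GreyscaleImage(np.asarray(right, dtype=float))
    if left_g.values.shape != right_g.values.shape:
        _warnings.warn(
            f"left/right shapes differ ({left_g.values.shape} vs {right_g.values.shape}); "
            "images are expected to be pre-aligned",
            stacklevel=2,
        )
    left_t, right_t = tf(left_g), tf(right_g)

    values = {}
    for dim in (0, 1):
        apf_l = apf_curve(rrpd(compute_persistence(left_t, dim)), side="left", transform=transform)
        apf_r = apf_curve(rrpd(compute_persistence(right_t, dim)), side="right", transform=transform)
        values[dim] = reva(apf_l, apf_r)
    return ReVAResult(
        reva0=values[0][0],
        reva1=values[1][0],
        m0_max=values[0][1],
        m1_max=values[1][1],
        transform=transform,
    )


class ReVAExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping aligned image pairs to asymmetry features.

    Each sample is a ``(left, right)`` pair of 2-D arrays (or
    :class:`GreyscaleImage`); the output row is
    ``[reva0, reva1, m0_max, m1_max]``.

    Parameters
    ----------
    intensity_transform : {"unit", "z"}, default="unit"
        Intensity transform applied to both images before filtering.
    """

    def __init__(self, intensity_transform: str = "unit"):
        self.intensity_transform = intensity_transform

    def fit(self, X, y=None):
        if self.intensity_transform not in ("unit", "z"):
            raise ValueError(
                f"intensity_transform must be 'unit' or 'z', got {self.intensity_transform!r}"
            )
        self.n_features_in_ = 2
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_features_in_"):
            self.fit(X)
        rows = []
        for left, right in X:
            res = compute_reva_pair(left, right, transform=self.intensity_transform)
            rows.append([res.reva0, res.reva1, res.m0_max, res.m1_max])
        return np.asarray(rows, dtype=float)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(["reva0", "reva1", "m0_max", "m1_max"], dtype=object)
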