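"""Cubical persistent homology of greyscale images under the sublevel-set filtration.

An image is a two-dimensional field of intensities ``z(i, j)`` on an N x M
pixel lattice.  The sublevel-set filtration at threshold ``l`` contains every
pixel with ``z(i, j) <= l``; as ``l`` grows the family of cubical complexes is
nested.  We use the vertex construction: each pixel is a vertex, edges join
4-neighbours and enter at the maximum of their endpoint values, and unit
squares enter at the maximum of their four corners.

Dimension-0 persistence (connected components) is computed with a union-find
sweep over edges in filtration order; dimension-1 persistence (loops) by
boundary-matrix reduction of the square columns over Z/2.  The one essential
component is assigned death equal to the maximum pixel value so that every
lifetime is finite and downstream lifetime sums are well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GreyscaleImage",
    "PersistenceDiagram",
    "REC601_WEIGHTS",
    "to_greyscale",
    "unit_transform",
    "z_transform",
    "compute_persistence",
    "oracle_betti",
    "filtration_levels",
    "read_image",
    "diagrams_to_frame",
    "write_diagrams_csv",
]

#: Rec.601 luminance weights for RGB -> grey conversion.
REC601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class GreyscaleImage:
    """A finite real-valued intensity field on an N x M pixel lattice.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Pixel intensities (dimensionless).
    transform_tag : {"raw", "unit", "z"}
        Which intensity transform produced these values.
    """

    values: np.ndarray
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite values")
        if self.transform_tag not in ("raw", "unit", "z"):
            raise ValueError(f"unknown transform_tag {self.transform_tag!r}")
        object.__setattr__(self, "values", arr)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death) pairs of one homology dimension.

    ``essential`` marks the never-dying class (the final connected component),
    whose death is set to the maximum pixel value by convention.
    """

    births: np.ndarray
    deaths: np.ndarray
    essential: np.ndarray
    dim: int
    source_transform: str = "raw"

    def __post_init__(self) -> None:
        b = np.asarray(self.births, dtype=float)
        d = np.asarray(self.deaths, dtype=float)
        e = np.asarray(self.essential, dtype=bool)
        if not (b.shape == d.shape == e.shape) or b.ndim != 1:
            raise ValueError("births, deaths and essential must be equal-length 1-D arrays")
        if np.any(d < b):
            raise ValueError("death < birth in persistence diagram")
        object.__setattr__(self, "births", b)
        object.__setattr__(self, "deaths", d)
        object.__setattr__(self, "essential", e)

    def __len__(self) -> int:
        return self.births.size

    def betti_at(self, level: float) -> int:
        """Number of classes alive at threshold ``level``.

        A finite class is alive when ``birth <= level < death``; the essential
        class is alive for every ``level >= birth``.
        """
        alive = (self.births <= level) & (level < self.deaths)
        alive |= self.essential & (self.births <= level)
        return int(alive.sum())


def to_greyscale(rgb: np.ndarray, weights: tuple[float, float, float] = REC601_WEIGHTS) -> GreyscaleImage:
    """Convert a 3-channel image to a single luminance channel.

    Uses Rec.601 weights (0.299 R + 0.587 G + 0.114 B) by default.  A 2-D
    input is passed through unchanged (already grey).
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim == 2:
        return GreyscaleImage(arr, transform_tag="raw")
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (N, M, 3) RGB array, got shape {arr.shape}")
    w = np.asarray(weights, dtype=float)
    grey = arr @ w
    return GreyscaleImage(grey, transform_tag="raw")


def unit_transform(img: GreyscaleImage | np.ndarray) -> GreyscaleImage:
    """Affinely rescale intensities to [0, 1] (min -> 0, max -> 1).

    A constant image maps to all zeros by convention.
    """
    values = img.values if isinstance(img, GreyscaleImage) else np.asarray(img, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return GreyscaleImage(np.zeros_like(values), transform_tag="unit")
    return GreyscaleImage((values - lo) / (hi - lo), transform_tag="unit")


def z_transform(img: GreyscaleImage | np.ndarray) -> GreyscaleImage:
    """Standardize intensities to mean 0, standard deviation 1 over all pixels.

    A constant image maps to all zeros with a warning.
    """
    values = img.values if isinstance(img, GreyscaleImage) else np.asarray(img, dtype=float)
    sd = values.std()
    if sd == 0:
        warnings.warn("constant image: z-transform returns all zeros", stacklevel=2)
        return GreyscaleImage(np.zeros_like(values), transform_tag="z")
    return GreyscaleImage((values - values.mean()) / sd, transform_tag="z")


def filtration_levels(img: GreyscaleImage | np.ndarray) -> np.ndarray:
    """Sorted distinct pixel values — the thresholds where the filtration changes."""
    values = img.values if isinstance(img, GreyscaleImage) else np.asarray(img, dtype=float)
    return np.unique(values)


def _edge_values(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Filtration values of horizontal and vertical edges (max of endpoints)."""
    horiz = np.maximum(z[:, :-1], z[:, 1:])
    vert = np.maximum(z[:-1, :], z[1:, :])
    return horiz, vert


def _h0_pairs(z: np.ndarray) -> tuple[list[tuple[float, float]], tuple[float, float]]:
    """Dimension-0 pairs by union-find over edges in filtration order.

    Components are born at the value of their minimal vertex; when an edge
    merges two components the younger one (larger birth, ties by larger
    minimal-vertex index) dies at the edge value — the elder rule.  Returns
    the finite pairs and the essential pair ``(min(z), max(z))``.
    """
    n, m = z.shape
    flat = z.ravel()
    horiz, vert = _edge_values(z)

    # edge list as (value, u, v) over flat vertex indices
    idx = np.arange(n * m).reshape(n, m)
    eu = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    ev = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    evals = np.concatenate([horiz.ravel(), vert.ravel()])
    order = np.lexsort((eu, evals))

    parent = np.arange(n * m)
    # birth value and birth vertex index per component root
    birth_val = flat.copy()
    birth_idx = np.arange(n * m)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    pairs: list[tuple[float, float]] = []
    for k in order:
        val = evals[k]
        ra, rb = find(int(eu[k])), find(int(ev[k]))
        if ra == rb:
            continue
        # elder rule: keep the component with the smaller (birth value, birth index)
        if (birth_val[ra], birth_idx[ra]) <= (birth_val[rb], birth_idx[rb]):
            elder, young = ra, rb
        else:
            elder, young = rb, ra
        if birth_val[young] < val:  # zero-lifetime merges are dropped
            pairs.append((float(birth_val[young]), float(val)))
        parent[young] = elder
    return pairs, (float(flat.min()), float(flat.max()))


def _h1_pairs(z: np.ndarray) -> list[tuple[float, float]]:
    """Dimension-1 pairs by Z/2 reduction of square columns over edge rows.

    Edges are ordered by (filtration value, index); each unit square's column
    is the set of its four boundary edges and is reduced against previously
    reduced columns sharing its pivot (largest edge in the order).  In a
    planar grid every square pairs with exactly one edge, giving the loop's
    (birth, death).
    """
    n, m = z.shape
    if n < 2 or m < 2:
        return []
    horiz, vert = _edge_values(z)
    n_h = n * (m - 1)
    evals = np.concatenate([horiz.ravel(), vert.ravel()])
    # rank of each edge in the global filtration order
    order = np.lexsort((np.arange(evals.size), evals))
    rank = np.empty(evals.size, dtype=np.int64)
    rank[order] = np.arange(evals.size)
    val_by_rank = evals[order]

    # square (i, j) has boundary: horiz (i,j), horiz (i+1,j), vert (i,j), vert (i,j+1)
    i, j = np.meshgrid(np.arange(n - 1), np.arange(m - 1), indexing="ij")
    top = rank[(i * (m - 1) + j).ravel()]
    bottom = rank[((i + 1) * (m - 1) + j).ravel()]
    left = rank[n_h + (i * m + j).ravel()]
    right = rank[n_h + (i * m + j + 1).ravel()]
    sq_vals = np.maximum.reduce(
        [z[:-1, :-1], z[:-1, 1:], z[1:, :-1], z[1:, 1:]]
    ).ravel()
    sq_order = np.lexsort((np.arange(sq_vals.size), sq_vals))

    pivots: dict[int, frozenset[int]] = {}
    pairs: list[tuple[float, float]] = []
    for s in sq_order:
        col = frozenset((int(top[s]), int(bottom[s]), int(left[s]), int(right[s])))
        while col:
            p = max(col)
            other = pivots.get(p)
            if other is None:
                break
            col = col ^ other
        if not col:  # cannot happen in a planar grid; guard for safety
            continue
        pivots[p] = col
        birth = float(val_by_rank[p])
        death = float(sq_vals[s])
        if death > birth:  # zero-lifetime loops dropped
            pairs.append((birth, death))
    return pairs


def compute_persistence(img: GreyscaleImage | np.ndarray, dim: int) -> PersistenceDiagram:
    """Persistence diagram of the sublevel-set cubical filtration.

    Parameters
    ----------
    img : GreyscaleImage or 2-D array
        The intensity field to filter.
    dim : {0, 1}
        Homology dimension: 0 for connected components, 1 for loops.

    Returns
    -------
    PersistenceDiagram
        Finite pairs with death > birth plus, in dimension 0, the one
        essential component with death set to ``max(values)``.
    """
    if dim not in (0, 1):
        raise ValueError(f"dim must be 0 or 1, got {dim}")
    if isinstance(img, GreyscaleImage):
        z, tag = img.values, img.transform_tag
    else:
        z, tag = np.asarray(img, dtype=float), "raw"
        if z.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {z.shape}")

    if dim == 0:
        pairs, (ess_b, ess_d) = _h0_pairs(z)
        births = np.array([p[0] for p in pairs] + [ess_b])
        deaths = np.array([p[1] for p in pairs] + [ess_d])
        essential = np.zeros(len(pairs) + 1, dtype=bool)
        essential[-1] = True
    else:
        pairs = _h1_pairs(z)
        births = np.array([p[0] for p in pairs])
        deaths = np.array([p[1] for p in pairs])
        essential = np.zeros(len(pairs), dtype=bool)
    return PersistenceDiagram(births, deaths, essential, dim=dim, source_transform=tag)


def oracle_betti(img: GreyscaleImage | np.ndarray, level: float) -> tuple[int, int]:
    """Brute-force Betti numbers of the sublevel complex at a threshold.

    ``b0`` is the flood-fill component count of the vertex mask under
    4-connectivity; ``b1 = b0 - chi`` with ``chi = #vertices - #edges +
    #squares`` of the included complex.  Intentionally independent of the
    persistence computation; guarded to small images (N*M <= 10,000).
    """
    from scipy import ndimage

    z = img.values if isinstance(img, GreyscaleImage) else np.asarray(img, dtype=float)
    if z.size > 10_000:
        raise ValueError(f"oracle_betti is restricted to N*M <= 10,000 pixels, got {z.size}")
    mask = z <= level
    if not mask.any():
        return 0, 0
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    _, b0 = ndimage.label(mask, structure=structure)
    n_vertices = int(mask.sum())
    n_edges = int((mask[:, :-1] & mask[:, 1:]).sum() + (mask[:-1, :] & mask[1:, :]).sum())
    n_squares = int((mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]).sum())
    chi = n_vertices - n_edges + n_squares
    return int(b0), int(b0 - chi)


def read_image(path) -> GreyscaleImage:
    """Read a PNG or TIFF image (8/16-bit, grey or RGB) as a GreyscaleImage.

    RGB(A) inputs are converted with Rec.601 luminance weights; the alpha
    channel, if present, is ignored.
    """
    import imageio.v3 as iio

    try:
        arr = np.asarray(iio.imread(path), dtype=float)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        return to_greyscale(arr)
    return GreyscaleImage(arr, transform_tag="raw")


def diagrams_to_frame(*diagrams: PersistenceDiagram):
    """Stack diagrams into a table with columns dim, birth, death, essential."""
    import pandas as pd

    rows = []
    for d in diagrams:
        rows.append(
            pd.DataFrame(
                {
                    "dim": np.full(len(d), d.dim, dtype=int),
                    "birth": d.births,
                    "death": d.deaths,
                    "essential": d.essential,
                }
            )
        )
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["dim", "birth", "death", "essential"]
    )


def write_diagrams_csv(path, *diagrams: PersistenceDiagram) -> None:
    """Write diagrams as CSV with columns dim, birth, death, essential (one row per point)."""
    diagrams_to_frame(*diagrams).to_csv(path, index=False)
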