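"""Cell-shape morphometrics on traced contours, plus the statistical layer.

Shape descriptors mirror the ImageJ measurements used for leaf cells:
area, perimeter, circularity (4*pi*A/P^2), solidity (A / convex hull A),
aspect ratio of the moment-equivalent ellipse, and the side lengths of the
minimum rotated bounding rectangle (cell length and width).  The statistics
layer provides Welch's t, Hedges' g, Tukey-Kramer HSD and standardized PCA
for comparing descriptor distributions between cell populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon
from sklearn.decomposition import PCA

__all__ = [
    "CellContour",
    "area_perimeter",
    "circularity",
    "solidity",
    "ellipse_aspect_ratio",
    "min_bounding_rectangle",
    "shape_descriptors",
    "descriptor_table",
    "welch_t",
    "hedges_g",
    "tukey_hsd",
    "pca_scores",
]

DESCRIPTOR_COLUMNS = ["area", "perimeter", "circularity", "solidity", "aspect_ratio", "length", "width"]


@dataclass
class CellContour:
    """Closed simple polygon traced around one cell."""

    vertices: np.ndarray  # (n, 2), implicitly closed
    cell_id: str = ""
    group: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 (x, y) vertices")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


def _as_polygon(contour) -> Polygon:
    poly = contour.polygon() if isinstance(contour, CellContour) else Polygon(np.asarray(contour, float))
    if not poly.is_valid:
        raise ValueError("contour is not a simple polygon (self-intersecting or degenerate)")
    if poly.area == 0:
        raise ValueError("contour encloses zero area")
    return poly


def area_perimeter(contour) -> tuple[float, float]:
    """Enclosed (shoelace) area and closed-path perimeter; orientation-free."""
    poly = _as_polygon(contour)
    return float(poly.area), float(poly.length)


def circularity(contour) -> float:
    """4*pi*A / P^2, clipped at 1 (discrete polygons can exceed it numerically)."""
    a, p = area_perimeter(contour)
    return min(1.0, 4.0 * np.pi * a / p**2)


def solidity(contour) -> float:
    """Area over convex-hull area; 1 for convex shapes, lower for lobed cells."""
    poly = _as_polygon(contour)
    return min(1.0, poly.area / poly.convex_hull.area)


def _central_moments(vertices: np.ndarray) -> tuple[float, float, float]:
    """Second-order central moments of the polygon interior (per unit area).

    Green's-theorem closed forms over the boundary, so the result depends on
    the enclosed region only, not on vertex density.
    """
    x = vertices[:, 0]
    y = vertices[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    cx = np.sum((x + x1) * cross) / (6.0 * a)
    cy = np.sum((y + y1) * cross) / (6.0 * a)
    ixx = np.sum(cross * (y * y + y * y1 + y1 * y1)) / 12.0
    iyy = np.sum(cross * (x * x + x * x1 + x1 * x1)) / 12.0
    ixy = np.sum(cross * (x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y)) / 24.0
    mu20 = iyy / a - cx * cx
    mu02 = ixx / a - cy * cy
    mu11 = ixy / a - cx * cy
    return mu20, mu02, mu11


def ellipse_aspect_ratio(contour) -> float:
    """Major/minor axis ratio of the moment-equivalent (best-fit) ellipse.

    The ellipse shares the polygon region's second-order central moments;
    the ratio of its axes is the square root of the covariance eigenvalue
    ratio.  Always >= 1; rotation invariant.
    """
    poly = _as_polygon(contour)
    verts = np.asarray(poly.exterior.coords)[:-1]
    mu20, mu02, mu11 = _central_moments(verts)
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    lam = np.linalg.eigvalsh(cov)
    if lam[0] <= 0:
        raise ValueError("degenerate region: zero minor axis")
    return float(np.sqrt(lam[1] / lam[0]))


def min_bounding_rectangle(contour) -> tuple[float, float]:
    """(length, width) of the minimum-area rotated enclosing rectangle.

    Rotation-free cell length and width: the rectangle is fitted over the
    convex hull at the optimal orientation, and the longer side is reported
    first.
    """
    poly = _as_polygon(contour)
    rect = shapely.minimum_rotated_rectangle(poly)
    coords = np.asarray(rect.exterior.coords)
    sides = np.linalg.norm(np.diff(coords, axis=0), axis=1)[:2]
    length, width = max(sides), min(sides)
    if width == 0:
        raise ValueError("degenerate contour: zero-width bounding rectangle")
    return float(length), float(width)


def shape_descriptors(contour) -> dict:
    """All descriptors of one contour as a dict (see DESCRIPTOR_COLUMNS)."""
    a, p = area_perimeter(contour)
    length, width = min_bounding_rectangle(contour)
    return {
        "area": a,
        "perimeter": p,
        "circularity": min(1.0, 4.0 * np.pi * a / p**2),
        "solidity": solidity(contour),
        "aspect_ratio": ellipse_aspect_ratio(contour),
        "length": length,
        "width": width,
    }


def descriptor_table(contours) -> pd.DataFrame:
    """One descriptor row per cell, keyed by cell id with its group label."""
    rows = []
    for i, c in enumerate(contours):
        rec = {"cell_id": c.cell_id or f"cell{i}", "group": c.group}
        rec.update(shape_descriptors(c))
        rows.append(rec)
    return pd.DataFrame(rows).set_index("cell_id")


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Welch-Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def hedges_g(group_a, group_b) -> float:
    """Standardized mean difference with small-sample bias correction.

    g = (mean_a - mean_b) / s_pooled * J with J = 1 - 3/(4(n_a+n_b-2)-1).
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two values")
    dof = na + nb - 2
    s2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / dof
    if s2 == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    j = 1.0 - 3.0 / (4.0 * dof - 1.0)
    return float((a.mean() - b.mean()) / np.sqrt(s2) * j)


def tukey_hsd(groups: dict, alpha: float = 0.05, letters: bool = False):
    """Tukey-Kramer pairwise comparisons over named groups.

    Studentized-range procedure on group means with pooled within-group
    variance.  Returns a DataFrame of pairwise adjusted p-values (and the
    mean difference), plus a compact letter display per group when
    ``letters`` is requested.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("Tukey HSD needs at least two groups")
    arrays = [np.asarray(groups[g], float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    if all(a.var(ddof=1) == 0 for a in arrays):
        raise ValueError("zero pooled within-group variance")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "pvalue": float(res.pvalue[i, j]),
                }
            )
    table = pd.DataFrame(rows)
    if not letters:
        return table

    # greedy compact letter display: groups sharing a letter are not distinct
    distinct = {
        (r["group_a"], r["group_b"]) for _, r in table.iterrows() if r["pvalue"] < alpha
    }
    distinct |= {(b, a) for a, b in distinct}
    order = sorted(names, key=lambda g: -np.mean(groups[g]))
    letter_sets: list[set] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all((g, other) not in distinct for other in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    display = {g: "" for g in names}
    for s, ch in zip(letter_sets, alphabet):
        for g in s:
            display[g] += ch
    return table, pd.Series(display, name="letters")


def pca_scores(index_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a cells x descriptors table after centering/unit-variance scaling.

    Zero-variance descriptors are dropped with a warning.  Returns the
    per-cell scores, the orthonormal loadings (descriptors x components) and
    the explained variances, which for standardized data sum to the number
    of descriptors kept.
    """
    import warnings

    numeric = index_table.select_dtypes(include=[np.number])
    if numeric.shape[1] < 2 or numeric.shape[0] < 3:
        raise ValueError("PCA needs at least 2 descriptors and 3 cells")
    sd = numeric.std(ddof=1)
    dead = sd.index[sd == 0]
    if len(dead):
        warnings.warn(f"dropping zero-variance descriptors: {list(dead)}", stacklevel=2)
        numeric = numeric.drop(columns=dead)
        sd = sd.drop(dead)
    z = (numeric - numeric.mean()) / sd
    pca = PCA()
    scores = pca.fit_transform(z.to_numpy())
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=numeric.index, columns=comps),
        pd.DataFrame(pca.components_.T, index=numeric.columns, columns=comps),
        pca.explained_variance_,
    )
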