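"""Hull-based (geometric) home-range estimators.

The minimum convex polygon (MCP) peels the outermost fixes by distance from
the centroid and takes the convex hull of what remains; the local convex
hull estimator (k-LoCoH) accumulates small k-nearest-neighbor hulls in order
of increasing area until the requested fraction of fixes is covered.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

from .errors import DegenerateGeometryError, DomainError
from .estimates import HomeRangeEstimator, _check_levels
from .tracks import Track

__all__ = ["Mcp", "Locoh", "hr_mcp", "hr_locoh"]


def _hull_of(points: np.ndarray):
    return MultiPoint(points).convex_hull


class Mcp(HomeRangeEstimator):
    """Minimum convex polygon home range.

    For each level α the fixes within the α-quantile of Euclidean distance
    to the mean-coordinate centroid are retained (linear-interpolation
    quantile, the R type-7 convention) and their convex hull is the
    home-range polygon.

    Parameters
    ----------
    levels : list of float in (0, 1], default [0.95]
        Home-range levels.
    keep_data : bool, default True
        Store the source track on the fitted estimator.

    Attributes
    ----------
    isopleths_ : DataFrame with columns level, what, geometry, area.
    """

    name = "mcp"

    def __init__(self, levels=(0.95,), keep_data=True):
        self.levels = levels
        self.keep_data = keep_data

    def fit(self, X: Track, y=None):
        track = X
        track.require_projected()
        levels = _check_levels(self.levels)
        xy = track.xy
        if len(xy) < 3:
            raise DegenerateGeometryError(
                f"MCP needs at least 3 fixes, got {len(xy)}"
            )
        centroid = xy.mean(axis=0)
        d = np.hypot(*(xy - centroid).T)
        rows = []
        for lev in levels:
            cut = np.quantile(d, lev, method="linear")  # R type-7
            retained = xy[d <= cut]
            hull = _hull_of(retained)
            if hull.geom_type != "Polygon":
                raise DegenerateGeometryError(
                    f"MCP at level {lev}: retained fixes are fewer than 3 or collinear"
                )
            rows.append(
                {"level": lev, "what": "estimate", "geometry": hull, "area": hull.area}
            )
        self.levels_ = levels
        self.crs_ = track.crs
        self.data_ = track if self.keep_data else None
        self.isopleths_ = pd.DataFrame(rows)
        return self


class Locoh(HomeRangeEstimator):
    """k-nearest-neighbor local convex hull (k-LoCoH) home range.

    Each fix forms a local hull with its ``n - 1`` nearest neighbors
    (``n`` points per hull, focal point included). Hulls are sorted by area
    (ties broken by fix index) and unioned cumulatively; the isopleth at
    level α is the first union covering at least ``ceil(α·N)`` fixes.

    Parameters
    ----------
    n : int or "auto"
        Points per local hull; "auto" uses ``ceil(sqrt(N))``, a common
        heuristic for the neighbor count.
    levels : list of float in (0, 1], default [0.95]
    keep_data : bool, default True
    """

    name = "locoh"

    def __init__(self, n="auto", levels=(0.95,), keep_data=True):
        self.n = n
        self.levels = levels
        self.keep_data = keep_data

    def fit(self, X: Track, y=None):
        track = X
        track.require_projected()
        levels = _check_levels(self.levels)
        xy = track.xy
        N = len(xy)
        n = int(np.ceil(np.sqrt(N))) if self.n == "auto" else int(self.n)
        if n < 3:
            raise DomainError(f"LoCoH needs n >= 3 points per hull, got {n}")
        if n > N:
            raise DomainError(f"n = {n} exceeds the number of fixes ({N})")

        # n-1 nearest neighbors of each fix (Euclidean), plus the fix itself
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        order = np.argsort(d2, axis=1, kind="stable")
        hulls = []
        n_degenerate = 0
        for i in range(N):
            pts = xy[order[i, :n]]
            hull = _hull_of(pts)
            if hull.geom_type != "Polygon" or hull.area == 0.0:
                n_degenerate += 1
                continue
            hulls.append((hull.area, i, hull))
        if n_degenerate:
            warnings.warn(
                f"LoCoH: skipped {n_degenerate} degenerate local hulls "
                "(duplicate or collinear neighbor sets)",
                stacklevel=2,
            )
        if not hulls:
            raise DegenerateGeometryError("LoCoH: all local hulls degenerate")
        hulls.sort(key=lambda h: (h[0], h[1]))

        pts = shapely.points(xy[:, 0], xy[:, 1])
        needed = {lev: int(np.ceil(lev * N)) for lev in levels}
        remaining = sorted(levels)
        rows = []
        union = None
        covered_mask = np.zeros(N, dtype=bool)
        for _, _, hull in hulls:
            union = hull if union is None else union.union(hull)
            todo = ~covered_mask
            if todo.any():
                covered_mask[todo] = shapely.covers(union, pts[todo])
            covered = int(covered_mask.sum())
            while remaining and covered >= needed[remaining[0]]:
                lev = remaining.pop(0)
                geom = union
                rows.append(
                    {"level": lev, "what": "estimate", "geometry": geom, "area": geom.area}
                )
            if not remaining:
                break
        # levels never reached (degenerate fixes excluded from every hull):
        for lev in remaining:
            geom = union
            rows.append(
                {"level": lev, "what": "estimate", "geometry": geom, "area": geom.area}
            )
        rows.sort(key=lambda r: r["level"])

        self.levels_ = levels
        self.n_ = n
        self.crs_ = track.crs
        self.data_ = track if self.keep_data else None
        self.isopleths_ = pd.DataFrame(rows)
        return self


def hr_mcp(track: Track, levels=(0.95,), keep_data=True) -> Mcp:
    """Minimum convex polygon home range of a track (thin wrapper over Mcp)."""
    return Mcp(levels=levels, keep_data=keep_data).fit(track)


def hr_locoh(track: Track, n="auto", levels=(0.95,), keep_data=True) -> Locoh:
    """k-LoCoH home range of a track (thin wrapper over Locoh)."""
    return Locoh(n=n, levels=levels, keep_data=keep_data).fit(track)
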