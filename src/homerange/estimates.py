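"""The shared estimator contract: areas, isopleths, overlap.

Every home-range estimator in this package — geometric or probabilistic —
is an sklearn-style estimator whose :meth:`fit` accepts a
:class:`~homerange.tracks.Track` and exposes, once fitted:

``levels_``      the home-range levels (isopleth fractions),
``crs_``         the EPSG code inherited from the data,
``data_``        the source track (unless dropped),
``isopleths_``   a DataFrame with columns ``level, what, geometry, area``
                 (``what`` is ``estimate`` or a confidence bound).

The module-level functions :func:`hr_area`, :func:`hr_isopleths` and
:func:`hr_overlap` work uniformly on any fitted estimator.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from sklearn.base import BaseEstimator

from .errors import CRSError, DomainError, UnsupportedOperationError

__all__ = [
    "HomeRangeEstimator",
    "hr_area",
    "hr_isopleths",
    "hr_overlap",
    "isopleths_to_geojson",
    "isopleths_from_geojson",
]

_SYMMETRIC = {"vi", "ba", "udoi", "hd"}
_INDICES = {"hr", "phr", "vi", "ba", "udoi", "hd"}


def _check_levels(levels, open_upper=False):
    levels = sorted(float(l) for l in levels)
    hi = 1.0
    for l in levels:
        if not (0.0 < l <= hi) or (open_upper and l >= 1.0):
            raise DomainError(f"home-range level {l} outside (0, 1{')' if open_upper else ']'}")
    if len(set(levels)) != len(levels):
        raise DomainError("duplicate home-range levels")
    return levels


class HomeRangeEstimator(BaseEstimator):
    """Base class for home-range estimators (do not instantiate directly)."""

    def fit(self, X, y=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_fitted(self):
        if not hasattr(self, "isopleths_"):
            raise UnsupportedOperationError(
                f"{type(self).__name__} is not fitted; call fit(track) first"
            )

    # -- shared contract ----------------------------------------------------
    def area(self) -> pd.DataFrame:
        """Long-format area table: one row per (level, what)."""
        self._check_fitted()
        return self.isopleths_[["level", "what", "area"]].reset_index(drop=True)

    def isopleth_table(self) -> pd.DataFrame:
        self._check_fitted()
        return self.isopleths_.reset_index(drop=True)

    @property
    def is_probabilistic(self) -> bool:
        return hasattr(self, "ud_")


def hr_area(est) -> pd.DataFrame:
    """Home-range area per level as a tidy table (level, what, area [m²])."""
    return est.area()


def hr_isopleths(est) -> pd.DataFrame:
    """Isopleth polygons per level with attributes level/what/area."""
    return est.isopleth_table()


# ---------------------------------------------------------------------------
# GeoJSON interchange


def isopleths_to_geojson(est_or_table, crs=None) -> dict:
    """Isopleths as a GeoJSON FeatureCollection.

    Feature properties: ``level``, ``what`` and ``area_m2``; the EPSG code
    (from ``crs`` or the estimator) is recorded as a named-CRS member.
    """
    if isinstance(est_or_table, pd.DataFrame):
        table = est_or_table
    else:
        table = est_or_table.isopleth_table()
        if crs is None:
            crs = getattr(est_or_table, "crs_", None)
    feats = []
    for _, row in table.iterrows():
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(row["geometry"]),
                "properties": {
                    "level": float(row["level"]),
                    "what": str(row["what"]),
                    "area_m2": float(row["area"]),
                },
            }
        )
    out = {"type": "FeatureCollection", "features": feats}
    if crs is not None:
        out["crs"] = {
            "type": "name",
            "properties": {"name": f"urn:ogc:def:crs:EPSG::{int(crs)}"},
        }
    return out


def geojson_crs(obj) -> int | None:
    """EPSG code recorded in a FeatureCollection's named-CRS member, if any."""
    name = obj.get("crs", {}).get("properties", {}).get("name", "")
    tail = name.rsplit(":", 1)[-1]
    return int(tail) if tail.isdigit() else None


def isopleths_from_geojson(obj) -> pd.DataFrame:
    """Inverse of :func:`isopleths_to_geojson` (accepts a dict or a path).

    The EPSG code, when present, is returned in ``df.attrs["crs"]``.
    """
    if not isinstance(obj, dict):
        with open(obj) as fh:
            obj = json.load(fh)
    rows = []
    for f in obj["features"]:
        rows.append(
            {
                "level": float(f["properties"]["level"]),
                "what": f["properties"].get("what", "estimate"),
                "geometry": shape(f["geometry"]),
                "area": float(f["properties"]["area_m2"]),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["crs"] = geojson_crs(obj)
    return out


class EstimateBundle:
    """A home-range estimate reloaded from files.

    Duck-types the fitted-estimator surface (`isopleth_table`, `levels_`,
    `crs_`, optional `ud_`/`trast_`) so :func:`hr_overlap` works on outputs
    of previous runs.
    """

    def __init__(self, isopleths: pd.DataFrame, crs=None, ud=None, trast=None):
        self.isopleths_ = isopleths
        self.levels_ = sorted(isopleths.loc[isopleths["what"] == "estimate", "level"].unique())
        self.crs_ = crs
        if ud is not None:
            self.ud_ = ud
            self.trast_ = trast

    @property
    def is_probabilistic(self):
        return hasattr(self, "ud_")

    def isopleth_table(self):
        return self.isopleths_

    def area(self):
        return self.isopleths_[["level", "what", "area"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# overlap


def _estimate_polygon(est, level):
    tab = est.isopleth_table()
    row = tab[(tab["what"] == "estimate") & (np.isclose(tab["level"], level))]
    if row.empty:
        raise DomainError(f"estimate has no isopleth at level {level}")
    return row.iloc[0]["geometry"]


def _shared_levels(a, b):
    la = {round(l, 12) for l in a.levels_}
    lb = {round(l, 12) for l in b.levels_}
    shared = sorted(la & lb)
    if not shared:
        raise DomainError("estimates share no home-range levels")
    return shared


def _masses_on_trast(est, trast):
    """Cell probability masses of ``est`` sampled onto template ``trast``."""
    if est.trast_ == trast:
        return est.ud_
    # cell-center sampling of the other estimate's grid, then renormalize
    xc, yc = trast.x_centers, trast.y_centers
    src = est.trast_
    j = np.floor((xc - src.xmin) / src.cell_size).astype(int)
    i = np.floor((yc - src.ymin) / src.cell_size).astype(int)
    ok_j = (j >= 0) & (j < src.ncol)
    ok_i = (i >= 0) & (i < src.nrow)
    out = np.zeros((trast.nrow, trast.ncol))
    jj, ii = np.meshgrid(np.clip(j, 0, src.ncol - 1), np.clip(i, 0, src.nrow - 1))
    vals = est.ud_[ii, jj]
    vals[~np.outer(ok_i, ok_j)] = 0.0
    s = vals.sum()
    if s <= 0:
        # disjoint supports: no mass falls on the target grid
        warnings.warn("re-rasterized UD has no mass on the target template")
        return vals
    return vals / s


def hr_overlap(
    a,
    b,
    type: str = "hr",
    levels=None,
    conditional: bool = False,
) -> pd.DataFrame:
    """Overlap of two home-range estimates.

    ``hr`` — fraction of *a*'s isopleth polygon intersected by *b*'s
    (directional: swapping the arguments changes the answer).
    ``phr`` — probability mass of *a*'s UD inside *b*'s isopleth (directional).
    ``vi``/``ba``/``udoi``/``hd`` — volume of intersection, Bhattacharyya
    affinity, UD overlap index and Hellinger's distance of the two UDs
    (symmetric). Probabilistic indices require both estimates to carry UDs;
    *b* is re-rasterized onto *a*'s template raster when the grids differ.
    With ``conditional=True`` each UD is first truncated to its isopleth at
    the evaluated level and renormalized.

    Returns a tidy table (level, index, value); the UD-wide symmetric indices
    are reported once per requested level for convenience.
    """
    if type not in _INDICES:
        raise DomainError(f"unknown overlap index {type!r} (choose from {sorted(_INDICES)})")
    if a.crs_ != b.crs_:
        raise CRSError(f"CRS mismatch: EPSG:{a.crs_} vs EPSG:{b.crs_}")
    levels = _shared_levels(a, b) if levels is None else _check_levels(levels)

    rows = []
    if type == "hr":
        for lev in levels:
            pa = _estimate_polygon(a, lev)
            pb = _estimate_polygon(b, lev)
            area_a = pa.area
            val = pa.intersection(pb).area / area_a if area_a > 0 else 0.0
            rows.append({"level": lev, "index": "hr", "value": min(1.0, max(0.0, val))})
        return pd.DataFrame(rows)

    if not a.is_probabilistic:
        raise UnsupportedOperationError(
            f"index {type!r} needs a utilization distribution; "
            f"{a.__class__.__name__} is geometric"
        )

    if type == "phr":
        # mass of a's UD inside b's isopleth polygon
        for lev in levels:
            pb = _estimate_polygon(b, lev)
            inside = a.trast_.centers_covered_by(pb)
            val = min(1.0, max(0.0, float(a.ud_[inside].sum())))
            rows.append({"level": lev, "index": "phr", "value": val})
        return pd.DataFrame(rows)

    if not b.is_probabilistic:
        raise UnsupportedOperationError(
            f"index {type!r} needs utilization distributions on both arguments"
        )
    # evaluate on the finer of the two grids so symmetric indices are
    # exactly invariant under argument swap
    def _rank(est):
        t = est.trast_
        return (t.cell_size, t.xmin, t.ymin, t.ncol, t.nrow)

    ref, other = (a, b)
    if b.trast_ != a.trast_ and _rank(b) < _rank(a):
        ref, other = (b, a)
    ud_a = ref.ud_
    ud_b = _masses_on_trast(other, ref.trast_)
    if ref is b:
        ud_a, ud_b = ud_b, ud_a
    cell = ref.trast_.cell_size ** 2

    for lev in levels:
        pa_, pb_ = ud_a, ud_b
        if conditional:
            pa_ = _truncate_to_level(a, ud_a, lev)
            pb_ = _truncate_to_level(None, ud_b, lev)
        if type == "vi":
            val = min(1.0, max(0.0, float(np.minimum(pa_, pb_).sum())))
        elif type == "ba":
            val = min(1.0, max(0.0, float(np.sqrt(pa_ * pb_).sum())))
        elif type == "hd":
            val = max(0.0, float(2.0 * (1.0 - np.sqrt(pa_ * pb_).sum())))
        elif type == "udoi":
            # canonical operand order keeps the swap invariance bit-exact
            inter = _estimate_polygon(ref, lev).intersection(
                _estimate_polygon(other, lev)
            ).area
            val = float(inter * (pa_ * pb_).sum() / cell)
        rows.append({"level": lev, "index": type, "value": val})
    return pd.DataFrame(rows)


def _truncate_to_level(est, masses, level):
    """Keep the highest-density cells holding ``level`` of the mass; renormalize."""
    flat = masses.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    keep = np.zeros_like(flat, dtype=bool)
    keep[order[:k]] = True
    out = np.where(keep, flat, 0.0)
    s = out.sum()
    return (out / s).reshape(masses.shape)
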