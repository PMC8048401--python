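"""Utilization-distribution estimators on a template raster.

Classical kernel density estimation (KDE) with the bivariate
normal-reference bandwidth, and autocorrelated KDE (aKDE) whose bandwidth
uses the effective sample size implied by a fitted continuous-time movement
model instead of the nominal n. The UD is stored as per-cell probability
masses; home-range isopleths are contours of the cumulative UD.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import chi2
from shapely.geometry import LinearRing, MultiPolygon, Polygon
from shapely.validation import make_valid
from skimage import measure

from .errors import DegenerateGeometryError, DomainError, UnsupportedOperationError
from .estimates import HomeRangeEstimator, _check_levels
from .movement import CTMMFit, fit_ctmm
from .raster import TemplateRaster
from .tracks import Track

__all__ = [
    "make_trast",
    "Kde",
    "Akde",
    "hr_kde",
    "hr_akde",
    "hr_ud",
    "hr_cud",
    "ud_level_mask",
    "ud_to_isopleths",
]


def make_trast(track: Track, buffer="auto", ncol: int = 200) -> TemplateRaster:
    """Template raster covering the track with a buffered extent.

    The extent is the bounding box of the fixes expanded by ``buffer`` meters
    on every side; ``"auto"`` uses half the larger bounding-box span. Cells
    are square, sized to give ``ncol`` columns.
    """
    if len(track) == 0:
        raise DomainError("cannot build a template raster from an empty track")
    xmin, xmax = float(track.x.min()), float(track.x.max())
    ymin, ymax = float(track.y.min()), float(track.y.max())
    if buffer == "auto":
        buffer = 0.5 * max(xmax - xmin, ymax - ymin)
    buffer = float(buffer)
    if xmax - xmin + 2 * buffer <= 0 or ymax - ymin + 2 * buffer <= 0:
        raise DegenerateGeometryError(
            "track has zero extent and no buffer; pass an explicit buffer > 0"
        )
    return TemplateRaster.from_extent(
        xmin - buffer, xmax + buffer, ymin - buffer, ymax + buffer, ncol=ncol, crs=track.crs
    )


def _gaussian_ud(xy: np.ndarray, hx: np.ndarray, hy: np.ndarray, trast: TemplateRaster):
    """Equally weighted product-Gaussian kernel masses on the template grid.

    ``hx``/``hy`` are per-fix standard deviations (scalar broadcastable).
    Returns masses normalized to total 1.
    """
    hx = np.broadcast_to(np.asarray(hx, float), (len(xy),))
    hy = np.broadcast_to(np.asarray(hy, float), (len(xy),))
    gx = np.exp(-0.5 * ((trast.x_centers[:, None] - xy[None, :, 0]) / hx[None, :]) ** 2) / hx
    gy = np.exp(-0.5 * ((trast.y_centers[:, None] - xy[None, :, 1]) / hy[None, :]) ** 2) / hy
    dens = gy @ gx.T  # (nrow, ncol)
    total = dens.sum()
    if total <= 0 or not np.isfinite(total):
        raise DomainError("kernel density underflowed the template grid")
    return dens / total


def hr_ud(est) -> np.ndarray:
    """Per-cell probability masses of a probabilistic estimate (sum = 1)."""
    if not hasattr(est, "ud_"):
        raise UnsupportedOperationError(
            f"{type(est).__name__} has no utilization distribution"
        )
    return est.ud_


def hr_cud(est_or_ud) -> np.ndarray:
    """Cumulative UD: each cell holds the total mass of cells at least as dense.

    Cells ranked by density descending; tied densities share the larger
    cumulative value; values lie in (0, 1].
    """
    ud = est_or_ud if isinstance(est_or_ud, np.ndarray) else hr_ud(est_or_ud)
    flat = ud.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    # ties share the cumulative value at the end of their tie block
    vals = flat[order]
    block_end = np.empty_like(cum)
    i = len(vals) - 1
    while i >= 0:
        j = i
        while j > 0 and vals[j - 1] == vals[i]:
            j -= 1
        block_end[j : i + 1] = cum[i]
        i = j - 1
    out = np.empty_like(flat)
    out[order] = block_end
    return out.reshape(ud.shape)


def ud_level_mask(ud: np.ndarray, level: float) -> np.ndarray:
    """Smallest set of highest-density cells whose total mass is >= level.

    Equivalent to thresholding the cumulative UD while including the cell at
    which the cumulative mass crosses the level (ties share membership).
    """
    cud = hr_cud(ud)
    return cud - ud < level


def _rings_to_multipolygon(rings):
    """Assemble closed rings into polygons-with-holes by containment parity."""
    polys = []
    for ring in rings:
        if len(ring) < 4:
            continue
        p = Polygon(LinearRing(ring))
        if p.area > 0:
            polys.append(p)
    if not polys:
        return Polygon()
    polys.sort(key=lambda p: -p.area)
    depth = [0] * len(polys)
    parent = [-1] * len(polys)
    for i, p in enumerate(polys):
        pt = p.representative_point()
        for j in range(i - 1, -1, -1):
            if polys[j].contains(pt):
                depth[i] = depth[j] + 1
                parent[i] = j
                break
    shells = {}
    for i, p in enumerate(polys):
        if depth[i] % 2 == 0:
            shells[i] = [p.exterior, []]
    for i, p in enumerate(polys):
        if depth[i] % 2 == 1 and parent[i] in shells:
            shells[parent[i]][1].append(p.exterior)
    out = [Polygon(sh, holes) for sh, holes in shells.values()]
    geom = out[0] if len(out) == 1 else MultiPolygon(out)
    if not geom.is_valid:
        geom = make_valid(geom)
    return geom


def ud_to_isopleths(est_or_ud, levels, trast: TemplateRaster | None = None) -> pd.DataFrame:
    """Isopleth polygons of the cumulative UD at the given levels.

    Contours are traced on the cumulative surface by marching squares and
    polygonized with holes preserved, so polygon membership matches the
    mass interpretation (cells inside hold the requested fraction of the UD).
    """
    if isinstance(est_or_ud, np.ndarray):
        ud = est_or_ud
        if trast is None:
            raise DomainError("passing a raw UD grid requires the template raster")
    else:
        ud = hr_ud(est_or_ud)
        trast = est_or_ud.trast_
    levels = _check_levels(levels, open_upper=True)
    cud = hr_cud(ud)
    padded = np.pad(cud, 1, constant_values=2.0)  # close contours at the edge
    cell = trast.cell_size
    rows = []
    for lev in levels:
        contours = measure.find_contours(padded, lev)
        rings = []
        for c in contours:
            # array index -> map coordinates (cell centers, row 0 at south)
            x = trast.xmin + (c[:, 1] - 1 + 0.5) * cell
            y = trast.ymin + (c[:, 0] - 1 + 0.5) * cell
            rings.append(np.column_stack([x, y]))
        geom = _rings_to_multipolygon(rings)
        if geom.is_empty:
            warnings.warn(f"no isopleth at level {lev}: outside the cumulative range")
        rows.append({"level": lev, "what": "estimate", "geometry": geom, "area": geom.area})
    return pd.DataFrame(rows)


class Kde(HomeRangeEstimator):
    """Kernel density home-range estimate with the normal-reference bandwidth.

    The default per-axis bandwidth ``h_i = sd_i * n**(-1/6)`` minimizes the
    asymptotic integrated mean squared error when the fixes are bivariate
    normal. The UD is the equally weighted sum of product-Gaussian kernels
    at the fixes, evaluated at cell centers and normalized to unit mass.

    Parameters
    ----------
    levels : list of float in (0, 1), default [0.95]
    h : "ref" or (hx, hy)
        Bandwidth per axis in meters, or the normal-reference rule.
    trast : TemplateRaster, optional
        Evaluation grid; built automatically from the track when omitted.
    buffer, ncol :
        Passed to :func:`make_trast` when ``trast`` is None.
    """

    name = "kde"

    def __init__(self, levels=(0.95,), h="ref", trast=None, buffer="auto", ncol=200, keep_data=True):
        self.levels = levels
        self.h = h
        self.trast = trast
        self.buffer = buffer
        self.ncol = ncol
        self.keep_data = keep_data

    def _bandwidth(self, track: Track):
        if self.h == "ref":
            n = len(track)
            if n < 5:
                raise DomainError("the reference bandwidth needs at least 5 fixes")
            sd = track.xy.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise DomainError(
                    "zero variance on an axis; the reference bandwidth is undefined "
                    "— pass an explicit h=(hx, hy)"
                )
            return sd * n ** (-1.0 / 6.0)
        hx, hy = (self.h, self.h) if np.isscalar(self.h) else self.h
        if hx <= 0 or hy <= 0:
            raise DomainError("bandwidths must be positive")
        return np.array([hx, hy], dtype=float)

    def fit(self, X: Track, y=None):
        track = X
        track.require_projected()
        levels = _check_levels(self.levels, open_upper=True)
        trast = self.trast if self.trast is not None else make_trast(track, self.buffer, self.ncol)
        h = self._bandwidth(track)
        ud = _gaussian_ud(track.xy, h[0], h[1], trast)
        self.levels_ = levels
        self.h_ = h
        self.trast_ = trast
        self.ud_ = ud
        self.crs_ = track.crs
        self.data_ = track if self.keep_data else None
        self.isopleths_ = ud_to_isopleths(ud, levels, trast)
        return self


class Akde(HomeRangeEstimator):
    """Autocorrelated kernel density home-range estimate.

    As :class:`Kde`, but the squared per-axis bandwidth is
    ``h_i² = sd_i² * dof_area**(-1/3)`` — the normal-reference rule with the
    nominal sample size replaced by the effective sample size implied by the
    fitted movement model's autocorrelation (so a fit with no autocorrelation
    reduces exactly to :class:`Kde`). When the fit carries a GPS
    error scale (uere), each fix's kernel is widened by its own error
    variance. Per-level area confidence intervals use a chi-squared sampling
    model for the positional variance with ``nu = 2 * dof_area`` degrees of
    freedom.

    Parameters
    ----------
    ctmm : CTMMFit, optional
        A fitted movement model for the same track; fitted internally
        (``model``, ``uere``) when omitted.
    model, uere :
        Passed to :func:`~homerange.movement.fit_ctmm` when ``ctmm`` is None.
    alpha : float, default 0.05
        1 - confidence level of the area interval.
    """

    name = "akde"

    def __init__(
        self,
        levels=(0.95,),
        ctmm: CTMMFit | None = None,
        model="auto",
        uere=None,
        trast=None,
        buffer="auto",
        ncol=200,
        alpha=0.05,
        keep_data=True,
    ):
        self.levels = levels
        self.ctmm = ctmm
        self.model = model
        self.uere = uere
        self.trast = trast
        self.buffer = buffer
        self.ncol = ncol
        self.alpha = alpha
        self.keep_data = keep_data

    def fit(self, X: Track, y=None):
        track = X
        track.require_projected()
        levels = _check_levels(self.levels, open_upper=True)
        fit = self.ctmm if self.ctmm is not None else fit_ctmm(track, self.model, self.uere)
        if fit.n != len(track):
            raise DomainError(
                f"movement model was fitted to {fit.n} fixes but the track has {len(track)}"
            )
        if fit.dof_area <= 1:
            raise DomainError(
                f"effective sample size {fit.dof_area:.2f} <= 1: too little "
                "independent data for a bandwidth; collect longer tracks"
            )
        trast = self.trast if self.trast is not None else make_trast(track, self.buffer, self.ncol)
        # normal-reference rule with n replaced by the effective sample size;
        # per-axis sample sd so that an uncorrelated fit reduces exactly to KDE
        sd = track.xy.std(axis=0, ddof=1)
        if np.any(sd <= 0):
            raise DomainError("zero variance on an axis; aKDE bandwidth undefined")
        h2 = sd**2 * fit.dof_area ** (-1.0 / 3.0)  # (2,)
        if fit.uere:
            hdop = track.hdop if track.hdop is not None else np.ones(len(track))
            err = (fit.uere * np.nan_to_num(hdop, nan=1.0)) ** 2 / 2.0
            hx = np.sqrt(h2[0] + err)
            hy = np.sqrt(h2[1] + err)
        else:
            hx = np.full(len(track), np.sqrt(h2[0]))
            hy = np.full(len(track), np.sqrt(h2[1]))
        ud = _gaussian_ud(track.xy, hx, hy, trast)

        iso = ud_to_isopleths(ud, levels, trast)
        nu = 2.0 * fit.dof_area
        lo_q, hi_q = chi2.ppf(1 - self.alpha / 2, nu), chi2.ppf(self.alpha / 2, nu)
        rows = []
        for _, r in iso.iterrows():
            est_area = r["area"]
            for what, q in (("estimate", None), ("lci", lo_q), ("uci", hi_q)):
                if q is None:
                    rows.append(dict(r))
                    continue
                area = est_area * nu / q
                scale = np.sqrt(area / est_area) if est_area > 0 else 1.0
                geom = _scale_about_centroid(r["geometry"], scale)
                rows.append({"level": r["level"], "what": what, "geometry": geom, "area": area})
        table = pd.DataFrame(rows).sort_values(["level", "what"], key=_what_key).reset_index(drop=True)

        self.levels_ = levels
        self.ctmm_ = fit
        self.h_ = np.column_stack([hx, hy])
        self.trast_ = trast
        self.ud_ = ud
        self.crs_ = track.crs
        self.data_ = track if self.keep_data else None
        self.isopleths_ = table
        return self


_WHAT_ORDER = {"estimate": 0, "lci": 1, "uci": 2}


def _what_key(col):
    if col.name == "what":
        return col.map(_WHAT_ORDER)
    return col


def _scale_about_centroid(geom, factor):
    """Scale a geometry about its centroid (presentation of CI bounds)."""
    if geom.is_empty:
        return geom
    c = geom.centroid
    from shapely import affinity

    return affinity.scale(geom, xfact=factor, yfact=factor, origin=(c.x, c.y))


def hr_kde(track: Track, trast=None, h="ref", levels=(0.95,), buffer="auto", ncol=200) -> Kde:
    """Kernel density home range (thin wrapper over Kde)."""
    return Kde(levels=levels, h=h, trast=trast, buffer=buffer, ncol=ncol).fit(track)


def hr_akde(
    track: Track, fit: CTMMFit | None = None, trast=None, levels=(0.95,), model="auto",
    uere=None, buffer="auto", ncol=200,
) -> Akde:
    """Autocorrelated kernel density home range (thin wrapper over Akde)."""
    return Akde(
        levels=levels, ctmm=fit, model=model, uere=uere, trast=trast, buffer=buffer, ncol=ncol
    ).fit(track)
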