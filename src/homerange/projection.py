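"""Forward map projections for the Movebank longitude/latitude dialect.

Supports the projected systems the package's examples use: the conterminous-US
Albers equal-area conic (EPSG:5070, NAD83/GRS80) and WGS84 UTM zones
(EPSG:326xx north / 327xx south). Formulas follow Snyder's *Map Projections —
A Working Manual* (USGS PP 1395); forward accuracy is sub-millimeter, which is
far below GPS error.
"""

from __future__ import annotations

import numpy as np

from .errors import CRSError

# ellipsoids: (semi-major axis a [m], inverse flattening 1/f)
_GRS80 = (6378137.0, 298.257222101)
_WGS84 = (6378137.0, 298.257223563)

#: EPSG codes the package recognizes as geographic (lon/lat degrees)
GEOGRAPHIC_EPSG = {4326, 4269, 4267, 4258}


def is_geographic(epsg: int) -> bool:
    return int(epsg) in GEOGRAPHIC_EPSG


def _q(sinphi, e):
    # authalic-latitude auxiliary (Snyder 3-12)
    return (1 - e**2) * (
        sinphi / (1 - (e * sinphi) ** 2)
        - (1 / (2 * e)) * np.log((1 - e * sinphi) / (1 + e * sinphi))
    )


def _m(phi, e):
    return np.cos(phi) / np.sqrt(1 - (e * np.sin(phi)) ** 2)


def _albers(lon, lat, a, inv_f, lat0, lon0, lat1, lat2, x0=0.0, y0=0.0):
    f = 1.0 / inv_f
    e = np.sqrt(2 * f - f * f)
    phi0, phi1, phi2 = np.radians([lat0, lat1, lat2])
    lam0 = np.radians(lon0)
    m1, m2 = _m(phi1, e), _m(phi2, e)
    q0, q1, q2 = (_q(np.sin(p), e) for p in (phi0, phi1, phi2))
    n = (m1**2 - m2**2) / (q2 - q1)
    C = m1**2 + n * q1
    rho0 = a * np.sqrt(C - n * q0) / n

    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    q = _q(np.sin(phi), e)
    rho = a * np.sqrt(C - n * q) / n
    theta = n * (lam - lam0)
    return x0 + rho * np.sin(theta), y0 + rho0 - rho * np.cos(theta)


def _transverse_mercator(lon, lat, a, inv_f, lon0, k0=0.9996, x0=500000.0, y0=0.0):
    f = 1.0 / inv_f
    e2 = 2 * f - f * f
    ep2 = e2 / (1 - e2)
    phi = np.radians(np.asarray(lat, dtype=float))
    lam = np.radians(np.asarray(lon, dtype=float))
    lam0 = np.radians(lon0)

    N = a / np.sqrt(1 - e2 * np.sin(phi) ** 2)
    T = np.tan(phi) ** 2
    C = ep2 * np.cos(phi) ** 2
    A = (lam - lam0) * np.cos(phi)
    # meridian arc (Snyder 3-21)
    M = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * np.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * np.sin(4 * phi)
        - (35 * e2**3 / 3072) * np.sin(6 * phi)
    )
    x = k0 * N * (
        A
        + (1 - T + C) * A**3 / 6
        + (5 - 18 * T + T**2 + 72 * C - 58 * ep2) * A**5 / 120
    )
    y = k0 * (
        M
        + N
        * np.tan(phi)
        * (
            A**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * A**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * ep2) * A**6 / 720
        )
    )
    return x0 + x, y0 + y


def _albers_inverse(x, y, a, inv_f, lat0, lon0, lat1, lat2, x0=0.0, y0=0.0):
    f = 1.0 / inv_f
    e = np.sqrt(2 * f - f * f)
    phi0, phi1, phi2 = np.radians([lat0, lat1, lat2])
    lam0 = np.radians(lon0)
    m1, m2 = _m(phi1, e), _m(phi2, e)
    q0, q1, q2 = (_q(np.sin(p), e) for p in (phi0, phi1, phi2))
    n = (m1**2 - m2**2) / (q2 - q1)
    C = m1**2 + n * q1
    rho0 = a * np.sqrt(C - n * q0) / n

    x = np.asarray(x, dtype=float) - x0
    yy = rho0 - (np.asarray(y, dtype=float) - y0)
    rho = np.hypot(x, yy)
    theta = np.arctan2(x, yy)
    q = (C - (rho * n / a) ** 2) / n
    phi = np.arcsin(np.clip(q / 2.0, -1.0, 1.0))
    for _ in range(8):  # Snyder 3-16 fixed point; converges to <1e-12 rad
        s = np.sin(phi)
        phi = phi + (1 - e**2 * s**2) ** 2 / (2 * np.cos(phi)) * (
            q / (1 - e**2)
            - s / (1 - e**2 * s**2)
            + (1 / (2 * e)) * np.log((1 - e * s) / (1 + e * s))
        )
    return np.degrees(lam0 + theta / n), np.degrees(phi)


def unproject(x, y, epsg: int):
    """Inverse of :func:`project` (EPSG:5070 only); returns (lon, lat) degrees."""
    if int(epsg) == 5070:
        a, inv_f = _GRS80
        return _albers_inverse(x, y, a, inv_f, lat0=23.0, lon0=-96.0, lat1=29.5, lat2=45.5)
    raise CRSError(f"inverse projection only implemented for EPSG:5070, got {epsg}")


def project(lon, lat, epsg: int):
    """Project geographic coordinates (degrees) to planar meters.

    Parameters
    ----------
    lon, lat : array-like of float
        Longitude and latitude in decimal degrees.
    epsg : int
        Target projected CRS. Supported: 5070 (CONUS Albers, NAD83) and
        WGS84 UTM zones 32601–32660 (north) / 32701–32760 (south).

    Returns
    -------
    (x, y) : tuple of ndarray
        Easting and northing in meters.
    """
    epsg = int(epsg)
    if epsg == 5070:
        a, inv_f = _GRS80
        return _albers(lon, lat, a, inv_f, lat0=23.0, lon0=-96.0, lat1=29.5, lat2=45.5)
    if 32601 <= epsg <= 32660:
        zone = epsg - 32600
        a, inv_f = _WGS84
        return _transverse_mercator(lon, lat, a, inv_f, lon0=-183.0 + 6 * zone)
    if 32701 <= epsg <= 32760:
        zone = epsg - 32700
        a, inv_f = _WGS84
        return _transverse_mercator(lon, lat, a, inv_f, lon0=-183.0 + 6 * zone, y0=10000000.0)
    raise CRSError(
        f"EPSG:{epsg} is not a supported projection target "
        "(supported: 5070, 326xx/327xx UTM)"
    )
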