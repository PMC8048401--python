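"""Simulators and fixtures: OU/OUF/IID tracks, GPS error, toy landscapes.

Everything every other module needs for testing without downloads: exact
stationary samplers for the three movement models, HDOP-scaled location
error, a patchy binary landscape, and a multi-animal fixture suite that
stands in for a real multi-animal GPS study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import projection
from .errors import DomainError
from .movement import ouf_stationary_cov, ouf_transition
from .raster import TemplateRaster, write_raster
from .tracks import Track, write_tracks

__all__ = ["SimSpec", "simulate_track", "make_toy_landscape", "make_fixture_suite"]

_T0 = pd.Timestamp("2011-01-01 00:00:00", tz="UTC")


@dataclass
class SimSpec:
    """Specification of a simulated track.

    Attributes
    ----------
    model : {"iid", "ou", "ouf"}
    mu : (2,) mean location (m)
    sigma2 : stationary positional variance per axis (m²)
    tau_pos, tau_vel : autocorrelation timescales (s) where applicable
    dt : sampling interval (s)
    n : number of fixes
    uere : GPS error scale (m 2-D RMS per unit HDOP); None/0 = no error
    hdop_law : ("constant", value) or ("lognormal", meanlog, sdlog)
    seed : integer seed; same seed, same track
    """

    model: str = "ou"
    mu: tuple = (0.0, 0.0)
    sigma2: float = 1e6
    tau_pos: float | None = 3600.0
    tau_vel: float | None = None
    dt: float = 600.0
    n: int = 1000
    uere: float | None = None
    hdop_law: tuple = ("constant", 1.0)
    seed: int = 0
    id: str = "sim"
    crs: int = 5070
    t0: pd.Timestamp = field(default_factory=lambda: _T0)

    def validate(self):
        if self.model not in ("iid", "ou", "ouf"):
            raise DomainError(f"unknown model {self.model!r}")
        if self.sigma2 <= 0 or self.dt <= 0 or self.n < 1:
            raise DomainError("sigma2, dt and n must be positive")
        if self.model in ("ou", "ouf") and (self.tau_pos is None or self.tau_pos <= 0):
            raise DomainError(f"{self.model} requires tau_pos > 0")
        if self.model == "ouf":
            if self.tau_vel is None or self.tau_vel <= 0 or self.tau_vel >= self.tau_pos:
                raise DomainError("ouf requires 0 < tau_vel < tau_pos")
        if self.uere is not None and self.uere < 0:
            raise DomainError("uere must be nonnegative")


def _draw_hdop(rng, law, n):
    kind = law[0]
    if kind == "constant":
        return np.full(n, float(law[1]))
    if kind == "lognormal":
        return rng.lognormal(mean=law[1], sigma=law[2], size=n)
    raise DomainError(f"unknown hdop law {kind!r}")


def simulate_track(spec: SimSpec) -> Track:
    """Exact stationary sample of the specified movement model.

    OU uses the exact AR(1) discretization (phi = exp(-dt/tau_pos), stationary
    start); OUF the exact position–velocity state-space discretization, so
    the simulated position autocovariance matches the analytic form with no
    time-stepping error. Location error, when requested, adds independent
    per-axis noise with variance (uere * hdop)² / 2.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, mu = spec.n, np.asarray(spec.mu, dtype=float)
    sd = np.sqrt(spec.sigma2)

    if spec.model == "iid":
        xy = mu + rng.standard_normal((n, 2)) * sd
    elif spec.model == "ou":
        phi = np.exp(-spec.dt / spec.tau_pos)
        innov_sd = sd * np.sqrt(1.0 - phi * phi)
        z = np.empty((n, 2))
        z[0] = rng.standard_normal(2) * sd
        eps = rng.standard_normal((n - 1, 2)) * innov_sd if n > 1 else None
        for k in range(1, n):
            z[k] = phi * z[k - 1] + eps[k - 1]
        xy = mu + z
    else:  # ouf
        pinf = ouf_stationary_cov(spec.sigma2, spec.tau_pos, spec.tau_vel)
        phi, q = ouf_transition(spec.dt, spec.sigma2, spec.tau_pos, spec.tau_vel)
        l_inf = np.linalg.cholesky(pinf)
        # q is positive semi-definite; tiny jitter guards the factorization
        l_q = np.linalg.cholesky(q + 1e-12 * np.trace(q) * np.eye(2))
        state = l_inf @ rng.standard_normal((2, 2))  # (pos, vel) x (x, y)
        z = np.empty((n, 2))
        z[0] = state[0]
        for k in range(1, n):
            state = phi @ state + l_q @ rng.standard_normal((2, 2))
            z[k] = state[0]
        xy = mu + z

    hdop = _draw_hdop(rng, spec.hdop_law, n)
    if spec.uere:
        err_sd = spec.uere * hdop / np.sqrt(2.0)
        xy = xy + rng.standard_normal((n, 2)) * err_sd[:, None]

    t = spec.t0 + pd.to_timedelta(np.arange(n) * spec.dt, unit="s")
    return Track(
        x=xy[:, 0], y=xy[:, 1], t=pd.DatetimeIndex(t), id=spec.id, crs=spec.crs, hdop=hdop
    )


def make_toy_landscape(
    extent=(0.0, 10000.0, 0.0, 10000.0),
    ncol: int = 200,
    forest_fraction: float = 0.5,
    patch_scale: float = 5.0,
    seed: int = 0,
    crs: int = 5070,
) -> tuple[np.ndarray, TemplateRaster]:
    """Patchy binary landscape: thresholded smoothed noise.

    White noise is smoothed with a Gaussian of ``patch_scale`` cells and
    thresholded at the (1 - forest_fraction) quantile, so the realized
    forest fraction matches the target up to grid rounding (well within
    0.02 for a 200-column grid).
    """
    if not 0.0 <= forest_fraction <= 1.0:
        raise DomainError("forest_fraction must be in [0, 1]")
    xmin, xmax, ymin, ymax = extent
    trast = TemplateRaster.from_extent(xmin, xmax, ymin, ymax, ncol=ncol, crs=crs)
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.standard_normal(trast.shape), sigma=patch_scale)
    if forest_fraction == 1.0:
        return np.ones(trast.shape), trast
    if forest_fraction == 0.0:
        return np.zeros(trast.shape), trast
    cut = np.quantile(noise, 1.0 - forest_fraction)
    return (noise > cut).astype(float), trast


# fisher-like study site: the projected extent the bundled examples use
_SITE_CENTER_5070 = (1783000.0, 2405000.0)


def make_fixture_suite(
    out_dir,
    n_animals: int = 6,
    weeks: int = 10,
    dt: float = 3600.0,
    uere: float = 1.67,
    seed: int = 7,
) -> dict:
    """Write a no-download stand-in for a multi-animal GPS study.

    Simulates a 6-animal, two-sex population of range-resident (OU) movers:
    per-animal sigma2 and tau_pos drawn from seeded log-normal laws around
    typical mustelid-scale values (sigma2 ~ 0.5 km² positional variance,
    tau ~ hours), hourly fixes over ``weeks`` weeks, log-normal HDOP, and
    HDOP-scaled location error with the given uere. Writes the population in
    both CSV dialects plus a patchy forest landscape, and returns a manifest
    (also written as JSON) with per-animal parameters and file names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n = int(weeks * 7 * 24 * 3600 / dt)
    cx, cy = _SITE_CENTER_5070

    animals = []
    tables = []
    for a in range(n_animals):
        sex = "F" if a < n_animals // 2 else "M"
        label = f"{sex}{a % (n_animals // 2) + 1}"
        sigma2 = float(rng.lognormal(np.log(5e5), 0.4))
        if sex == "M":
            sigma2 *= 2.0  # males range wider, a common mammalian pattern
        tau = float(rng.lognormal(np.log(4 * 3600.0), 0.3))
        mu = (cx + rng.uniform(-4000, 4000), cy + rng.uniform(-4000, 4000))
        spec = SimSpec(
            model="ou",
            mu=mu,
            sigma2=sigma2,
            tau_pos=tau,
            dt=dt,
            n=n,
            uere=uere,
            hdop_law=("lognormal", np.log(2.0), 0.5),
            seed=int(rng.integers(0, 2**31 - 1)),
            id=label,
        )
        track = simulate_track(spec)
        df = track.to_dataframe()
        df.insert(1, "sex", sex)
        tables.append(df)
        animals.append(
            {"id": label, "sex": sex, "sigma2": sigma2, "tau_pos": tau,
             "mu": [float(mu[0]), float(mu[1])], "n": n, "seed": spec.seed}
        )

    pop = pd.concat(tables, ignore_index=True)
    generic = out / "population_generic.csv"
    write_tracks(pop[["id", "x", "y", "t", "hdop"]], generic)

    lon, lat = projection.unproject(pop["x"].to_numpy(), pop["y"].to_numpy(), 5070)
    movebank = out / "population_movebank.csv"
    pd.DataFrame(
        {
            "individual-local-identifier": pop["id"],
            "location-long": lon,
            "location-lat": lat,
            "timestamp": pd.DatetimeIndex(pop["t"]).strftime("%Y-%m-%d %H:%M:%S.%f"),
            "gps:dop": pop["hdop"],
        }
    ).to_csv(movebank, index=False, float_format="%.10f")

    pad = 3000.0
    extent = (
        float(pop["x"].min() - pad),
        float(pop["x"].max() + pad),
        float(pop["y"].min() - pad),
        float(pop["y"].max() + pad),
    )
    forest, trast = make_toy_landscape(
        extent, ncol=200, forest_fraction=0.55, patch_scale=6.0, seed=seed + 1
    )
    write_raster(forest, trast, out / "forest.asc")
    write_raster(forest, trast, out / "forest.tif")

    manifest = {
        "seed": seed,
        "uere": uere,
        "dt": dt,
        "weeks": weeks,
        "animals": animals,
        "files": {
            "generic_csv": generic.name,
            "movebank_csv": movebank.name,
            "forest_asc": "forest.asc",
            "forest_tif": "forest.tif",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
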