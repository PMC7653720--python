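"""Ornstein--Uhlenbeck movement models and autocorrelation-corrected
kernel density home ranges.

The stationary OU process is the simplest continuous-time movement model
with a finite home range: positions revert to a centre mu with
covariance Sigma and exponentially decaying autocorrelation
Cov(x_t, x_s) = Sigma * exp(-|t-s|/tau). Its exact Gaussian likelihood
over irregularly spaced fixes factorises through a forward recursion
(each fix conditioned on the previous one), and both mu and Sigma have
closed-form profile estimates, leaving a one-dimensional search over
tau.

The home-range density is a Gaussian kernel density estimate whose
bandwidth uses the *effective* sample size n_eff = tracking span / tau
instead of the raw fix count — the essential autocorrelation correction:
strongly autocorrelated tracks carry fewer independent looks at the
range and therefore get more smoothing. Isopleths are highest-density
regions containing 25/50/75/95% of the probability mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from skimage import measure

from .geo import AzimuthalEquidistant

log = logging.getLogger(__name__)

ISOPLETH_LEVELS = (0.25, 0.50, 0.75, 0.95)


class OUFitError(Exception):
    pass


@dataclass
class MovementModelFit:
    """ML fit of the stationary 2-D OU process to one bird's track."""

    bird_id: str
    mu: np.ndarray               # home-range centre, km in the local plane
    Sigma: np.ndarray            # 2x2 positional covariance, km^2
    tau_pos: float               # positional autocorrelation timescale, h
    loglik: float
    n_eff: float                 # effective number of independent fixes
    n: int
    proj: AzimuthalEquidistant = field(repr=False, default=None)
    times_h: np.ndarray = field(repr=False, default=None)
    xy: np.ndarray = field(repr=False, default=None)


def _profile_pieces(xy: np.ndarray, dt: np.ndarray, tau: float):
    """Profile mu and Sigma out of the OU likelihood at fixed tau.

    Returns (mu, Sigma, loglik). Terms: x_1 ~ N(mu, Sigma) and
    x_{i+1} | x_i ~ N(mu + rho_i (x_i - mu), Sigma (1 - rho_i^2)).
    """
    n = len(xy)
    rho = np.exp(-dt / tau)
    # z_i = x_{i+1} - rho_i x_i = a_i mu + e_i,  Var(e_i) = Sigma v_i
    a = np.concatenate([[1.0], 1.0 - rho])
    v = np.concatenate([[1.0], 1.0 - rho**2])
    z = np.vstack([xy[0], xy[1:] - rho[:, None] * xy[:-1]])
    w = a / v
    mu = (w[:, None] * z).sum(axis=0) / (a * w).sum()
    r = z - a[:, None] * mu
    S = (r[:, :, None] * r[:, None, :] / v[:, None, None]).sum(axis=0) / n
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0:
        return mu, S, -np.inf
    ll = -0.5 * (2 * n * np.log(2 * np.pi) + n * logdetS
                 + 2.0 * np.log(v).sum() + 2 * n)
    return mu, S, ll


def fit_ou(traj: pd.DataFrame | np.ndarray, times_h=None,
           bird_id: str = "", proj: AzimuthalEquidistant | None = None
           ) -> MovementModelFit:
    """Fit the stationary OU model by maximum likelihood.

    Accepts either a trajectory DataFrame (bird_id, timestamp, lon, lat;
    projected internally onto a local azimuthal-equidistant plane centred
    on the track mean) or an (n, 2) array of plane coordinates in km with
    ``times_h`` in hours.
    """
    if isinstance(traj, pd.DataFrame):
        if not bird_id and "bird_id" in traj.columns:
            bird_id = str(traj["bird_id"].iloc[0])
        ts = pd.to_datetime(traj["timestamp"])
        times_h = ((ts - ts.iloc[0]) / pd.Timedelta(hours=1)).to_numpy()
        lon = traj["lon"].to_numpy(dtype=float)
        lat = traj["lat"].to_numpy(dtype=float)
        proj = proj or AzimuthalEquidistant(lon.mean(), lat.mean())
        x, y = proj.forward(lon, lat)
        xy = np.column_stack([x, y])
    else:
        xy = np.asarray(traj, dtype=float)
        times_h = np.asarray(times_h, dtype=float)
    if len(xy) < 50:
        raise OUFitError(f"need >= 50 fixes to fit the OU model "
                         f"(got {len(xy)})")
    order = np.argsort(times_h)
    xy, times_h = xy[order], times_h[order]
    keep = np.concatenate([[True], np.diff(times_h) > 0])
    xy, times_h = xy[keep], times_h[keep]
    dt = np.diff(times_h)
    span = times_h[-1] - times_h[0]

    def nll(log_tau):
        return -_profile_pieces(xy, dt, np.exp(log_tau))[2]

    lo, hi = np.log(dt.min() / 10.0), np.log(span * 10.0)
    # coarse grid then local refine: the profile can be multimodal
    grid = np.linspace(lo, hi, 40)
    vals = [nll(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = optimize.minimize_scalar(
        nll, bounds=(max(lo, g0 - 1.5), min(hi, g0 + 1.5)),
        method="bounded", options={"xatol": 1e-6})
    if not np.isfinite(res.fun):
        prof = pd.DataFrame({"log_tau": grid, "nll": vals})
        raise OUFitError(f"OU likelihood did not converge for {bird_id!r}; "
                         f"profile:\n{prof}")
    tau = float(np.exp(res.x))
    mu, Sigma, ll = _profile_pieces(xy, dt, tau)
    n_eff = float(np.clip(span / tau, 1.0, len(xy)))
    return MovementModelFit(bird_id=bird_id, mu=mu, Sigma=Sigma,
                            tau_pos=tau, loglik=float(ll), n_eff=n_eff,
                            n=len(xy), proj=proj, times_h=times_h, xy=xy)


def simulate_ou(mu, Sigma, tau, times_h, rng) -> np.ndarray:
    """Simulate a stationary OU track at the given (sorted) times."""
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    L = np.linalg.cholesky(Sigma)
    times_h = np.asarray(times_h, dtype=float)
    n = len(times_h)
    xy = np.empty((n, 2))
    xy[0] = mu + L @ rng.standard_normal(2)
    rho = np.exp(-np.diff(times_h) / tau)
    for i in range(1, n):
        s = np.sqrt(1.0 - rho[i - 1] ** 2)
        xy[i] = mu + rho[i - 1] * (xy[i - 1] - mu) \
            + s * (L @ rng.standard_normal(2))
    return xy


# ---------------------------------------------------------------------------
# AKDE


@dataclass
class HomeRange:
    """Kernel home-range density on a regular grid, with isopleths."""

    bird_id: str
    x: np.ndarray                # grid cell centres, km (nx,)
    y: np.ndarray                # (ny,)
    density: np.ndarray          # (ny, nx), integrates to 1
    bandwidth: np.ndarray        # 2x2 H, km^2
    n_eff: float
    proj: AzimuthalEquidistant = field(repr=False, default=None)
    isopleths: dict = field(default_factory=dict)
    # per level: {"level": density threshold, "area_km2": ..., "polygons": ...}

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def isopleth_area(self, frac: float) -> float:
        return self.isopleths[frac]["area_km2"]


def _hdr_threshold(density: np.ndarray, cell_area: float, frac: float):
    """Smallest density bound whose superlevel set holds >= frac mass."""
    d = np.sort(density.ravel())[::-1]
    csum = np.cumsum(d) * cell_area
    k = int(np.searchsorted(csum, frac))
    k = min(k, len(d) - 1)
    return float(d[k])


def akde(fit: MovementModelFit, cell_km: float = 0.5,
         levels: tuple[float, ...] = ISOPLETH_LEVELS,
         max_cells: int = 4000) -> HomeRange:
    """Autocorrelation-corrected Gaussian kernel home range.

    Bandwidth H = Sigma_hat * n_eff^(-1/3): the bivariate Gaussian
    reference rule evaluated at the effective (not nominal) sample size,
    so autocorrelated tracks are smoothed more.
    """
    xy = fit.xy
    H = fit.Sigma * fit.n_eff ** (-1.0 / 3.0)
    evals = np.linalg.eigvalsh(H)
    pad = 3.5 * np.sqrt(evals.max())
    x0, x1 = xy[:, 0].min() - pad, xy[:, 0].max() + pad
    y0, y1 = xy[:, 1].min() - pad, xy[:, 1].max() + pad
    nx, ny = int(np.ceil((x1 - x0) / cell_km)), int(np.ceil((y1 - y0) / cell_km))
    if max(nx, ny) > max_cells:
        scale = max(nx, ny) / max_cells
        cell_km *= scale
        nx, ny = int(np.ceil((x1 - x0) / cell_km)), int(np.ceil((y1 - y0) / cell_km))
        log.warning("AKDE grid overflow; coarsened cells to %.3f km", cell_km)
    gx = x0 + (np.arange(nx) + 0.5) * cell_km
    gy = y0 + (np.arange(ny) + 0.5) * cell_km

    Hinv = linalg.inv(H)
    norm = 1.0 / (2 * np.pi * np.sqrt(linalg.det(H)))
    dens = np.zeros((ny, nx))
    XX, YY = np.meshgrid(gx, gy)
    # chunk over fixes to bound memory
    for i0 in range(0, len(xy), 256):
        chunk = xy[i0:i0 + 256]
        dx = XX[None, :, :] - chunk[:, 0, None, None]
        dy = YY[None, :, :] - chunk[:, 1, None, None]
        quad = (Hinv[0, 0] * dx**2 + 2 * Hinv[0, 1] * dx * dy
                + Hinv[1, 1] * dy**2)
        dens += norm * np.exp(-0.5 * quad).sum(axis=0)
    dens /= len(xy)
    cell_area = cell_km * cell_km
    dens /= dens.sum() * cell_area   # exact discrete normalisation

    iso = {}
    for frac in levels:
        thr = _hdr_threshold(dens, cell_area, frac)
        area = float((dens >= thr).sum()) * cell_area
        polys = []
        for cont in measure.find_contours(dens, thr):
            px = x0 + (cont[:, 1] + 0.5) * cell_km
            py = y0 + (cont[:, 0] + 0.5) * cell_km
            if fit.proj is not None:
                lon, lat = fit.proj.inverse(px, py)
                polys.append(np.column_stack([lon, lat]))
            else:
                polys.append(np.column_stack([px, py]))
        iso[frac] = {"level": thr, "area_km2": area, "polygons": polys}
    return HomeRange(bird_id=fit.bird_id, x=gx, y=gy, density=dens,
                     bandwidth=H, n_eff=fit.n_eff, proj=fit.proj,
                     isopleths=iso)


def isopleths_geojson(hr: HomeRange) -> dict:
    """Isopleth contours as a GeoJSON FeatureCollection (lon/lat)."""
    feats = []
    for frac, d in hr.isopleths.items():
        for ring in d["polygons"]:
            ring = np.asarray(ring)
            if not np.allclose(ring[0], ring[-1]):
                ring = np.vstack([ring, ring[:1]])
            feats.append({
                "type": "Feature",
                "properties": {"bird_id": hr.bird_id, "isopleth": frac,
                               "area_km2": d["area_km2"]},
                "geometry": {"type": "Polygon",
                             "coordinates": [ring.tolist()]},
            })
    return {"type": "FeatureCollection", "features": feats}
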