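"""Pairwise distances between areal units and Gaussian distance-decay weights.

Geographically weighted regression calibrates one local model per sampled
location, down-weighting observations by their distance to the calibration
point.  This module computes the N x N distance matrix D and turns it into
kernel weights

    w_ij = exp(-1/2 (d_ij / theta)^2)

where ``theta`` is the bandwidth: small theta makes the fit local, large
theta approaches a single global model.  The 1/2 convention follows the
standard Gaussian GWR kernel; the variant without the 1/2 factor differs
only by a sqrt(2) rescaling of theta and is available via ``half=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics.pairwise import haversine_distances

from .exceptions import InputError, ParameterError

EARTH_RADIUS_KM = 6371.0088

_METRICS = ("euclidean", "manhattan", "minkowski", "haversine")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with the metric recorded."""

    D: np.ndarray
    metric: str
    minkowski_power: float | None = None

    @property
    def n(self) -> int:
        return self.D.shape[0]


@dataclass(frozen=True)
class KernelWeights:
    """Gaussian kernel weight matrix W with entries in (0, 1]."""

    W: np.ndarray
    theta: float
    half: bool = True
    cutoff: float = 0.0


def _validate_coords(coords: np.ndarray, crs_mode: str) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InputError(f"coordinates must be an (N, 2) array, got {coords.shape}")
    if coords.shape[0] < 2:
        raise InputError("need at least 2 locations")
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        rows = np.flatnonzero(bad)
        raise InputError(f"non-finite coordinates at rows {rows.tolist()}")
    if crs_mode == "spherical":
        lon, lat = coords[:, 0], coords[:, 1]
        if (np.abs(lon) > 180).any() or (np.abs(lat) > 90).any():
            raise InputError("spherical coordinates require lon in [-180, 180], lat in [-90, 90]")
    return coords


def pairwise_distances(
    coords: np.ndarray,
    metric: str = "euclidean",
    minkowski_power: float = 2.0,
    crs_mode: str = "planar",
) -> DistanceMatrix:
    """Compute the N x N matrix of pairwise distances between unit coordinates.

    Parameters
    ----------
    coords
        (N, 2) array of x/y (planar) or lon/lat (spherical) coordinates.
    metric
        One of ``euclidean``, ``manhattan``, ``minkowski`` (with
        ``minkowski_power`` >= 1) or ``haversine`` (great-circle km;
        requires ``crs_mode='spherical'``).
    """
    if metric not in _METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {_METRICS}")
    coords = _validate_coords(coords, crs_mode)
    if metric == "haversine":
        if crs_mode != "spherical":
            raise ParameterError("haversine distances require crs_mode='spherical' (lon/lat)")
        latlon = np.radians(coords[:, ::-1])  # haversine expects (lat, lon)
        D = haversine_distances(latlon) * EARTH_RADIUS_KM
        power: float | None = None
    elif metric == "minkowski":
        if not np.isfinite(minkowski_power) or minkowski_power < 1:
            raise ParameterError(f"minkowski_power must be >= 1, got {minkowski_power}")
        D = cdist(coords, coords, metric="minkowski", p=minkowski_power)
        power = float(minkowski_power)
    else:
        D = cdist(coords, coords, metric="cityblock" if metric == "manhattan" else metric)
        power = None
    # enforce exact symmetry / zero diagonal against rounding
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(D=D, metric=metric, minkowski_power=power)


def kernel_weights(
    D: DistanceMatrix | np.ndarray,
    theta: float,
    half: bool = True,
    cutoff: float = 0.0,
) -> KernelWeights:
    """Gaussian distance-decay weights w_ij = exp(-1/2 (d_ij/theta)^2).

    ``half=False`` drops the 1/2 factor (equivalent to rescaling theta by
    sqrt(2)).  ``cutoff`` optionally zeroes weights below a threshold
    (default 0, i.e. the kernel keeps its unbounded support).
    """
    if not np.isfinite(theta) or theta <= 0:
        raise ParameterError(f"bandwidth theta must be positive, got {theta}")
    if cutoff < 0:
        raise ParameterError("cutoff must be nonnegative")
    d = D.D if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    scale = 0.5 if half else 1.0
    W = np.exp(-scale * (d / theta) ** 2)
    np.fill_diagonal(W, 1.0)
    if cutoff > 0:
        W = np.where(W < cutoff, 0.0, W)
        np.fill_diagonal(W, 1.0)
    return KernelWeights(W=W, theta=float(theta), half=half, cutoff=cutoff)
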