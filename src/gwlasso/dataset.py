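"""The in-memory container for an areal-unit dataset.

Holds unit identifiers, 2-D coordinates, raw and standardized covariates,
the binary outcome, and the optional continuous rates and household counts
used for index calibration and validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError


@dataclass
class SpatialDataset:
    """N areal units with coordinates, covariates and a binary outcome.

    ``X`` holds the standardized covariates actually used in model fitting;
    ``X_raw`` the original values, with the per-column ``x_mean``/``x_sd``
    needed to round-trip.  ``rates`` and ``households`` are optional.
    """

    unit_id: np.ndarray
    coords: np.ndarray
    X: np.ndarray
    y: np.ndarray
    covariate_names: list[str]
    X_raw: np.ndarray | None = None
    x_mean: np.ndarray | None = None
    x_sd: np.ndarray | None = None
    rates: np.ndarray | None = None
    households: np.ndarray | None = None
    crs_mode: str = "planar"

    def __post_init__(self):
        self.unit_id = np.asarray(self.unit_id)
        self.coords = np.asarray(self.coords, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.unit_id)
        if len(np.unique(self.unit_id)) != n:
            raise InputError("duplicated unit_id")
        if self.coords.shape != (n, 2):
            raise InputError(f"coords must be ({n}, 2), got {self.coords.shape}")
        if self.X.shape[0] != n or self.y.shape != (n,):
            raise InputError("X/y shapes inconsistent with unit count")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise InputError("y must be binary in {0, 1}")
        if len(self.covariate_names) != self.X.shape[1]:
            raise InputError("covariate_names length must match X columns")
        if self.households is not None:
            self.households = np.asarray(self.households, dtype=float)
            if (self.households <= 0).any():
                raise InputError("households must be positive where present")
        if self.rates is not None:
            self.rates = np.asarray(self.rates, dtype=float)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]
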