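"""CSV/JSON/GeoJSON readers and writers.

All outputs are written atomically (temp file in the destination
directory, then rename) so a failed run never leaves a truncated file.
Coefficient CSVs use full-precision repr formatting and round-trip the
coefficient field exactly; human-facing reports use 6 significant digits.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import SpatialDataset
from .estimation import CoefficientField, CVGrid
from .exceptions import ConfigError, InputError
from .index import IndexResult, binarize_by_median, standardize


@contextmanager
def _atomic_write(path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c is not None and c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing mapped column(s) {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = {}
    for c in cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise InputError(f"{path}: non-numeric value {df[c].iloc[row]!r} "
                             f"in column {c!r}, data row {row}")
        out[c] = converted
    return pd.DataFrame(out)


def read_dataset(
    path,
    id_col: str = "id",
    x_col: str = "x",
    y_col: str = "y",
    outcome_col: str | None = None,
    rate_col: str | None = None,
    households_col: str | None = None,
    covariate_cols: list[str] | None = None,
    threshold: float | None = None,
    crs_mode: str = "planar",
) -> SpatialDataset:
    """Read an areal-unit dataset from a delimited text file.

    Exactly one of ``outcome_col`` (already binary) or ``rate_col``
    (continuous, binarized at the median or at ``threshold``) must be
    given.  ``covariate_cols`` defaults to every remaining numeric column.
    Covariates are standardized; rows with missing values in any used
    column are rejected with a row-numbered report.
    """
    if (outcome_col is None) == (rate_col is None):
        raise ConfigError("specify exactly one of outcome_col / rate_col")
    df = pd.read_csv(path)
    roles = [id_col, x_col, y_col, outcome_col, rate_col, households_col]
    _require_columns(df, roles, path)
    assigned = [c for c in roles if c is not None]
    if len(set(assigned)) != len(assigned):
        raise ConfigError(f"column roles must be disjoint, got {assigned}")
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in assigned]
    else:
        _require_columns(df, covariate_cols, path)
        overlap = set(covariate_cols) & set(assigned)
        if overlap:
            raise ConfigError(f"covariate columns overlap other roles: {sorted(overlap)}")
    if not covariate_cols:
        raise ConfigError(f"{path}: no covariate columns")

    used = assigned + list(covariate_cols)
    na = df[used].isna().any(axis=1)
    if na.any():
        rows = np.flatnonzero(na).tolist()
        raise InputError(f"{path}: missing values in used columns at data rows {rows}")

    num_cols = [x_col, y_col] + ([outcome_col] if outcome_col else [rate_col]) \
        + ([households_col] if households_col else []) + list(covariate_cols)
    num = _numeric(df, num_cols, path)

    X_raw = num[list(covariate_cols)].to_numpy(float)
    X, mean, sd = standardize(X_raw, list(covariate_cols))
    rates = None
    if rate_col is not None:
        rates = num[rate_col].to_numpy(float)
        y = binarize_by_median(rates, threshold)
    else:
        y = num[outcome_col].to_numpy(float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise InputError(f"{path}: outcome column {outcome_col!r} is not binary")
    return SpatialDataset(
        unit_id=df[id_col].to_numpy(),
        coords=num[[x_col, y_col]].to_numpy(float),
        X=X, y=y, covariate_names=list(covariate_cols),
        X_raw=X_raw, x_mean=mean, x_sd=sd, rates=rates,
        households=num[households_col].to_numpy(float) if households_col else None,
        crs_mode=crs_mode)


def write_dataset(dataset: SpatialDataset, path) -> None:
    """Write a dataset back to CSV (id, x, y, outcome, optional extras, raw covariates)."""
    df = pd.DataFrame({"id": dataset.unit_id,
                       "x": dataset.coords[:, 0], "y": dataset.coords[:, 1],
                       "outcome": dataset.y.astype(int)})
    if dataset.rates is not None:
        df["rate"] = dataset.rates
    if dataset.households is not None:
        df["households"] = dataset.households
    X = dataset.X_raw if dataset.X_raw is not None else dataset.X
    for k, name in enumerate(dataset.covariate_names):
        df[name] = X[:, k]
    with _atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def write_coefficients(field: CoefficientField, path) -> None:
    """Coefficient CSV: unit_id, intercept, one full-precision column per covariate."""
    names = field.covariate_names or [f"x{k + 1}" for k in range(field.B.shape[1] - 1)]
    ids = field.unit_id if field.unit_id is not None else np.arange(field.B.shape[0])
    df = pd.DataFrame(field.B, columns=["intercept"] + list(names))
    df.insert(0, "unit_id", ids)
    df["converged"] = field.converged.astype(int)
    df["degenerate"] = field.degenerate.astype(int)
    with _atomic_write(path) as fh:
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def read_coefficients(path) -> CoefficientField:
    """Inverse of :func:`write_coefficients` (theta/lambda live in run metadata)."""
    df = pd.read_csv(path)
    for col in ("unit_id", "intercept"):
        if col not in df.columns:
            raise InputError(f"{path}: missing column {col!r}")
    flags = [c for c in ("converged", "degenerate") if c in df.columns]
    names = [c for c in df.columns if c not in ("unit_id", *flags)]
    B = df[names].to_numpy(float)
    n = B.shape[0]
    return CoefficientField(
        B=B, theta=np.nan, lam=np.nan, alpha=np.nan,
        converged=df["converged"].to_numpy(bool) if "converged" in flags else np.ones(n, bool),
        degenerate=df["degenerate"].to_numpy(bool) if "degenerate" in flags else np.zeros(n, bool),
        unit_id=df["unit_id"].to_numpy(), covariate_names=names[1:])


def write_cv_grid(cv: CVGrid, path) -> None:
    """Long-format CV surface: theta, lambda, criterion, n_evaluated."""
    rows = [(th, lm, cv.criterion[s, t], int(cv.n_evaluated[s, t]))
            for s, th in enumerate(cv.theta_candidates)
            for t, lm in enumerate(cv.lambda_candidates)]
    df = pd.DataFrame(rows, columns=["theta", "lambda", cv.criterion_name, "n_evaluated"])
    with _atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def write_index(result: IndexResult, unit_id, path) -> None:
    df = pd.DataFrame({"unit_id": unit_id, "raw": result.raw, "ind": result.ind})
    with _atomic_write(path) as fh:
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def write_clusters(row_labels, col_labels, unit_ids, covariate_names, path) -> None:
    df = pd.DataFrame({
        "kind": ["row"] * len(row_labels) + ["col"] * len(col_labels),
        "name": list(unit_ids) + list(covariate_names),
        "cluster": list(map(int, row_labels)) + list(map(int, col_labels))})
    with _atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def write_geojson(dataset: SpatialDataset, values: dict[str, np.ndarray], path) -> None:
    """Point FeatureCollection with one feature per unit and given properties."""
    features = []
    for i in range(dataset.n):
        props = {"unit_id": str(dataset.unit_id[i])}
        for name, vec in values.items():
            props[name] = float(vec[i])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(dataset.coords[i, 0]),
                                         float(dataset.coords[i, 1])]},
            "properties": props})
    with _atomic_write(path) as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_metadata(meta: dict, path) -> None:
    """JSON run metadata: config echo, selected hyperparameters, version."""
    from . import __version__

    meta = dict(meta)
    meta.setdefault("gwlasso_version", __version__)
    with _atomic_write(path) as fh:
        json.dump(meta, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
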