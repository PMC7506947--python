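"""The four throwing-speed prediction models.

All four are ordinary multivariable linear regressions of release speed
(m/s) on subsets of {log peak total acceleration, sex, throw type}:

* Base: speed ~ log(peak acceleration)
* Sex:  speed ~ log(peak acceleration) + sex
* Type: speed ~ log(peak acceleration) + throw type
* Full: speed ~ log(peak acceleration) + sex + throw type

Categorical predictors use treatment coding with reference levels female
(sex) and jump throw (type), so coefficients read as offsets from a female
jump throw. ``published_model`` returns any of the four pre-loaded with the
published point estimates and 95% CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, FittingError
from .synthdata import THROW_TYPES

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "FittedModel",
    "model_spec",
    "build_design_matrix",
    "fit_model",
    "predict",
    "published_model",
    "write_model",
    "read_model",
]

MODEL_NAMES = ("Base", "Sex", "Type", "Full")
SEX_LEVELS = ("female", "male")
TYPE_REFERENCE = "jump"  # reference category of the type predictor
#: Non-reference type levels in design-matrix column order.
TYPE_DUMMY_LEVELS = tuple(t for t in THROW_TYPES if t != TYPE_REFERENCE)

_PREDICTOR_SETS = {
    "Base": ("log_peak_accel",),
    "Sex": ("log_peak_accel", "sex"),
    "Type": ("log_peak_accel", "throw_type"),
    "Full": ("log_peak_accel", "sex", "throw_type"),
}


@dataclass(frozen=True)
class ModelSpec:
    name: str
    predictors: tuple

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise DataError(f"unknown model name {self.name!r}")
        if tuple(self.predictors) != _PREDICTOR_SETS[self.name]:
            raise DataError(
                f"model {self.name} must use predictors {_PREDICTOR_SETS[self.name]}"
            )

    @property
    def columns(self) -> tuple:
        cols = ["intercept", "log_peak_accel"]
        if "sex" in self.predictors:
            cols.append("sex_male")
        if "throw_type" in self.predictors:
            cols.extend(f"type_{t}" for t in TYPE_DUMMY_LEVELS)
        return tuple(cols)


def model_spec(name: str) -> ModelSpec:
    if name not in _PREDICTOR_SETS:
        raise DataError(
            f"unknown model name {name!r}; expected one of {MODEL_NAMES}"
        )
    return ModelSpec(name, _PREDICTOR_SETS[name])


@dataclass(frozen=True)
class FittedModel:
    """A fitted (or published) model: point estimates plus 95% CIs.

    ``params`` and ``conf_int`` are indexed by design-matrix column names;
    reference levels are female sex and jump throw.
    """

    spec: ModelSpec
    params: pd.Series
    conf_int: pd.DataFrame  # columns ci_low, ci_high
    nobs: int = 0

    def __post_init__(self):
        if tuple(self.params.index) != self.spec.columns:
            raise FittingError(
                f"coefficients {tuple(self.params.index)} do not match the "
                f"{self.spec.name} design columns {self.spec.columns}"
            )
        inside = (self.conf_int["ci_low"] <= self.params) & (
            self.params <= self.conf_int["ci_high"]
        )
        if not bool(inside.all()):
            raise FittingError("confidence intervals must contain their estimates")

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return predict(self, rows)


def build_design_matrix(
    rows: pd.DataFrame, spec: ModelSpec, require_response: bool = True
):
    """Design matrix (with intercept and treatment-coded dummies) + response.

    Column order is fixed: intercept, log_peak_accel, sex_male, then type
    dummies in protocol order (low, medium, maximal standing, standing with
    run-up) against the jump-throw reference.
    """
    if len(rows) == 0:
        raise DataError("no feature rows")
    needed = set(spec.predictors) | (
        {"observed_speed_mps"} if require_response else set()
    )
    missing = needed - set(rows.columns)
    if missing:
        raise DataError(f"feature rows missing columns {sorted(missing)}")

    X = pd.DataFrame(index=rows.index)
    X["intercept"] = 1.0
    log_peak = rows["log_peak_accel"].to_numpy(float)
    if not np.all(np.isfinite(log_peak)):
        raise DataError("log_peak_accel contains missing or non-finite values")
    X["log_peak_accel"] = log_peak
    if "sex" in spec.predictors:
        unknown = set(rows["sex"]) - set(SEX_LEVELS)
        if unknown:
            raise DataError(f"unknown sex level(s) {sorted(unknown)}")
        X["sex_male"] = (rows["sex"] == "male").astype(float)
    if "throw_type" in spec.predictors:
        unknown = set(rows["throw_type"]) - set(THROW_TYPES)
        if unknown:
            raise DataError(f"unknown throw type(s) {sorted(unknown)}")
        for level in TYPE_DUMMY_LEVELS:
            X[f"type_{level}"] = (rows["throw_type"] == level).astype(float)

    y = None
    if require_response:
        y = rows["observed_speed_mps"].astype(float)
        if not np.all(np.isfinite(y)):
            raise DataError("observed_speed_mps contains missing values")
    return X, y


def _collinear_column(X: pd.DataFrame) -> str:
    """Name the first design column that is linearly dependent on the ones
    before it (QR diagonal test)."""
    values = X.to_numpy(float)
    r = np.linalg.qr(values, mode="r")
    diag = np.abs(np.diag(r))
    scale = max(diag.max(), 1.0)
    for j, d in enumerate(diag):
        if d < 1e-10 * scale:
            return str(X.columns[j])
    return str(X.columns[-1])


def fit_model(rows: pd.DataFrame, spec: ModelSpec | str) -> FittedModel:
    """Ordinary least squares fit with t-based 95% confidence intervals."""
    if isinstance(spec, str):
        spec = model_spec(spec)
    X, y = build_design_matrix(rows, spec)
    if len(rows) <= X.shape[1]:
        raise FittingError(
            f"{len(rows)} rows cannot identify {X.shape[1]} coefficients"
        )
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise FittingError(
            f"design matrix is rank deficient; column "
            f"'{_collinear_column(X)}' is collinear with the ones before it"
        )
    res = sm.OLS(y.to_numpy(float), X).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["ci_low", "ci_high"]
    return FittedModel(spec=spec, params=res.params, conf_int=ci, nobs=len(rows))


def predict(model: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    """Predicted speeds (m/s): the linear combination, without clipping."""
    X, _ = build_design_matrix(rows, model.spec, require_response=False)
    return X.to_numpy(float) @ model.params.to_numpy(float)


# Published coefficient tables: term -> (estimate, ci_low, ci_high),
# fitted to the full laboratory dataset (475 throws).
_PUBLISHED = {
    "Base": {
        "intercept": (-4.9, -6.2, -3.5),
        "log_peak_accel": (6.4, 6.0, 6.8),
    },
    "Sex": {
        "intercept": (-4.5, -5.9, -3.2),
        "log_peak_accel": (6.1, 5.7, 6.5),
        "sex_male": (1.5, 1.1, 1.9),
    },
    "Type": {
        "intercept": (5.6, 3.6, 7.6),
        "log_peak_accel": (4.0, 3.5, 4.4),
        "type_low_norun": (-4.0, -4.6, -3.3),
        "type_med_norun": (-3.0, -3.6, -2.4),
        "type_max_norun": (-0.5, -1.0, 0.1),
        "type_max_run": (0.6, 0.0, 1.1),
    },
    "Full": {
        "intercept": (9.0, 7.4, 10.7),
        "log_peak_accel": (2.7, 2.3, 3.1),
        "sex_male": (2.4, 2.1, 2.7),
        "type_low_norun": (-5.0, -5.6, -4.4),
        "type_med_norun": (-3.7, -4.2, -3.2),
        "type_max_norun": (-0.3, -0.8, 0.2),
        "type_max_run": (0.9, 0.5, 1.4),
    },
}


def published_model(name: str) -> FittedModel:
    """The named model pre-loaded with the published estimates and CIs."""
    if name not in _PUBLISHED:
        raise DataError(
            f"unknown published model {name!r}; expected one of {MODEL_NAMES}"
        )
    spec = model_spec(name)
    table = _PUBLISHED[name]
    params = pd.Series({k: v[0] for k, v in table.items()})[list(spec.columns)]
    ci = pd.DataFrame(
        {
            "ci_low": {k: v[1] for k, v in table.items()},
            "ci_high": {k: v[2] for k, v in table.items()},
        }
    ).loc[list(spec.columns)]
    return FittedModel(spec=spec, params=params, conf_int=ci, nobs=475)


def write_model(model: FittedModel, path) -> None:
    """Serialize a fitted model to a plain-text coefficient file."""
    df = pd.DataFrame(
        {
            "name": model.spec.name,
            "term": model.params.index,
            "estimate": model.params.to_numpy(float),
            "ci_low": model.conf_int["ci_low"].to_numpy(float),
            "ci_high": model.conf_int["ci_high"].to_numpy(float),
        }
    )
    df.to_csv(path, index=False)


def read_model(path) -> FittedModel:
    df = pd.read_csv(path)
    needed = {"name", "term", "estimate", "ci_low", "ci_high"}
    if not needed <= set(df.columns):
        raise DataError(f"model file must have columns {sorted(needed)}")
    names = df["name"].unique()
    if len(names) != 1:
        raise DataError("model file must contain exactly one model")
    spec = model_spec(str(names[0]))
    df = df.set_index("term").loc[list(spec.columns)]
    df.index.name = None
    params = df["estimate"].astype(float)
    params.name = None
    return FittedModel(
        spec=spec,
        params=params,
        conf_int=df[["ci_low", "ci_high"]].astype(float),
    )
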