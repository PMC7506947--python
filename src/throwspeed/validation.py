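"""Cross-validated performance and three-level calibration assessment.

Internal validity is estimated by 10-fold cross-validation: the data are
split at random into 10 near-equal folds, each fold is predicted by a model
fitted to the other nine, and every row receives exactly one out-of-fold
prediction. Precision (R^2 and mean absolute error) is computed within each
hold-out fold and summarised as across-fold mean and SD; calibration is
assessed on the pooled out-of-fold predictions at three levels:

1. mean calibration (calibration-in-the-large): mean predicted minus mean
   observed speed — 0 is ideal;
2. weak calibration (calibration slope): the OLS slope of observed on
   predicted — 1 is ideal, below 1 flags predictions that are too spread
   out (overestimation at the high end), above 1 the reverse;
3. moderate calibration: visual agreement of a binned observed-vs-predicted
   curve with the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FittingError, FoldError, MetricError, ParameterError, SizeError
from .models import FittedModel, ModelSpec, fit_model, model_spec, predict

__all__ = [
    "FoldAssignment",
    "CalibrationReport",
    "CalibrationPlotData",
    "kfold_split",
    "cross_validate",
    "r_squared",
    "mae",
    "mean_calibration",
    "calibration_slope",
    "calibration_plot_data",
    "render_calibration_plot",
    "report_table",
    "write_report_table",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Seeded random partition of n rows into k folds labelled 1..k."""

    labels: np.ndarray  # (n,) ints in 1..k
    k: int
    seed: int


def kfold_split(n: int, k: int, seed: int) -> FoldAssignment:
    """Assign n rows to k folds uniformly at random (sizes differ by <= 1)."""
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n:
        raise ParameterError(f"k = {k} folds cannot partition {n} rows")
    base, rem = divmod(n, k)
    sizes = [base + 1] * rem + [base] * (k - rem)
    labels = np.repeat(np.arange(1, k + 1), sizes)
    rng = np.random.default_rng(seed)
    return FoldAssignment(labels=labels[rng.permutation(n)], k=k, seed=seed)


def r_squared(observed, predicted) -> float:
    """1 - SSE/SST, with SST about the mean of the evaluated observations."""
    observed, predicted = _paired(observed, predicted, minimum=2)
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0.0:
        raise MetricError("R^2 is undefined for constant observations")
    sse = float(np.sum((observed - predicted) ** 2))
    return 1.0 - sse / sst


def mae(observed, predicted) -> float:
    """Mean absolute error, in m/s."""
    observed, predicted = _paired(observed, predicted, minimum=1)
    return float(np.mean(np.abs(observed - predicted)))


def mean_calibration(observed, predicted) -> float:
    """Calibration-in-the-large: mean(predicted) - mean(observed), m/s."""
    observed, predicted = _paired(observed, predicted, minimum=1)
    return float(predicted.mean() - observed.mean())


def calibration_slope(observed, predicted) -> float:
    """Weak calibration: OLS slope of observed regressed ON predicted."""
    observed, predicted = _paired(observed, predicted, minimum=2)
    var = float(np.var(predicted))
    if var == 0.0:
        raise MetricError("calibration slope is undefined for constant predictions")
    cov = float(np.mean((predicted - predicted.mean()) * (observed - observed.mean())))
    return cov / var


def _paired(observed, predicted, minimum: int):
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise SizeError("observed and predicted must have equal length")
    if observed.size < minimum:
        raise SizeError(f"need at least {minimum} observation/prediction pair(s)")
    return observed, predicted


@dataclass(frozen=True)
class CalibrationPlotData:
    """Everything needed to draw one calibration panel."""

    predicted: np.ndarray
    observed: np.ndarray
    slope: float
    intercept: float  # of the observed-on-predicted calibration line
    calibration_line: np.ndarray  # (2, 2): [[x0, y0], [x1, y1]]
    identity_line: np.ndarray  # (2, 2)
    curve_predicted: np.ndarray  # moderate-calibration smoother (bin means)
    curve_observed: np.ndarray


def calibration_plot_data(observed, predicted, bins: int = 20) -> CalibrationPlotData:
    """Scatter pairs, fitted calibration line, identity reference and a
    local-averaging smoother over ``bins`` equal-count bins of predictions."""
    observed, predicted = _paired(observed, predicted, minimum=2)
    slope = calibration_slope(observed, predicted)
    intercept = float(observed.mean() - slope * predicted.mean())
    x0, x1 = float(predicted.min()), float(predicted.max())
    cal_line = np.array([[x0, intercept + slope * x0], [x1, intercept + slope * x1]])
    identity = np.array([[x0, x0], [x1, x1]])

    bins = min(bins, observed.size)
    order = np.argsort(predicted, kind="stable")
    groups = np.array_split(order, bins)
    curve_p = np.array([predicted[g].mean() for g in groups if len(g)])
    curve_o = np.array([observed[g].mean() for g in groups if len(g)])
    return CalibrationPlotData(
        predicted=predicted,
        observed=observed,
        slope=slope,
        intercept=intercept,
        calibration_line=cal_line,
        identity_line=identity,
        curve_predicted=curve_p,
        curve_observed=curve_o,
    )


@dataclass(frozen=True)
class CalibrationReport:
    """Cross-validated performance of one model specification."""

    model_name: str
    k: int
    seed: int
    fold_r2: np.ndarray
    fold_mae: np.ndarray
    mean_calibration: float
    calibration_slope: float
    observed: np.ndarray
    predicted: np.ndarray  # pooled out-of-fold predictions, row order
    fold_labels: np.ndarray
    plot: CalibrationPlotData = field(repr=False, default=None)

    @property
    def r2_mean(self) -> float:
        return float(self.fold_r2.mean())

    @property
    def r2_sd(self) -> float:
        return float(self.fold_r2.std(ddof=1))

    @property
    def mae_mean(self) -> float:
        return float(self.fold_mae.mean())

    @property
    def mae_sd(self) -> float:
        return float(self.fold_mae.std(ddof=1))


def cross_validate(
    rows: pd.DataFrame,
    spec: ModelSpec | str,
    k: int = 10,
    seed: int = 0,
) -> CalibrationReport:
    """k-fold cross-validation of one model specification.

    Fits the model k times, each time predicting the left-out fold, then
    computes per-fold R^2/MAE and pooled calibration metrics.
    """
    if isinstance(spec, str):
        spec = model_spec(spec)
    n = len(rows)
    assignment = kfold_split(n, k, seed)
    observed = rows["observed_speed_mps"].to_numpy(float)
    predicted = np.full(n, np.nan)
    fold_r2 = np.empty(k)
    fold_mae = np.empty(k)
    for j in range(1, k + 1):
        holdout = assignment.labels == j
        try:
            fitted = fit_model(rows.loc[~holdout], spec)
        except FittingError as exc:
            raise FoldError(j, f"refit failed: {exc}") from exc
        predicted[holdout] = predict(fitted, rows.loc[holdout])
        fold_r2[j - 1] = r_squared(observed[holdout], predicted[holdout])
        fold_mae[j - 1] = mae(observed[holdout], predicted[holdout])
    assert not np.any(np.isnan(predicted)), "every row must be predicted once"
    return CalibrationReport(
        model_name=spec.name,
        k=k,
        seed=seed,
        fold_r2=fold_r2,
        fold_mae=fold_mae,
        mean_calibration=mean_calibration(observed, predicted),
        calibration_slope=calibration_slope(observed, predicted),
        observed=observed,
        predicted=predicted,
        fold_labels=assignment.labels,
        plot=calibration_plot_data(observed, predicted),
    )


REPORT_ROWS = ["R2_mean", "R2_sd", "MAE_mean", "MAE_sd", "weak_calibration", "mean_calibration"]


def report_table(reports: dict) -> pd.DataFrame:
    """Performance table: one column per model, the six summary metrics as
    rows. Slope is rounded to 2 decimals and mean calibration to 4, the
    precision at which such tables are conventionally reported; R^2/MAE
    summaries to 4."""
    table = {}
    for name, rep in reports.items():
        table[name] = [
            round(rep.r2_mean, 4),
            round(rep.r2_sd, 4),
            round(rep.mae_mean, 4),
            round(rep.mae_sd, 4),
            round(rep.calibration_slope, 2),
            round(rep.mean_calibration, 4),
        ]
    return pd.DataFrame(table, index=REPORT_ROWS)


def write_report_table(reports: dict, path) -> None:
    report_table(reports).to_csv(path, index_label="measure")


def render_calibration_plot(report: CalibrationReport, path) -> None:
    """One calibration panel: out-of-fold scatter, calibration line,
    identity line and the binned moderate-calibration curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = report.plot
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(data.predicted, data.observed, s=8, alpha=0.4, color="grey")
    ax.plot(*data.identity_line.T, "k--", lw=1, label="identity")
    ax.plot(*data.calibration_line.T, color="tab:blue", lw=2, label="calibration")
    ax.plot(
        data.curve_predicted,
        data.curve_observed,
        color="tab:orange",
        marker="o",
        ms=3,
        lw=1,
        label="binned mean",
    )
    ax.set_xlabel("estimated speed (m/s)")
    ax.set_ylabel("observed speed (m/s)")
    ax.set_title(
        f"{report.model_name}: slope {data.slope:.2f}, "
        f"mean cal. {report.mean_calibration:+.2f} m/s"
    )
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
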