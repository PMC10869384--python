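"""Regression statistics and cross-validation for QSAR models.

Conventions used throughout:

* R^2 = 1 - SSres/SStot and SEE = sqrt(SSres/(n-k-1)) on the training fit;
* LOO Q^2 = 1 - PRESS/SStot with SStot taken about the full training-sample
  mean (the standard chemometrics convention) and SEP = sqrt(PRESS/n);
* external predictivity r2_pred = (SD - PRESS)/SD where SD is the spread of
  the test activities about the *training* mean.

Q^2 is unbounded below: a model worse than the mean predictor goes negative.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ValidationReport",
    "regression_stats",
    "loo_q2",
    "r2_pred",
    "pseudo_r2_corr",
    "pseudo_r2_press",
]

FitFunction = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


@dataclass
class ValidationReport:
    """Bundle of the statistics reported for a fitted QSAR model."""

    r2: float
    q2_loo: float
    see: float
    sep: float
    f_stat: float
    f_ratio: float
    n_train: int
    n_test: int
    r2_pred: float | None
    press: float
    sd: float | None

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), indent=2, **kwargs)

    def to_markdown(self) -> str:
        lines = [
            "| statistic | value |",
            "|---|---|",
            f"| n_train | {self.n_train} |",
            f"| n_test | {self.n_test} |",
            f"| R2 | {self.r2:.4f} |",
            f"| Q2 (LOO) | {self.q2_loo:.4f} |",
            f"| SEE | {self.see:.4f} |",
            f"| SEP | {self.sep:.4f} |",
            f"| F | {self.f_stat:.4f} |",
            f"| F ratio R2/(1-R2) | {self.f_ratio:.4f} |",
        ]
        if self.r2_pred is not None:
            lines.append(f"| r2_pred | {self.r2_pred:.4f} |")
        return "\n".join(lines)


def regression_stats(
    y: Sequence[float], y_hat: Sequence[float], k: int
) -> tuple[float, float, float]:
    """Training-fit R^2, SEE and F for a model with k predictors."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = y.size
    if y_hat.size != n:
        raise ValueError("y and y_hat differ in length")
    if n <= k + 1:
        raise ValueError(f"need n > k+1 (n={n}, k={k})")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total variance in y")
    ss_res = float(np.sum((y - y_hat) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    see = float(np.sqrt(ss_res / (n - k - 1)))
    if r2 >= 1.0:
        f = float("inf")
    else:
        f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return r2, see, f


def loo_q2(
    fit: FitFunction,
    X: np.ndarray,
    y: Sequence[float],
    sep_ddof: int = 0,
) -> tuple[float, float]:
    """Leave-one-out Q^2 and SEP for an arbitrary fit function.

    ``fit(X_train, y_train)`` must return a callable mapping feature rows to
    predictions.  The model is refit n times, each time excluding one sample.
    ``sep_ddof=1`` switches SEP to sqrt(PRESS/(n-1)).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("LOO needs at least 3 samples")
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        try:
            predict = fit(X[mask], y[mask])
            pred_i = float(np.asarray(predict(X[i : i + 1])).ravel()[0])
        except Exception as exc:
            raise RuntimeError(f"LOO sub-fit failed leaving out index {i}: {exc}") from exc
        press += (y[i] - pred_i) ** 2
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total variance in y")
    q2 = 1.0 - press / ss_tot
    sep = float(np.sqrt(press / (n - sep_ddof)))
    return q2, sep


def r2_pred(
    y_test: Sequence[float], y_hat_test: Sequence[float], y_train_mean: float
) -> float:
    """External predictivity (SD - PRESS)/SD on a held-out test set."""
    y_test = np.asarray(y_test, dtype=float)
    y_hat_test = np.asarray(y_hat_test, dtype=float)
    if y_test.size < 1:
        raise ValueError("empty test set")
    if y_hat_test.size != y_test.size:
        raise ValueError("y_test and y_hat_test differ in length")
    sd = float(np.sum((y_test - y_train_mean) ** 2))
    if sd == 0:
        raise ValueError("test set has no spread about training mean")
    press = float(np.sum((y_test - y_hat_test) ** 2))
    return (sd - press) / sd


def pseudo_r2_corr(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Squared Pearson correlation between observed and predicted values."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.std() == 0 or y_hat.std() == 0:
        return 0.0
    return float(np.corrcoef(y, y_hat)[0, 1] ** 2)


def pseudo_r2_press(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """1 - PRESS/SStot form of the predictive r^2 (can be negative)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero total variance in y")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def build_report(
    y_train: Sequence[float],
    y_hat_train: Sequence[float],
    k: int,
    q2: float,
    sep: float,
    press: float,
    y_test: Sequence[float] | None = None,
    y_hat_test: Sequence[float] | None = None,
) -> ValidationReport:
    """Assemble a ValidationReport from pre-computed pieces."""
    y_train = np.asarray(y_train, dtype=float)
    r2, see, f = regression_stats(y_train, y_hat_train, k)
    f_ratio = float("inf") if r2 >= 1 else r2 / (1.0 - r2)
    n_test = 0 if y_test is None else len(y_test)
    rp = sd = None
    if y_test is not None and y_hat_test is not None and len(y_test):
        sd = float(np.sum((np.asarray(y_test) - y_train.mean()) ** 2))
        rp = r2_pred(y_test, y_hat_test, float(y_train.mean()))
    return ValidationReport(
        r2=r2,
        q2_loo=q2,
        see=see,
        sep=sep,
        f_stat=f,
        f_ratio=f_ratio,
        n_train=y_train.size,
        n_test=n_test,
        r2_pred=rp,
        press=press,
        sd=sd,
    )
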