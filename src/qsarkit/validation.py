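"""Shared model-quality statistics and external validation."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["ValidationReport", "r2_ext", "summary_metrics", "verdict", "make_report"]

R2_EXT_THRESHOLD = 0.5


@dataclass
class ValidationReport:
    r2_ext: float
    verdict: str
    train: dict
    test: dict

    def to_dict(self) -> dict:
        return {
            "r2_ext": self.r2_ext,
            "verdict": self.verdict,
            "train": self.train,
            "test": self.test,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def r2_ext(y_test, yhat_test, ytrain_mean: float) -> float:
    """External-validation statistic:
    ``1 - sum (y_i - yhat_i)^2 / sum (y_i - mean(y_train))^2``."""
    y_test = np.asarray(y_test, dtype=float)
    yhat_test = np.asarray(yhat_test, dtype=float)
    if y_test.size == 0:
        raise ValueError("test set is empty")
    if y_test.shape != yhat_test.shape:
        raise ValueError("y_test and yhat_test must have equal length")
    denom = float(np.sum((y_test - ytrain_mean) ** 2))
    if denom == 0.0:
        raise ValueError("all test responses equal the training mean: denominator is zero")
    return 1.0 - float(np.sum((y_test - yhat_test) ** 2)) / denom


def summary_metrics(y, yhat, n_params: int) -> dict[str, float]:
    """r2, SEE, F, Pearson r, MAE and RMSE for a prediction vector.

    ``r2 = 1 - RSS/TSS``; ``SEE = sqrt(RSS/(n - n_params - 1))``;
    ``F = (r2/k) / ((1-r2)/(n-k-1))``.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    n = len(y)
    if n <= n_params + 1:
        raise ValueError(f"need n > n_params + 1 (n={n}, n_params={n_params})")
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        raise ValueError("zero-variance response")
    r2 = 1.0 - rss / tss
    dof = n - n_params - 1
    see = float(np.sqrt(rss / dof))
    with np.errstate(divide="ignore"):
        f = (r2 / n_params) / ((1.0 - r2) / dof) if r2 < 1.0 else float("inf")
    if np.ptp(yhat) == 0.0:
        pearson = 0.0
    else:
        pearson = float(np.corrcoef(y, yhat)[0, 1])
    mae = float(np.mean(np.abs(y - yhat)))
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return {"r2": r2, "see": see, "f": f, "pearson_r": pearson, "mae": mae, "rmse": rmse}


def verdict(value: float) -> str:
    """'pass' iff the external-validation statistic strictly exceeds 0.5."""
    if not np.isfinite(value):
        raise ValueError("r2_ext must be finite")
    return "pass" if value > R2_EXT_THRESHOLD else "fail"


def make_report(y_train, yhat_train, y_test, yhat_test, n_params: int) -> ValidationReport:
    y_train = np.asarray(y_train, dtype=float)
    rext = r2_ext(y_test, yhat_test, float(y_train.mean()))
    return ValidationReport(
        r2_ext=rext,
        verdict=verdict(rext),
        train=summary_metrics(y_train, yhat_train, n_params),
        test=summary_metrics(y_test, yhat_test, n_params)
        if len(np.asarray(y_test)) > n_params + 1
        else {
            "mae": float(np.mean(np.abs(np.asarray(y_test) - np.asarray(yhat_test)))),
            "rmse": float(np.sqrt(np.mean((np.asarray(y_test) - np.asarray(yhat_test)) ** 2))),
            "pearson_r": float(np.corrcoef(y_test, yhat_test)[0, 1])
            if np.ptp(np.asarray(yhat_test, dtype=float)) > 0
            else 0.0,
        },
    )
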