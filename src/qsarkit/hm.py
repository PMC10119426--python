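"""Heuristic stepwise multilinear model search.

Search protocol: exhaustive best pair (by R^2, among pairs passing the
pairwise collinearity cap), then greedy forward addition of the single
descriptor that maximizes R^2 subject to the cap and a t-significance
threshold, recording the best model at each size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LinearModel",
    "SearchConfig",
    "SearchTrace",
    "fit_ols",
    "loo_r2cv",
    "prefilter",
    "heuristic_search",
    "correlation_table",
    "choose_model_size",
    "hm_reference_predict",
    "HM_REFERENCE_COEFFICIENTS",
    "HM_REFERENCE_INTERCEPT",
]

# Reference five-descriptor linear model for VEGFR3 inhibitor activity
# (literature coefficients, evaluated as published).
HM_REFERENCE_INTERCEPT = 49.779
HM_REFERENCE_COEFFICIENTS = {
    "MREB": -4.0867,
    "NN": 6.6215e-2,
    "YZS/YZR": 6.3779,
    "MPCO(ZPC)": 3.7446,
    "MSEC": -1.0425e-1,
}


@dataclass
class LinearModel:
    """Fitted multilinear model and its quality statistics."""

    names: list[str]
    coef: np.ndarray
    intercept: float
    r2: float
    s2: float
    f: float
    t_values: np.ndarray
    n: int
    r2cv: float | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "descriptors": list(self.names),
            "coefficients": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "r2": float(self.r2),
            "s2": float(self.s2),
            "f": float(self.f),
            "t_values": [float(t) for t in self.t_values],
            "r2cv": None if self.r2cv is None else float(self.r2cv),
            "n": int(self.n),
        }


@dataclass
class SearchConfig:
    max_model_size: int = 5
    collinearity_cap: float = 0.8
    t_min: float = 0.0  # 0 disables the per-addition t filter
    f_min: float = 0.0
    drop_constant: bool = True
    drop_missing: bool = True
    prefilter_t_min: float = 0.0

    def __post_init__(self) -> None:
        if self.max_model_size < 1:
            raise ValueError("max_model_size must be >= 1")
        if not (0 < self.collinearity_cap <= 1):
            raise ValueError("collinearity_cap must be in (0, 1]")


@dataclass
class SearchTrace:
    """Best model found at each size along the greedy path."""

    models: dict[int, LinearModel] = field(default_factory=dict)

    @property
    def sizes(self) -> list[int]:
        return sorted(self.models)

    def best(self) -> LinearModel:
        return self.models[max(self.models)]

    def to_dict(self) -> dict:
        return {str(k): m.to_dict() for k, m in self.models.items()}


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(X)), X])


def fit_ols(X, y, names: list[str] | None = None) -> LinearModel:
    """Ordinary least squares with R^2, residual variance S^2, F and t-values.

    ``S^2 = RSS / (n - k - 1)`` (residual variance); a zero-variance response
    yields R^2 = 0 with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) > 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{i}" for i in range(k)]
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 rows (n={n}, k={k})")
    A = _design(X)
    if np.linalg.matrix_rank(A) < k + 1:
        raise np.linalg.LinAlgError("design matrix is rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss < 1e-300:
        warnings.warn("zero-variance response: R^2 defined as 0")
        r2 = 0.0
    else:
        r2 = 1.0 - rss / tss
    dof = n - k - 1
    s2 = rss / dof
    f = (r2 / k) / ((1.0 - r2) / dof) if r2 < 1.0 else np.inf
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(np.maximum(s2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = np.where(se > 0, beta / se, 0.0)
    return LinearModel(
        names=list(names),
        coef=beta[1:],
        intercept=float(beta[0]),
        r2=r2,
        s2=s2,
        f=f,
        t_values=t_all[1:],
        n=n,
    )


def loo_r2cv(X, y) -> float:
    """Leave-one-out cross-validated R^2, ``1 - PRESS/TSS``.

    Uses the hat-matrix identity ``e_i / (1 - h_ii)`` for the deleted
    residuals, which equals n explicit refits for full-rank OLS.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) > 1:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 for LOO (n={n}, k={k})")
    A = _design(X)
    if np.linalg.matrix_rank(A) < k + 1:
        raise np.linalg.LinAlgError("design matrix is rank-deficient")
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    h = np.einsum("ij,jk,ik->i", A, np.linalg.inv(A.T @ A), A)
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss < 1e-300:
        raise ValueError("zero-variance response")
    return 1.0 - press / tss


def _single_t(x: np.ndarray, y: np.ndarray) -> float:
    # t of the slope in a univariate regression with intercept
    n = len(y)
    r = np.corrcoef(x, y)[0, 1]
    if not np.isfinite(r) or abs(r) >= 1.0:
        return np.inf if np.isfinite(r) else 0.0
    return abs(r) * np.sqrt((n - 2) / (1.0 - r * r))


def prefilter(matrix: pd.DataFrame, y, config: SearchConfig | None = None) -> pd.DataFrame:
    """Drop constant columns, columns with missing values, and columns whose
    one-parameter |t| falls below ``config.prefilter_t_min``."""
    config = config or SearchConfig()
    y = np.asarray(y, dtype=float)
    keep = []
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        if config.drop_missing and not np.all(np.isfinite(x)):
            continue
        if config.drop_constant and np.ptp(x) < 1e-300:
            continue
        if config.prefilter_t_min > 0 and _single_t(x, y) < config.prefilter_t_min:
            continue
        keep.append(col)
    if not keep:
        raise ValueError("prefilter removed every column")
    out = matrix[keep].copy()
    out.attrs = dict(matrix.attrs)
    return out


def correlation_table(names: list[str], matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the selected descriptors."""
    missing = [n for n in names if n not in matrix.columns]
    if missing:
        raise ValueError(f"descriptors not in matrix: {missing}")
    sub = matrix[names].to_numpy(dtype=float)
    corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(corr)
    return pd.DataFrame(corr, index=names, columns=names)


def _admissible(candidate: np.ndarray, chosen: list[np.ndarray], cap: float) -> bool:
    for x in chosen:
        r = np.corrcoef(candidate, x)[0, 1]
        if abs(r) > cap:
            return False
    return True


def heuristic_search(matrix: pd.DataFrame, y, config: SearchConfig | None = None) -> SearchTrace:
    """Stepwise model search: exhaustive best pair, then greedy forward additions.

    Ties in R^2 are broken by the larger minimum |t| over the model's
    coefficients, then by column order.  Raises if no admissible pair exists.
    """
    config = config or SearchConfig()
    y = np.asarray(y, dtype=float)
    cols = list(matrix.columns)
    data = {c: matrix[c].to_numpy(dtype=float) for c in cols}
    n = len(y)
    if n <= config.max_model_size + 2:
        raise ValueError("too few rows for the requested max_model_size")

    def score(names: list[str]) -> tuple[float, float, LinearModel] | None:
        X = np.column_stack([data[c] for c in names])
        try:
            m = fit_ols(X, y, names)
        except np.linalg.LinAlgError:
            return None
        return m.r2, float(np.min(np.abs(m.t_values))), m

    cap = config.collinearity_cap
    best = None
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if cap < 1.0 and not _admissible(data[cols[j]], [data[cols[i]]], cap):
                continue
            sc = score([cols[i], cols[j]])
            if sc is None:
                continue
            key = (sc[0], sc[1])
            if best is None or key > best[0]:
                best = (key, [cols[i], cols[j]], sc[2])
    if best is None:
        raise ValueError("no admissible descriptor pair under the collinearity cap")

    trace = SearchTrace()
    selected = best[1]
    model = best[2]
    model.r2cv = loo_r2cv(np.column_stack([data[c] for c in selected]), y)
    trace.models[2] = model

    while len(selected) < config.max_model_size:
        chosen_vecs = [data[c] for c in selected]
        step_best = None
        for c in cols:
            if c in selected:
                continue
            if not _admissible(data[c], chosen_vecs, cap):
                continue
            sc = score(selected + [c])
            if sc is None:
                continue
            r2, tmin, m = sc
            if config.t_min > 0 and abs(m.t_values[-1]) < config.t_min:
                continue
            if config.f_min > 0 and m.f < config.f_min:
                continue
            key = (r2, tmin)
            if step_best is None or key > step_best[0]:
                step_best = (key, c, m)
        if step_best is None:
            break
        selected = selected + [step_best[1]]
        model = step_best[2]
        model.r2cv = loo_r2cv(np.column_stack([data[c] for c in selected]), y)
        trace.models[len(selected)] = model
    return trace


def choose_model_size(trace: SearchTrace, delta_r2_threshold: float = 0.02) -> int:
    """Smallest size after which the R^2 gain drops below the threshold."""
    sizes = trace.sizes
    if len(sizes) < 2:
        raise ValueError("trace must contain at least two model sizes")
    for a, b in zip(sizes, sizes[1:]):
        if trace.models[b].r2 - trace.models[a].r2 < delta_r2_threshold:
            return a
    return sizes[-1]


def hm_reference_predict(mreb, nn, yzs_yzr, mpco, msec):
    """Evaluate the reference five-descriptor linear equation (LogIC50 scale)."""
    c = HM_REFERENCE_COEFFICIENTS
    return (
        HM_REFERENCE_INTERCEPT
        + c["MREB"] * np.asarray(mreb, dtype=float)
        + c["NN"] * np.asarray(nn, dtype=float)
        + c["YZS/YZR"] * np.asarray(yzs_yzr, dtype=float)
        + c["MPCO(ZPC)"] * np.asarray(mpco, dtype=float)
        + c["MSEC"] * np.asarray(msec, dtype=float)
    )


def save_model_json(trace: SearchTrace, path, chosen_size: int | None = None) -> None:
    payload = {
        "trace": trace.to_dict(),
        "chosen_size": chosen_size,
        "model": trace.models[chosen_size].to_dict() if chosen_size else trace.best().to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
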