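"""Linear quantile regression under a variable sliding-window protocol.

The conditional τ-quantile of next-day morning PEFR is modelled as a linear
function of the daily feature vector and fitted by minimising the pinball
(check) loss

    L_τ(β) = Σ_i ρ_τ(y_i − x_i·β),   ρ_τ(u) = u (τ − 1{u < 0}),

posed as a linear program and solved with HiGHS.  Fitting is wrapped in a
variable sliding window: a window of W consecutive days (split D_train /
D_valid, default 2:1) fits and validates one model which is then used to
predict the following m days, after which the window slides forward by m.
Calibration of the predicted quantiles on test days is summarised by

    Err_τ = | N_τ / N − τ |,

where N_τ counts test days whose observed PEFR fell strictly below that
day's predicted τ-quantile and N is the number of test days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "WindowSpec",
    "SlidingQRModel",
    "QuantileCrossingWarning",
    "DEFAULT_TAU_GRID",
    "TAU_BANDS",
    "fit_qr",
    "pinball_loss",
    "predict_quantile",
    "detect_crossings",
    "sliding_window_run",
    "err_tau",
    "err_tau_by_quantile",
    "band_table",
    "band_table_marginals",
    "grid_search_windows",
]

#: τ grid used throughout; extremes 0.01/0.99 plus a 0.05-step lattice.
DEFAULT_TAU_GRID: Tuple[float, ...] = tuple(
    round(t, 2) for t in (0.01, *np.arange(0.05, 0.951, 0.05), 0.99)
)

#: the ten τ bands of width ~0.1 used for reporting band-averaged Err_τ.
TAU_BANDS: Tuple[Tuple[float, float], ...] = tuple(
    (round(0.01 + 0.10 * i, 2), round(0.10 + 0.10 * i, 2) if i < 9 else 0.99)
    for i in range(10)
)


class QuantileCrossingWarning(UserWarning):
    """Raised when a fitted higher quantile predicts below a lower one."""


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: W = train_size + valid_size, slide size m."""

    window: int
    train_size: int
    valid_size: int
    m: int

    def __post_init__(self) -> None:
        if self.window != self.train_size + self.valid_size:
            raise ValueError("window must equal train_size + valid_size")
        if not 1 <= self.m <= self.window:
            raise ValueError("slide size m must satisfy 1 <= m <= W")

    @classmethod
    def from_window(cls, window: int, m: int, train_frac: float = 2 / 3) -> "WindowSpec":
        """Split W at the canonical 2:1 train:valid ratio (45 -> 30/15)."""
        train = int(round(window * train_frac))
        return cls(window=window, train_size=train, valid_size=window - train, m=m)


@dataclass
class SlidingQRModel:
    """Per-τ linear coefficients fitted on one window of days."""

    coefficients: Dict[float, np.ndarray]
    feature_names: List[str]
    window: Optional[WindowSpec] = None
    iteration: int = 0
    train_loss: Dict[float, float] = field(default_factory=dict)
    valid_loss: Dict[float, float] = field(default_factory=dict)

    @property
    def tau_grid(self) -> Tuple[float, ...]:
        return tuple(sorted(self.coefficients))

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "feature_names": list(self.feature_names),
            "coefficients": {str(t): list(map(float, b)) for t, b in self.coefficients.items()},
            "train_loss": {str(t): v for t, v in self.train_loss.items()},
            "valid_loss": {str(t): v for t, v in self.valid_loss.items()},
        }


def pinball_loss(y: np.ndarray, pred: np.ndarray, tau: float) -> float:
    """Mean check loss ρ_τ averaged over observations."""
    u = np.asarray(y, float) - np.asarray(pred, float)
    return float(np.mean(u * (tau - (u < 0))))


def _design(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(X.shape[0]), X])


def _collinear_columns(A: np.ndarray) -> List[int]:
    """Indices of design columns involved in a rank deficiency (QR pivoting)."""
    from scipy.linalg import qr as scipy_qr

    _, r, piv = scipy_qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(A.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    return sorted(int(p) for p in piv[rank:])


def fit_qr(X, y, tau: float) -> np.ndarray:
    """Fit one linear τ-quantile by LP; returns (intercept, slopes...).

    The pinball minimiser is found as a vertex of the LP feasible set; on a
    flat optimum (common for extreme τ at small n) the returned vertex is
    one of the optimal solutions — the achieved loss, not the coefficient
    values, is the invariant quantity there.
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    y = np.asarray(y, dtype=float).ravel()
    A = _design(X)
    n, p1 = A.shape
    if n < p1 + 1:
        raise ValueError(f"need at least {p1 + 1} rows to fit {p1} coefficients, got {n}")
    if np.linalg.matrix_rank(A) < p1:
        bad = _collinear_columns(A)
        names = ["intercept"] + [f"x{j}" for j in range(1, p1)]
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(names[j] for j in bad)
        )
    # variables: beta (free, p1), u >= 0 (n), v >= 0 (n); A beta + u - v = y
    c = np.concatenate([np.zeros(p1), np.full(n, tau), np.full(n, 1.0 - tau)])
    A_eq = np.hstack([A, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p1 + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS is robust on these LPs
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:p1]


def predict_quantile(model: SlidingQRModel, x, tau: float) -> np.ndarray:
    """Predict the τ-quantile x·β_τ for one or more feature rows."""
    if tau not in model.coefficients:
        raise KeyError(
            f"tau={tau} not on the fitted grid; available: {sorted(model.coefficients)}"
        )
    return _design(x) @ model.coefficients[tau]


def detect_crossings(model: SlidingQRModel, x) -> List[Tuple[float, float]]:
    """(τ_low, τ_high) pairs whose predictions cross on any row of ``x``.

    Quantiles are fitted independently per τ (classical QR), so crossings
    can occur; they are reported, never silently repaired.
    """
    taus = sorted(model.coefficients)
    preds = {t: predict_quantile(model, x, t) for t in taus}
    crossings = []
    for lo, hi in zip(taus, taus[1:]):
        if np.any(preds[hi] < preds[lo]):
            crossings.append((lo, hi))
    return crossings


def sliding_window_run(
    series: pd.DataFrame,
    spec: WindowSpec,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    *,
    feature_cols: Sequence[str],
    response_col: str = "am_pefr",
    valid_loss_threshold: Optional[float] = None,
    warn_on_crossing: bool = False,
) -> Tuple[List[SlidingQRModel], pd.DataFrame]:
    """Run the variable sliding-window protocol over a daily series.

    Iteration k fits per-τ models on rows [s_k, s_k + train_size), computes
    validation pinball loss on the next valid_size rows, then predicts the
    following min(m, remaining) rows; s_{k+1} = s_k + m.  Every row after
    the first W is predicted exactly once, out-of-window, so the combined
    prediction frame has ``len(series) - W`` rows.

    If ``valid_loss_threshold`` is given and the mean validation loss
    exceeds it, the model is refit on the full window (train + valid)
    before use — the operational reading of "refit when validation quality
    is unacceptable".
    """
    n = len(series)
    if n <= spec.window:
        raise ValueError(f"series length {n} must exceed window W={spec.window}")
    # constant columns (e.g. a patient's static covariates) carry no
    # within-patient information and would break every window's design
    feature_cols = [c for c in feature_cols if series[c].nunique() > 1]
    X_all = series[list(feature_cols)].to_numpy(dtype=float)
    y_all = series[response_col].to_numpy(dtype=float)

    models: List[SlidingQRModel] = []
    pred_rows = []
    s, k = 0, 0
    while s + spec.window < n:
        tr = slice(s, s + spec.train_size)
        va = slice(s + spec.train_size, s + spec.window)
        te_stop = min(s + spec.window + spec.m, n)
        te = slice(s + spec.window, te_stop)

        coefs, tr_loss, va_loss = {}, {}, {}
        for tau in tau_grid:
            beta = fit_qr(X_all[tr], y_all[tr], tau)
            coefs[tau] = beta
            tr_loss[tau] = pinball_loss(y_all[tr], _design(X_all[tr]) @ beta, tau)
            va_loss[tau] = pinball_loss(y_all[va], _design(X_all[va]) @ beta, tau)
        if valid_loss_threshold is not None and np.mean(list(va_loss.values())) > valid_loss_threshold:
            win = slice(s, s + spec.window)
            for tau in tau_grid:
                coefs[tau] = fit_qr(X_all[win], y_all[win], tau)
        model = SlidingQRModel(
            coefficients=coefs,
            feature_names=list(feature_cols),
            window=spec,
            iteration=k,
            train_loss=tr_loss,
            valid_loss=va_loss,
        )
        if warn_on_crossing:
            crossed = detect_crossings(model, X_all[te])
            if crossed:
                warnings.warn(
                    f"iteration {k}: quantile crossing at {crossed}", QuantileCrossingWarning
                )
        models.append(model)

        idx = series.index[te]
        frame = {"iteration": k, "observed": y_all[te]}
        for tau in tau_grid:
            frame[f"q{tau:g}"] = _design(X_all[te]) @ coefs[tau]
        pred_rows.append(pd.DataFrame(frame, index=idx))
        s += spec.m
        k += 1

    predictions = pd.concat(pred_rows)
    return models, predictions


def err_tau(predicted: Sequence[float], observed: Sequence[float], tau: float) -> float:
    """Calibration error |N_τ/N − τ|; ties count as not-under (strict <)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.size == 0 or pred.shape != obs.shape:
        raise ValueError("need >= 1 aligned (prediction, observation) pairs")
    n_tau = int(np.sum(obs < pred))
    return float(abs(n_tau / pred.size - tau))


def err_tau_by_quantile(predictions: pd.DataFrame, tau_grid: Sequence[float]) -> pd.Series:
    """Err_τ per τ over a pooled prediction frame from sliding_window_run."""
    out = {}
    for tau in tau_grid:
        out[tau] = err_tau(predictions[f"q{tau:g}"], predictions["observed"], tau)
    return pd.Series(out).rename("err_tau")


def _band_label(lo: float, hi: float) -> str:
    return f"{lo:.2f}-{hi:.2f}"


def band_table(err_by_tau: pd.DataFrame) -> pd.DataFrame:
    """Collapse an (index=τ, columns=W) error table into the ten τ bands."""
    rows = {}
    for lo, hi in TAU_BANDS:
        in_band = [t for t in err_by_tau.index if lo <= t <= hi]
        if in_band:
            rows[_band_label(lo, hi)] = err_by_tau.loc[in_band].mean(axis=0)
    return pd.DataFrame(rows).T


def band_table_marginals(cells: pd.DataFrame, *, decimals: int = 3) -> pd.DataFrame:
    """Append the published-style marginals to a band × window Err_τ table.

    The "Average" column holds each band's across-window mean rounded to the
    table's display precision; the "average" row holds each window column's
    raw mean (shown at one more decimal); the bottom-right grand cell is the
    mean of the (rounded) Average column — the convention of tables that
    average their own printed column.
    """
    out = cells.copy()
    out["Average"] = cells.mean(axis=1).round(decimals)
    col_avg = cells.mean(axis=0)
    grand = round(float(out["Average"].mean()), decimals + 1)
    avg_row = pd.concat([col_avg.round(decimals + 1), pd.Series({"Average": grand})])
    out.loc["average"] = avg_row
    return out


def grid_search_windows(
    series_list: Iterable[pd.DataFrame],
    W_set: Sequence[int],
    m_set: Sequence[int],
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    *,
    feature_cols: Sequence[str],
    response_col: str = "am_pefr",
) -> Tuple[pd.DataFrame, Tuple[int, int], Dict[int, pd.DataFrame]]:
    """Grid search over window sizes W and slide sizes m.

    For every (W, m) pair each patient series is run through the sliding
    window, per-τ Err_τ is computed on that patient's pooled out-of-window
    days, and errors are averaged across patients (unweighted).  Returns a
    long table indexed by (W, m, τ), the (W, m) pair minimising the mean
    Err_τ over the τ grid, and one band × W table per m.
    """
    series_list = list(series_list)
    if not series_list or not list(W_set) or not list(m_set):
        raise ValueError("need non-empty series, W_set and m_set")
    records = []
    for W in W_set:
        for m in m_set:
            spec = WindowSpec.from_window(W, m)
            per_patient = []
            for s in series_list:
                if len(s) <= W:
                    raise ValueError(f"series of length {len(s)} too short for W={W}")
                _, preds = sliding_window_run(
                    s, spec, tau_grid, feature_cols=feature_cols, response_col=response_col
                )
                per_patient.append(err_tau_by_quantile(preds, tau_grid))
            mean_err = pd.concat(per_patient, axis=1).mean(axis=1)
            for tau, e in mean_err.items():
                records.append({"W": W, "m": m, "tau": tau, "err_tau": e})
    long = pd.DataFrame(records)
    by_pair = long.groupby(["W", "m"])["err_tau"].mean()
    best = tuple(int(v) for v in by_pair.idxmin())
    tables = {}
    for m in m_set:
        sub = long[long["m"] == m].pivot(index="tau", columns="W", values="err_tau")
        tables[int(m)] = band_table(sub)
    return long, best, tables
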