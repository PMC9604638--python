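"""Daily two-model decision engine and end-to-end pipeline.

Each day the classifier predicts the next day's risk class from today's
aggregated exposures.  Only when the predicted class is risk is the
quantile-regression model consulted for PEFR(τ_c), the predicted critical
quantile of next-day PEFR; an alert is raised when that prediction has
dropped by more than a threshold θ since the last day the quantile model
was consulted.  Parameter-update hooks receive every step outcome and may
adjust τ_c or the critical PEFR, but do nothing by default: no update rule
is imposed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .classifier import (
    Hyperparams,
    SourceModel,
    TLClassifier,
    evaluate_split,
    train_source_model,
)
from .exposure import FEATURE_COLUMNS, InhalationTable, build_feature_table
from .metrics import relative_improvement
from .qr import (
    DEFAULT_TAU_GRID,
    SlidingQRModel,
    WindowSpec,
    band_table,
    band_table_marginals,
    err_tau_by_quantile,
    predict_quantile,
    sliding_window_run,
)
from .synth import CohortConfig, SyntheticPatient, simulate_cohort
from .zoning import critical_pefr, label_days

log = logging.getLogger(__name__)

__all__ = [
    "EngineConfig",
    "PredictionReport",
    "daily_decision",
    "run_pipeline",
    "read_cohort",
    "featurize_patient",
]

METRIC_COLUMNS = ["weighted_accuracy", "sensitivity", "specificity", "precision", "f1", "roc_auc"]


@dataclass
class EngineConfig:
    """Decision-engine parameters; all defaults are deliberate and visible.

    ``theta`` may be given directly (L/min) or left None, in which case it
    resolves to ``theta_fraction`` of the patient's median PEFR.
    """

    classification_threshold: float = 0.5
    tau_c: float = 0.2
    theta: Optional[float] = None
    theta_fraction: float = 0.05
    on_classification: Optional[Callable[[dict], None]] = None
    on_alert: Optional[Callable[[dict], None]] = None

    def __post_init__(self) -> None:
        if not 0 < self.tau_c < 1:
            raise ValueError("tau_c must be in (0, 1)")
        if self.theta is not None and self.theta < 0:
            raise ValueError("theta must be >= 0")

    def resolve_theta(self, median_pefr: float) -> float:
        return self.theta if self.theta is not None else self.theta_fraction * median_pefr


@dataclass
class PredictionReport:
    """One day's structured decision output."""

    date: object
    risk_class: str  # "risk" | "noRisk"
    probability: float
    pefr_tau_c: Optional[float] = None
    previous_pefr_tau_c: Optional[float] = None
    drop: Optional[float] = None
    alert: bool = False
    model_versions: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["date"] = str(self.date)
        return d


def daily_decision(
    clf: TLClassifier,
    qr_model: SlidingQRModel,
    today_features: np.ndarray,
    previous_pefr_tau_c: Optional[float],
    config: EngineConfig,
    *,
    theta: Optional[float] = None,
    date: object = None,
    qr_features: Optional[np.ndarray] = None,
) -> PredictionReport:
    """Run the four-step daily procedure for one patient-day.

    1. Classify next-day risk from today's features; below the threshold
       the quantile model is not consulted and the report says noRisk.
    2–3. Otherwise query the quantile model for PEFR(τ_c).
    4. Alert iff the new PEFR(τ_c) is below the previous one by more than θ.
    A report is always emitted; hooks are invoked with the step outcomes.
    """
    x = np.atleast_2d(np.asarray(today_features, dtype=float))
    _, p = clf.predict(x)
    p = float(p[0])
    versions = {"package": _pkg_version}
    theta_val = theta if theta is not None else config.resolve_theta(np.nan)
    if config.on_classification:
        config.on_classification({"date": date, "probability": p})

    if p < config.classification_threshold:
        return PredictionReport(
            date=date, risk_class="noRisk", probability=p, model_versions=versions
        )

    # the quantile model may use a reduced feature set (constant columns
    # carry no within-patient information and are dropped at fit time)
    xq = x if qr_features is None else np.atleast_2d(np.asarray(qr_features, dtype=float))
    pefr_tc = float(predict_quantile(qr_model, xq, config.tau_c)[0])
    drop: Optional[float] = None
    alert = False
    if previous_pefr_tau_c is None:
        log.warning("risk day with no previous PEFR(tau_c); drop undefined, no alert")
    else:
        drop = float(previous_pefr_tau_c - pefr_tc)
        alert = pefr_tc < previous_pefr_tau_c and drop > theta_val
    report = PredictionReport(
        date=date,
        risk_class="risk",
        probability=p,
        pefr_tau_c=pefr_tc,
        previous_pefr_tau_c=previous_pefr_tau_c,
        drop=drop,
        alert=alert,
        model_versions=versions,
    )
    if alert and config.on_alert:
        config.on_alert(report.to_dict())
    return report


# ---------------------------------------------------------------------------
# cohort I/O


def read_cohort(root: str | Path) -> List[SyntheticPatient]:
    """Read a cohort directory written by ``synth.write_cohort``."""
    root = Path(root)
    cov = pd.read_csv(root / "covariates.csv").set_index("patient_id")
    manifest = json.loads((root / "manifest.json").read_text())
    patients = []
    for entry in manifest["patients"]:
        pid = entry["patient_id"]
        pdir = root / pid
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                air_quality=pd.read_csv(pdir / "air_quality.csv", parse_dates=["timestamp"]),
                pefr_diary=pd.read_csv(pdir / "pefr.csv", parse_dates=["date"]),
                activity_diary=pd.read_csv(pdir / "activities.csv", parse_dates=["start", "end"]),
                covariates=cov.loc[pid].to_dict(),
            )
        )
    return patients


def featurize_patient(
    patient: SyntheticPatient,
    *,
    inh: Optional[InhalationTable] = None,
    risk_quantile: float = 0.2,
    zoning_history_frac: float = 0.8,
) -> pd.DataFrame:
    """Feature table + risk labels for one patient.

    PEFR_C is estimated once, from the chronologically first
    ``zoning_history_frac`` of days (the training era), and applied to all
    rows — re-estimating it on later data is an opt-in update hook, not the
    default.
    """
    table, report = build_feature_table(
        patient.air_quality, patient.pefr_diary, patient.activity_diary, patient.covariates, inh
    )
    if report.dropped_missing_pefr or report.dropped_incomplete_exposure:
        log.info(
            "%s: dropped %d rows (missing PEFR) / %d rows (incomplete exposure)",
            patient.patient_id,
            report.dropped_missing_pefr,
            report.dropped_incomplete_exposure,
        )
    if table.empty:
        return table
    n_hist = max(int(round(zoning_history_frac * len(table))), 1)
    history = table["am_pefr"].iloc[:n_hist]
    zoning = critical_pefr(history, risk_quantile)
    labeled = label_days(table, zoning)
    labeled.insert(0, "patient_id", patient.patient_id)
    return labeled


# ---------------------------------------------------------------------------
# end-to-end pipeline


def run_pipeline(
    config: CohortConfig,
    out_dir: str | Path,
    *,
    engine_config: Optional[EngineConfig] = None,
    hyperparams: Hyperparams = Hyperparams(),
    enable_classifier: bool = True,
    enable_qr: bool = True,
    classifier_targets: Optional[Sequence[str]] = None,
    qr_window: int = 45,
    qr_m: int = 7,
    tau_grid: Sequence[float] = DEFAULT_TAU_GRID,
    n_report_days: int = 7,
) -> Dict[str, object]:
    """Simulate (or load), featurize, label, train, evaluate and report.

    Writes per-patient metrics (Table-4-shaped summary), the band-averaged
    quantile-calibration table, daily decision reports for each evaluated
    patient, and a manifest of versions and seeds.  Fully reproducible from
    ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    engine_config = engine_config or EngineConfig()
    seed = config.seed

    cohort = simulate_cohort(config)
    tables = {p.patient_id: featurize_patient(p, risk_quantile=config.risk_quantile) for p in cohort}
    all_rows = pd.concat(tables.values())
    all_rows.reset_index().to_csv(out / "daily_features.csv", index=False)

    artifacts: Dict[str, object] = {"features": all_rows}
    metric_rows = []
    reports_out = []

    if enable_classifier:
        targets = list(classifier_targets or tables.keys())
        for t_i, pid in enumerate(targets):
            target_rows = tables[pid]
            pooled = all_rows[all_rows["patient_id"] != pid]
            try:
                source = train_source_model(
                    pooled[FEATURE_COLUMNS].to_numpy(float),
                    pooled["label"].to_numpy(int),
                    pooled["patient_id"],
                    excluded_patient=pid,
                    hyperparams=hyperparams,
                    seed=seed + t_i,
                )
                for pipe in ("lr", "tl+lr"):
                    rep, _, clf = evaluate_split(
                        target_rows,
                        pipe,
                        seed=seed + t_i,
                        source=source,
                        hyperparams=hyperparams,
                    )
                    metric_rows.append({"patient_id": pid, "method": pipe, **rep.to_dict()})
                    if pipe == "tl+lr" and enable_qr:
                        reports_out.extend(
                            _daily_reports(
                                target_rows, clf, engine_config, qr_window, qr_m, n_report_days
                            )
                        )
            except ValueError as e:
                raise RuntimeError(f"classifier stage failed for {pid}: {e}") from e
        metrics = pd.DataFrame(metric_rows)
        summary = (
            metrics.groupby("method")[METRIC_COLUMNS].mean().reindex(["lr", "tl+lr"])
        )
        gains = {
            m: relative_improvement(summary.loc["lr", m], summary.loc["tl+lr", m])
            for m in METRIC_COLUMNS
            if pd.notna(summary.loc["lr", m]) and summary.loc["lr", m] > 0
        }
        metrics.to_csv(out / "classifier_metrics.csv", index=False)
        summary.to_csv(out / "classifier_summary.csv")
        artifacts.update(metrics=metrics, summary=summary, gains=gains)
        if reports_out:
            (out / "daily_reports.json").write_text(
                json.dumps([r.to_dict() for r in reports_out], indent=2)
            )
            artifacts["daily_reports"] = reports_out

    if enable_qr:
        per_patient = []
        for pid, rows in tables.items():
            if len(rows) <= qr_window:
                log.warning("%s: too few rows for W=%d, skipped in QR", pid, qr_window)
                continue
            spec = WindowSpec.from_window(qr_window, qr_m)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, preds = sliding_window_run(
                    rows, spec, tau_grid, feature_cols=FEATURE_COLUMNS
                )
            per_patient.append(err_tau_by_quantile(preds, tau_grid))
        if per_patient:
            mean_err = pd.concat(per_patient, axis=1).mean(axis=1).to_frame(qr_window)
            qr_table = band_table_marginals(band_table(mean_err))
            qr_table.to_csv(out / "qr_err_table.csv")
            artifacts["qr_err_table"] = qr_table

    manifest = {
        "package_version": _pkg_version,
        "seed": seed,
        "n_patients": config.n_patients,
        "stages": {
            "classifier": enable_classifier,
            "qr": enable_qr,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return artifacts


def _daily_reports(
    rows: pd.DataFrame,
    clf: TLClassifier,
    engine_config: EngineConfig,
    qr_window: int,
    qr_m: int,
    n_days: int,
) -> List[PredictionReport]:
    """Decision reports for the final ``n_days`` of one patient's series."""
    if len(rows) <= qr_window + n_days:
        return []
    spec = WindowSpec.from_window(qr_window, qr_m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models, _ = sliding_window_run(
            rows.iloc[: len(rows) - n_days + qr_window], spec, (engine_config.tau_c,),
            feature_cols=FEATURE_COLUMNS,
        )
    qr_model = models[-1]
    theta = engine_config.resolve_theta(float(rows["am_pefr"].median()))
    reports = []
    prev: Optional[float] = None
    for date, row in rows.iloc[-n_days:].iterrows():
        rep = daily_decision(
            clf,
            qr_model,
            row[FEATURE_COLUMNS].to_numpy(float),
            prev,
            engine_config,
            theta=theta,
            date=date,
            qr_features=row[qr_model.feature_names].to_numpy(float),
        )
        if rep.pefr_tau_c is not None:
            prev = rep.pefr_tau_c
        reports.append(rep)
    return reports
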