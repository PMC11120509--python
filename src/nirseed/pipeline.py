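"""End-to-end experiment matrices: pretreatment × classifier and selector × PLS-DA.

Two orchestrated studies mirror the harvest-year analysis:

* :func:`run_model_comparison` — every pretreatment (raw, SGS, SNV, MSC,
  SG-D1, SG-D2, Norm) crossed with every classifier (PLS-DA, LS-SVM, KNN,
  ELM) on the full wavelength grid.
* :func:`run_selection_comparison` — a fixed pretreatment (Norm by default)
  with each wavelength selector (MC-UVE, CARS, BOSS, SPA, MC-UVE→SPA,
  MC-UVE→BOSS) feeding a PLS-DA model.

All stages train strictly on the training set (MSC references, CV folds,
selector fits); the prediction set only ever contributes its spectra at
predict time.  A master seed derives every stage seed through a fixed
offset table, so a whole run is a pure function of (dataset, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import selection as sel
from .io import SpectralDataset
from .preprocess import PretreatmentSpec, apply_pretreatment, canonical_name

__all__ = [
    "ExperimentConfig", "ReportRow", "STAGE_SEED_OFFSETS",
    "run_model_comparison", "run_selection_comparison", "report_write",
    "MODELS", "SELECTOR_CHOICES",
]

log = logging.getLogger("nirseed")

#: Fixed stage-seed derivation: stage seed = master_seed + offset.
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "partition": 1,
    "cv": 2,
    "mcuve": 3,
    "cars": 4,
    "boss": 5,
    "spa": 6,
    "elm": 7,
}

MODELS = ("plsda", "lssvm", "knn", "elm")
SELECTOR_CHOICES = ("mcuve", "cars", "boss", "spa", "mcuve+spa", "mcuve+boss")


@dataclass
class ExperimentConfig:
    """Settings of one orchestrated run."""

    pretreatments: tuple = ("raw", "SGS", "SNV", "MSC", "SG-D1", "SG-D2", "Norm")
    models: tuple = MODELS
    selectors: tuple = SELECTOR_CHOICES
    selection_pretreatment: str = "Norm"
    train_fraction: float = 0.8
    folds: int = 10
    master_seed: int = 0
    max_lv: int = 10
    lssvm_gamma_grid: np.ndarray | None = None
    lssvm_sigma2_grid: np.ndarray | None = None
    knn_k_candidates: tuple = tuple(range(1, 16))
    elm_hidden_grid: tuple = tuple(range(10, 151, 10))
    selector_params: dict = field(default_factory=dict)

    def stage_seed(self, stage: str) -> int:
        return int(self.master_seed) + STAGE_SEED_OFFSETS[stage]


@dataclass
class ReportRow:
    model: str
    preprocessing: str
    selector: str
    n_wavelengths: int
    hyperparameters: str
    train_acc_neg: float
    train_acc_pos: float
    train_acc_total: float
    pred_acc_neg: float
    pred_acc_pos: float
    pred_acc_total: float

    def __post_init__(self) -> None:
        for v in (self.train_acc_neg, self.train_acc_pos, self.train_acc_total,
                  self.pred_acc_neg, self.pred_acc_pos, self.pred_acc_total):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"accuracy {v} outside [0, 100]")


def _pretreat_pair(name: str, train: SpectralDataset, pred: SpectralDataset):
    spec = PretreatmentSpec(name=name)
    spacing = float(np.mean(np.diff(train.wavelengths)))
    Xtr = apply_pretreatment(spec, train.X, fit_context=train.X, spacing=spacing)
    Xpr = apply_pretreatment(spec, pred.X, fit_context=train.X, spacing=spacing)
    return Xtr, Xpr


def _fit_predict_model(model_name: str, Xtr, ytr, Xpr, config: ExperimentConfig):
    """Tune+fit one classifier on the training set; return predictions + params."""
    seed = config.stage_seed("cv")
    if model_name == "plsda":
        n_lv, _ = clf.choose_lvs(Xtr, ytr, max_lv=config.max_lv, k=config.folds, seed=seed)
        model = clf.plsda_fit(Xtr, ytr, n_lv)
        return (clf.plsda_predict(model, Xtr)[1], clf.plsda_predict(model, Xpr)[1],
                f"LVs={n_lv}", {"n_lv": n_lv})
    if model_name == "lssvm":
        model, cv = clf.lssvm_tune(Xtr, ytr, config.lssvm_gamma_grid,
                                   config.lssvm_sigma2_grid, k=config.folds, seed=seed)
        return (clf.lssvm_predict(model, Xtr)[1], clf.lssvm_predict(model, Xpr)[1],
                f"gamma={model.gamma:g};sigma2={model.sigma2:g}", cv.params)
    if model_name == "knn":
        model, cv = clf.knn_tune_fit(Xtr, ytr, k_candidates=config.knn_k_candidates,
                                     folds=config.folds, seed=seed)
        return (clf.knn_predict(model, Xtr), clf.knn_predict(model, Xpr),
                f"K={model.k};metric={model.metric}", cv.params)
    if model_name == "elm":
        model, cv = clf.elm_tune(Xtr, ytr, hidden_grid=config.elm_hidden_grid,
                                 folds=config.folds, seed=config.stage_seed("elm"))
        return (clf.elm_predict(model, Xtr)[1], clf.elm_predict(model, Xpr)[1],
                f"hidden={model.n_hidden}", cv.params)
    raise ValueError(f"unknown model {model_name!r}")


def _row(model_name, pre_name, selector, n_wl, hyper, ytr, ptr, ypr, ppr) -> ReportRow:
    tr = clf.class_accuracy(ytr, ptr)
    pr = clf.class_accuracy(ypr, ppr)
    return ReportRow(model=model_name, preprocessing=pre_name, selector=selector,
                     n_wavelengths=n_wl, hyperparameters=hyper,
                     train_acc_neg=tr[0], train_acc_pos=tr[1], train_acc_total=tr[2],
                     pred_acc_neg=pr[0], pred_acc_pos=pr[1], pred_acc_total=pr[2])


def run_model_comparison(train: SpectralDataset, pred: SpectralDataset,
                         config: ExperimentConfig) -> list[ReportRow]:
    """Pretreatment × classifier matrix on the full wavelength grid."""
    rows = []
    for pre_name in config.pretreatments:
        pre_name = canonical_name(pre_name)
        Xtr, Xpr = _pretreat_pair(pre_name, train, pred)
        for model_name in config.models:
            try:
                ptr, ppr, hyper, _ = _fit_predict_model(model_name, Xtr, train.y, Xpr, config)
            except Exception as exc:
                raise RuntimeError(
                    f"model comparison failed at ({pre_name}, {model_name}): {exc}"
                ) from exc
            row = _row(model_name, pre_name, "none", train.n_channels, hyper,
                       train.y, ptr, pred.y, ppr)
            rows.append(row)
            log.info("model=%s pre=%s hyper=%s pred_total=%.2f",
                     model_name, pre_name, hyper, row.pred_acc_total)
    return rows


def _selector_stages(selector: str, config: ExperimentConfig) -> list:
    """Translate a selector choice into chain stages with derived seeds."""
    user = config.selector_params
    def stage(name):
        kwargs = dict(user.get(name, {}))
        kwargs.setdefault("seed", config.stage_seed(name))
        if name in ("cars", "boss", "spa"):
            kwargs.setdefault("folds", config.folds)
        return (name, kwargs)
    parts = selector.split("+")
    bad = [p for p in parts if p not in sel.SELECTORS]
    if bad:
        raise ValueError(f"unknown selector(s) {bad} in {selector!r}")
    return [stage(p) for p in parts]


def run_selection_comparison(train: SpectralDataset, pred: SpectralDataset,
                             config: ExperimentConfig) -> list[ReportRow]:
    """Selector × PLS-DA matrix on a fixed pretreatment (Norm by default)."""
    pre_name = canonical_name(config.selection_pretreatment)
    Xtr, Xpr = _pretreat_pair(pre_name, train, pred)
    rows = []
    for selector in config.selectors:
        stages = _selector_stages(selector, config)
        try:
            subset = sel.chain_select(stages, Xtr, train.y)
            n_lv, _ = clf.choose_lvs(Xtr[:, subset.indices], train.y,
                                     max_lv=config.max_lv, k=config.folds,
                                     seed=config.stage_seed("cv"))
            model = clf.plsda_fit(Xtr[:, subset.indices], train.y, n_lv)
            ptr = clf.plsda_predict(model, Xtr[:, subset.indices])[1]
            ppr = clf.plsda_predict(model, Xpr[:, subset.indices])[1]
        except Exception as exc:
            raise RuntimeError(
                f"selection comparison failed at ({pre_name}, {selector}): {exc}"
            ) from exc
        row = _row("plsda", pre_name, subset.method, subset.n_wavelengths,
                   f"LVs={n_lv}", train.y, ptr, pred.y, ppr)
        rows.append(row)
        log.info("selector=%s n_wl=%d LVs=%d pred_total=%.2f",
                 subset.method, subset.n_wavelengths, n_lv, row.pred_acc_total)
    return rows


_REPORT_COLUMNS = [
    "model", "preprocessing", "selector", "n_wavelengths", "hyperparameters",
    "train_acc_neg", "train_acc_pos", "train_acc_total",
    "pred_acc_neg", "pred_acc_pos", "pred_acc_total",
]


def report_write(rows: list[ReportRow], path) -> pd.DataFrame:
    """Write the report CSV (percentages to 2 decimals); returns the frame."""
    if not rows:
        raise ValueError("no report rows")
    frame = pd.DataFrame([vars(r) for r in rows], columns=_REPORT_COLUMNS)
    out = frame.copy()
    for col in _REPORT_COLUMNS[5:]:
        out[col] = out[col].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)
    return frame
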