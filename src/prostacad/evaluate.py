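"""Evaluation: metrics, cross-validation harness, and pipeline integration.

The experimental protocol: a stratified 85/15 training/test split of the
cohort, 5-fold cross-validation inside the 85% (feature selection and model
fitting per fold on the fold-train portion only), and final test metrics
from a model refit on the full 85%. Metrics are AUC-ROC, sensitivity and
specificity with the malignant class positive. Lesion-level instances
inherit their case's split assignment so no case ever contributes to both
sides of a fold.

Pipeline integration emulates an external lesion-segmentation pipeline
(EmulatedSegmenter): it returns the ground-truth lesion masks corrupted by a
configurable false-negative drop rate and a false-positive proposal rate.
Mode 1 places a whole-image/gland/zone classifier upstream as a filter —
cases predicted lesion-free skip segmentation and are labelled benign.
Mode 2 places a lesion classifier downstream — every proposed lesion is
classified and the case is malignant iff any proposal is called malignant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from prostacad.classify import ModelSpec, TrainedClassifier, train
from prostacad.features import FeatureConfig, extract_study_features, feature_matrix
from prostacad.phantom import _sphere_mask, _physical_coords
from prostacad.regions import bounding_box, extract_region_inputs, resize_to, DEFAULT_REGION_SHAPES
from prostacad.selection import SelectionModel
from prostacad.volume import MRIVolume, StudyCase
from prostacad.windows import build_heatmap, choose_cutoff, label_window, make_windows

# ---------------------------------------------------------------- metrics


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC-ROC = P(score_pos > score_neg) + 0.5 P(tie) over pos/neg pairs."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def sens_spec(pred_labels: Sequence[int], true_labels: Sequence[int]
              ) -> tuple[float, float]:
    """(sensitivity, specificity) with malignant (1) as the positive class.

    When a class is absent the corresponding rate is undefined and reported
    as NaN rather than 0.
    """
    pred = np.asarray(pred_labels).astype(int)
    true = np.asarray(true_labels).astype(int)
    tp = int(((pred == 1) & (true == 1)).sum())
    fn = int(((pred == 0) & (true == 1)).sum())
    tn = int(((pred == 0) & (true == 0)).sum())
    fp = int(((pred == 1) & (true == 0)).sum())
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return sens, spec


# ----------------------------------------------------------- split plan


@dataclass
class SplitPlan:
    """Stratified 85/15 train/test split plus 5 CV folds over the 85%."""

    test_fraction: float = 0.15
    n_folds: int = 5
    seed: int = 0

    def assign(self, labels: Sequence[int]) -> dict:
        """Per-case assignments: held-out test indices and (train, val) folds."""
        labels = np.asarray(labels).astype(int)
        idx = np.arange(len(labels))
        train_idx, test_idx = train_test_split(
            idx, test_size=self.test_fraction, random_state=self.seed,
            stratify=labels)
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.seed)
        folds = [(train_idx[tr], train_idx[va])
                 for tr, va in skf.split(train_idx, labels[train_idx])]
        return {"train": np.sort(train_idx), "test": np.sort(test_idx),
                "folds": folds}


@dataclass
class EvalReport:
    """AUC-ROC / sensitivity / specificity per fold and on the held-out test."""

    mode: str
    fold_metrics: pd.DataFrame                   # columns: fold, auc, sensitivity, specificity
    test_metrics: dict
    extras: dict = field(default_factory=dict)

    def mean_sd(self) -> dict:
        out = {}
        for m in ("auc", "sensitivity", "specificity"):
            if m in self.fold_metrics:
                out[m] = {"mean": float(self.fold_metrics[m].mean()),
                          "sd": float(self.fold_metrics[m].std(ddof=1))
                          if len(self.fold_metrics) > 1 else 0.0}
        return out

    def to_dict(self) -> dict:
        return {"mode": self.mode,
                "fold_metrics": self.fold_metrics.to_dict(orient="records"),
                "cv_summary": self.mean_sd(),
                "test_metrics": self.test_metrics,
                "extras": self.extras}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, allow_nan=True)

    def summary(self) -> str:
        lines = [f"EvalReport (mode={self.mode})"]
        for m, s in self.mean_sd().items():
            lines.append(f"  CV {m:12s}: {s['mean']:.4f} ± {s['sd']:.4f}")
        for k, v in self.test_metrics.items():
            if isinstance(v, float):
                lines.append(f"  test {k:10s}: {v:.4f}")
            else:
                lines.append(f"  test {k:10s}: {v}")
        return "\n".join(lines)


# -------------------------------------------------- standalone pipelines


@dataclass
class PipelineConfig:
    """One standalone experiment: region → features → selection → model."""

    region_kind: str = "whole"
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    selection_kind: str = "pca"          # "pca" | "mrmr" | "none"
    selection_k: int = 95
    model_spec: ModelSpec = field(default_factory=lambda: ModelSpec(family="svm"))
    threshold: float = 0.5
    region_shapes: Optional[dict] = None
    # cap the retained dimensionality at what the training rows support
    # (k <= n_train - 1 for PCA); the requested k applies whenever feasible
    adapt_k: bool = True

    def make_selection(self, n_train: Optional[int] = None,
                       n_features: Optional[int] = None) -> SelectionModel:
        if self.selection_kind == "none":
            return SelectionModel(kind="none")
        k = self.selection_k
        if self.adapt_k and n_train is not None:
            bound = n_train - 1 if self.selection_kind == "pca" else n_train
            if n_features is not None:
                bound = min(bound, n_features)
            k = max(1, min(k, bound))
        return SelectionModel(kind=self.selection_kind, k=k)


def region_feature_table(cases: Sequence[StudyCase], cfg: PipelineConfig
                         ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Feature matrix, labels and case indices for all region instances."""
    fvs, labels, case_idx = [], [], []
    for i, case in enumerate(cases):
        for ri in extract_region_inputs(case, cfg.region_kind, cfg.region_shapes):
            fvs.append(extract_study_features(ri.volumes, cfg.feature_config))
            labels.append(ri.label)
            case_idx.append(i)
    X = feature_matrix(fvs)
    return X, np.asarray(labels, dtype=int), np.asarray(case_idx, dtype=int)


def _fit_and_score(X: pd.DataFrame, y: np.ndarray, rows_tr: np.ndarray,
                   rows_ev: np.ndarray, cfg: PipelineConfig) -> dict:
    """Fit selection+model on training rows, score evaluation rows."""
    if len(np.unique(y[rows_tr])) < 2:
        raise ValueError("stratification failure: single-class training rows")
    sel = cfg.make_selection(n_train=len(rows_tr), n_features=X.shape[1])
    Xtr = sel.fit_transform(X.iloc[rows_tr].to_numpy(), y[rows_tr])
    model = train(Xtr, y[rows_tr], cfg.model_spec)
    Xev = sel.transform(X.iloc[rows_ev].to_numpy())
    scores = model.predict_proba(Xev)
    pred = (scores >= cfg.threshold).astype(int)
    out = {"scores": scores, "pred": pred, "selection": sel, "model": model}
    if len(np.unique(y[rows_ev])) > 1:
        out["auc"] = auc_roc(scores, y[rows_ev])
    else:
        out["auc"] = float("nan")
    out["sensitivity"], out["specificity"] = sens_spec(pred, y[rows_ev])
    return out


def cross_validate(cases: Sequence[StudyCase], cfg: PipelineConfig,
                   plan: Optional[SplitPlan] = None) -> EvalReport:
    """Leakage-safe cross-validated evaluation of one standalone pipeline.

    The split plan is stratified at case level; lesion instances inherit
    their case's assignment. Selection and model are refit per fold on the
    fold-train rows only; final test metrics come from a refit on all
    training rows.
    """
    plan = plan or SplitPlan()
    case_labels = np.array([c.case_label for c in cases], dtype=int)
    assign = plan.assign(case_labels)
    X, y, case_idx = region_feature_table(cases, cfg)
    if X.empty:
        raise ValueError("no region instances extracted from the cohort")

    def rows_of(case_set):
        mask = np.isin(case_idx, case_set)
        return np.nonzero(mask)[0]

    fold_rows = []
    for f, (tr_cases, va_cases) in enumerate(assign["folds"]):
        res = _fit_and_score(X, y, rows_of(tr_cases), rows_of(va_cases), cfg)
        fold_rows.append({"fold": f, "auc": res["auc"],
                          "sensitivity": res["sensitivity"],
                          "specificity": res["specificity"]})
    fold_df = pd.DataFrame(fold_rows)

    final = _fit_and_score(X, y, rows_of(assign["train"]), rows_of(assign["test"]), cfg)
    test_metrics = {"auc": final["auc"], "sensitivity": final["sensitivity"],
                    "specificity": final["specificity"],
                    "n_test_instances": int(len(rows_of(assign["test"])))}
    return EvalReport(mode="standalone", fold_metrics=fold_df,
                      test_metrics=test_metrics,
                      extras={"region_kind": cfg.region_kind,
                              "selection": cfg.selection_kind,
                              "selection_k": cfg.selection_k,
                              "family": cfg.model_spec.family,
                              "seed": plan.seed,
                              "fitted_selection": final["selection"],
                              "fitted_model": final["model"]})


# ------------------------------------------------------ emulated pipeline


@dataclass
class EmulatedSegmenter:
    """Stand-in for an external lesion-segmentation pipeline.

    Returns the ground-truth lesion masks, dropping each with probability
    ``fn_rate`` and adding ``~Poisson(fp_rate)`` false spherical proposals
    inside the gland. With both rates zero it returns the ground truth
    exactly. Proposals are deterministic per (seed, case index).
    """

    fp_rate: float = 1.0
    fn_rate: float = 0.0
    fp_radius_mm: tuple[float, float] = (4.0, 8.0)
    seed: int = 0

    def propose(self, case: StudyCase, case_index: int
                ) -> list[tuple[np.ndarray, int]]:
        """Proposals as (mask, true_label) pairs; false proposals have label 0."""
        rng = np.random.default_rng([self.seed, case_index])
        out = []
        for mask, lab in case.lesion_masks:
            if rng.random() >= self.fn_rate:
                out.append((mask, int(lab)))
        n_fp = rng.poisson(self.fp_rate)
        if n_fp and case.gland_mask is not None and case.gland_mask.any():
            gland_idx = np.argwhere(case.gland_mask > 0)
            coords = _physical_coords(case.shape, case.spacing_mm)
            for _ in range(n_fp):
                vx = gland_idx[rng.integers(len(gland_idx))]
                center = tuple(coords[a][vx[a]] for a in range(3))
                radius = rng.uniform(*self.fp_radius_mm)
                m = _sphere_mask(case.shape, case.spacing_mm, center, radius)
                m &= case.gland_mask.astype(m.dtype)
                if m.any():
                    out.append((m, 0))
        return out


def baseline_labels(cases: Sequence[StudyCase], segmenter: EmulatedSegmenter
                    ) -> np.ndarray:
    """Segmenter-only case labels: malignant iff any lesion is proposed."""
    return np.array([int(len(segmenter.propose(c, i)) > 0)
                     for i, c in enumerate(cases)], dtype=int)


@dataclass
class RegionClassifierBundle:
    """A trained standalone pipeline packaged for in-pipeline use."""

    region_kind: str
    feature_config: FeatureConfig
    selection: SelectionModel
    model: TrainedClassifier
    threshold: float = 0.5
    region_shapes: Optional[dict] = None

    def score_case(self, case: StudyCase) -> float:
        inputs = extract_region_inputs(case, self.region_kind, self.region_shapes)
        if not inputs:
            return 0.0
        fvs = [extract_study_features(ri.volumes, self.feature_config) for ri in inputs]
        Xs = self.selection.transform(np.vstack([f.values for f in fvs]))
        return float(self.model.predict_proba(Xs).max())

    def predict_case(self, case: StudyCase) -> int:
        return int(self.score_case(case) >= self.threshold)

    def score_proposal(self, case: StudyCase, mask: np.ndarray) -> float:
        shapes = dict(DEFAULT_REGION_SHAPES)
        if self.region_shapes:
            shapes.update(self.region_shapes)
        box = bounding_box(mask, (2, 2, 0), kind="lesion")
        vols = {m: MRIVolume(data=resize_to(v.data[box.slices()], shapes["lesion"]),
                             spacing_mm=v.spacing_mm, modality=m)
                for m, v in case.sequences().items()}
        fv = extract_study_features(vols, self.feature_config)
        Xs = self.selection.transform(fv.values[None, :])
        return float(self.model.predict_proba(Xs)[0])


def bundle_from_report(report: EvalReport, cfg: PipelineConfig) -> RegionClassifierBundle:
    """Package the final refit selection+model of a cross_validate report."""
    return RegionClassifierBundle(
        region_kind=cfg.region_kind, feature_config=cfg.feature_config,
        selection=report.extras["fitted_selection"],
        model=report.extras["fitted_model"], threshold=cfg.threshold,
        region_shapes=cfg.region_shapes)


def _case_report(pred: np.ndarray, truth: np.ndarray, mode: str, extras: dict
                 ) -> EvalReport:
    sens, spec = sens_spec(pred, truth)
    metrics = {"sensitivity": sens, "specificity": spec}
    if len(np.unique(truth)) > 1:
        metrics["auc"] = auc_roc(pred.astype(float), truth)
    return EvalReport(mode=mode, fold_metrics=pd.DataFrame(), test_metrics=metrics,
                      extras=extras)


def run_mode1(cases: Sequence[StudyCase],
              classifier: RegionClassifierBundle | str | Callable[[StudyCase], int],
              segmenter: EmulatedSegmenter) -> EvalReport:
    """Upstream filter evaluation (whole/gland/zone classifier before
    segmentation).

    Cases the classifier predicts lesion-free get the final label 0 and skip
    the segmenter (the skip count is reported); the rest receive the
    segmenter-only label. ``classifier`` may be a trained bundle, a callable
    case → {0,1}, or one of the contract strings "always_pass",
    "always_block", "oracle".
    """
    truth = np.array([c.case_label for c in cases], dtype=int)
    decide = _case_decider(classifier)
    pred = np.zeros(len(cases), dtype=int)
    skipped = 0
    for i, case in enumerate(cases):
        if decide(case) == 0:
            pred[i] = 0
            skipped += 1
        else:
            pred[i] = int(len(segmenter.propose(case, i)) > 0)
    return _case_report(pred, truth, "pipeline_mode1",
                        {"skipped": skipped, "n_cases": len(cases),
                         "segmenter": {"fp_rate": segmenter.fp_rate,
                                       "fn_rate": segmenter.fn_rate,
                                       "seed": segmenter.seed}})


def _case_decider(classifier) -> Callable[[StudyCase], int]:
    if classifier == "always_pass":
        return lambda case: 1
    if classifier == "always_block":
        return lambda case: 0
    if classifier == "oracle":
        return lambda case: case.case_label
    if isinstance(classifier, RegionClassifierBundle):
        return classifier.predict_case
    if callable(classifier):
        return classifier
    raise ValueError(f"unsupported classifier argument: {classifier!r}")


def run_mode2(cases: Sequence[StudyCase],
              lesion_classifier: RegionClassifierBundle | str,
              segmenter: EmulatedSegmenter) -> EvalReport:
    """Downstream lesion-proposal classification (mode 2).

    Every proposal from the segmenter is classified; the case is malignant
    iff any proposal is classified malignant. ``lesion_classifier`` may be a
    trained lesion bundle, "oracle" (uses each proposal's true label) or
    "always_malignant".
    """
    truth = np.array([c.case_label for c in cases], dtype=int)
    pred = np.zeros(len(cases), dtype=int)
    for i, case in enumerate(cases):
        proposals = segmenter.propose(case, i)
        labs = []
        for mask, true_lab in proposals:
            if lesion_classifier == "oracle":
                labs.append(int(true_lab))
            elif lesion_classifier == "always_malignant":
                labs.append(1)
            elif isinstance(lesion_classifier, RegionClassifierBundle):
                s = lesion_classifier.score_proposal(case, mask)
                labs.append(int(s >= lesion_classifier.threshold))
            else:
                raise ValueError(f"unsupported lesion classifier: {lesion_classifier!r}")
        pred[i] = int(any(l == 1 for l in labs))
    return _case_report(pred, truth, "pipeline_mode2",
                        {"n_cases": len(cases),
                         "segmenter": {"fp_rate": segmenter.fp_rate,
                                       "fn_rate": segmenter.fn_rate,
                                       "seed": segmenter.seed}})


# --------------------------------------------- sliding-window evaluation


def window_feature_table(case: StudyCase, cfg: PipelineConfig,
                         window_shape, overlap: float = 0.5):
    """Per-window study features and three-way labels for one case."""
    grid = make_windows(case.shape, window_shape, overlap)
    fvs, labels = [], []
    for box in grid.boxes:
        vols = {m: MRIVolume(data=v.data[box.slices()], spacing_mm=v.spacing_mm,
                             modality=m)
                for m, v in case.sequences().items()}
        fvs.append(extract_study_features(vols, cfg.feature_config))
        labels.append(label_window(box, case.lesion_masks))
    return grid, feature_matrix(fvs), labels


def sliding_window_cv(cases: Sequence[StudyCase], cfg: PipelineConfig,
                      plan: Optional[SplitPlan] = None,
                      window_shape=(70, 65, 3), overlap: float = 0.5) -> EvalReport:
    """Localization-free evaluation: window classifier → heatmap → cutoff.

    Windows are trained malignant-vs-rest (background and benign windows
    merged into the negative class; the three-way labels are retained in the
    window tables). Per held-out case the window confidences form a heatmap;
    the image-level score is the heatmap maximum, the ROC cutoff is chosen
    on the training cases by Youden's J, and metrics are case-level.
    """
    plan = plan or SplitPlan()
    case_labels = np.array([c.case_label for c in cases], dtype=int)
    assign = plan.assign(case_labels)

    tables = [window_feature_table(c, cfg, window_shape, overlap) for c in cases]
    y_win = [np.array([1 if l == "malignant" else 0 for l in labels])
             for _, _, labels in tables]

    def case_scores(model, sel, case_ids):
        """Image-level score per case: max of its mean-accumulated heatmap."""
        out = []
        for i in case_ids:
            grid, X, _ = tables[i]
            scores = model.predict_proba(sel.transform(X.to_numpy()))
            hm = build_heatmap(grid, scores)
            out.append(float(hm.confidence.max()))
        return np.asarray(out)

    def fit_on(case_ids):
        Xtr = pd.concat([tables[i][1] for i in case_ids], ignore_index=True)
        ytr = np.concatenate([y_win[i] for i in case_ids])
        if len(np.unique(ytr)) < 2:
            raise ValueError("training windows contain a single class")
        sel = cfg.make_selection(n_train=len(ytr), n_features=Xtr.shape[1])
        Xs = sel.fit_transform(Xtr.to_numpy(), ytr)
        return train(Xs, ytr, cfg.model_spec), sel

    fold_rows = []
    for f, (tr_cases, va_cases) in enumerate(assign["folds"]):
        model, sel = fit_on(tr_cases)
        s_tr = case_scores(model, sel, tr_cases)
        cutoff, _ = choose_cutoff(s_tr, case_labels[tr_cases])
        s_va = case_scores(model, sel, va_cases)
        pred = (s_va > cutoff).astype(int)
        auc = auc_roc(s_va, case_labels[va_cases]) \
            if len(np.unique(case_labels[va_cases])) > 1 else float("nan")
        sens, spec = sens_spec(pred, case_labels[va_cases])
        fold_rows.append({"fold": f, "auc": auc, "sensitivity": sens,
                          "specificity": spec, "cutoff": cutoff})
    fold_df = pd.DataFrame(fold_rows)

    model, sel = fit_on(assign["train"])
    s_tr = case_scores(model, sel, assign["train"])
    cutoff, cut_info = choose_cutoff(s_tr, case_labels[assign["train"]])
    s_te = case_scores(model, sel, assign["test"])
    pred = (s_te > cutoff).astype(int)
    test = {"sensitivity": sens_spec(pred, case_labels[assign["test"]])[0],
            "specificity": sens_spec(pred, case_labels[assign["test"]])[1],
            "cutoff": cutoff, **{f"cutoff_{k}": v for k, v in cut_info.items()}}
    if len(np.unique(case_labels[assign["test"]])) > 1:
        test["auc"] = auc_roc(s_te, case_labels[assign["test"]])
    return EvalReport(mode="standalone", fold_metrics=fold_df, test_metrics=test,
                      extras={"region_kind": "sliding_window",
                              "window_shape": list(window_shape),
                              "overlap": overlap, "seed": plan.seed})


def cohort_checksum(cases: Sequence[StudyCase]) -> str:
    """SHA-256 over all volumes and masks; used to prove evaluation data
    are untouched by training."""
    h = hashlib.sha256()
    for c in cases:
        for v in c.sequences().values():
            h.update(np.ascontiguousarray(v.data).tobytes())
        for m in c._all_masks():
            h.update(np.ascontiguousarray(m).tobytes())
        h.update(bytes([c.case_label]))
    return h.hexdigest()
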