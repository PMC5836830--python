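"""Class-weighted C-SVC on precomputed Grams, k-fold CV, and grid search.

The solver is libsvm via scikit-learn's ``SVC(kernel="precomputed")``; the
contract kept here is the asymmetric box constraint (positive dual
coefficients bounded by C+ for positives, negative ones by -C- for
negatives) and the decision rule: predict +1 iff the decision value is >= 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_model_io import LabeledPairSet, Pair
from .feature_maps import psi_matrix
from .kernels import GramMatrix, KernelInputs, KernelSpec, pair_component_gram


class EvaluationError(ValueError):
    pass


@dataclass
class CsvcModel:
    """Fitted class-weighted C-SVC over a precomputed Gram.

    ``dual_coefficients[i]`` is the signed dual variable of training pair i:
    in [0, c_pos] for positive examples, in [-c_neg, 0] for negatives.
    """

    dual_coefficients: np.ndarray
    bias: float
    training_pair_ids: list[Pair]
    c_pos: float
    c_neg: float


def fit(
    train_gram: GramMatrix, labels: np.ndarray, c_pos: float, c_neg: float
) -> CsvcModel:
    """Train a C-SVC with per-class penalties on a square training Gram."""
    labels = np.asarray(labels)
    if not train_gram.is_square:
        raise EvaluationError("training Gram must be square (row_pairs == col_pairs)")
    if c_pos <= 0 or c_neg <= 0:
        raise EvaluationError("c_pos and c_neg must be positive")
    if len(np.unique(labels)) < 2:
        raise EvaluationError("training labels contain a single class")
    svc = SVC(kernel="precomputed", C=1.0, class_weight={1: c_pos, -1: c_neg})
    svc.fit(train_gram.entries, labels)
    dual = np.zeros(len(labels))
    dual[svc.support_] = svc.dual_coef_[0]
    return CsvcModel(
        dual_coefficients=dual,
        bias=float(svc.intercept_[0]),
        training_pair_ids=list(train_gram.row_pairs),
        c_pos=float(c_pos),
        c_neg=float(c_neg),
    )


def decision_values(model: CsvcModel, cross_gram: GramMatrix) -> np.ndarray:
    if cross_gram.col_pairs != model.training_pair_ids:
        raise EvaluationError("cross Gram columns do not match training pair ids")
    return cross_gram.entries @ model.dual_coefficients + model.bias


def predict(model: CsvcModel, cross_gram: GramMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, decision values); label +1 iff decision >= 0."""
    dec = decision_values(model, cross_gram)
    labels = np.where(dec >= 0, 1, -1).astype(np.int64)
    return labels, dec


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F-measure with zero-division conventions -> 0."""
    if tp < 0 or fp < 0 or fn < 0:
        raise EvaluationError("counts must be nonnegative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    else:
        f = 0.0
    return precision, recall, f


@dataclass
class FoldResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float


@dataclass
class EvaluationReport:
    """Per-fold and fold-averaged precision/recall/F plus the run config."""

    per_fold: list[FoldResult]
    mean_precision: float
    mean_recall: float
    mean_f: float
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_fold": [vars(fr) for fr in self.per_fold],
            "mean_precision": self.mean_precision,
            "mean_recall": self.mean_recall,
            "mean_f": self.mean_f,
            "config": self.config,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("fold\ttp\tfp\tfn\tprecision\trecall\tf_measure\n")
            for i, fr in enumerate(self.per_fold):
                fh.write(
                    f"{i}\t{fr.tp}\t{fr.fp}\t{fr.fn}\t{fr.precision!r}\t{fr.recall!r}\t{fr.f_measure!r}\n"
                )
            fh.write(
                f"mean\t\t\t\t{self.mean_precision!r}\t{self.mean_recall!r}\t{self.mean_f!r}\n"
            )


def _fold_indices(labels: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def _evaluate_folds(
    full_gram: np.ndarray,
    pairs: list[Pair],
    labels: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    c_pos: float,
    c_neg: float,
    config: dict,
) -> EvaluationReport:
    per_fold: list[FoldResult] = []
    for tr, te in folds:
        train_pairs = [pairs[i] for i in tr]
        test_pairs = [pairs[i] for i in te]
        model = fit(
            GramMatrix(train_pairs, train_pairs, full_gram[np.ix_(tr, tr)]),
            labels[tr], c_pos, c_neg,
        )
        pred, _ = predict(model, GramMatrix(test_pairs, train_pairs, full_gram[np.ix_(te, tr)]))
        truth = labels[te]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fp = int(np.sum((pred == 1) & (truth == -1)))
        fn = int(np.sum((pred == -1) & (truth == 1)))
        p, r, f = prf(tp, fp, fn)
        per_fold.append(FoldResult(tp, fp, fn, p, r, f))
    return EvaluationReport(
        per_fold=per_fold,
        mean_precision=float(np.mean([fr.precision for fr in per_fold])),
        mean_recall=float(np.mean([fr.recall for fr in per_fold])),
        mean_f=float(np.mean([fr.f_measure for fr in per_fold])),
        config=config,
    )


def _minmax_scale_rows(X: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    """Per-feature min-max scaling with statistics fit on the training rows only."""
    lo = X[train_idx].min(axis=0)
    hi = X[train_idx].max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def cross_validate(
    pairset: LabeledPairSet,
    spec: KernelSpec,
    inputs: KernelInputs,
    c_pos: float,
    c_neg: float,
    n_folds: int = 10,
    seed: int = 0,
    scale_psi: bool = False,
) -> EvaluationReport:
    """Stratified k-fold CV of the combined kernel + C-SVC pipeline.

    The full square Gram is assembled once; fold blocks are sliced from it.
    With ``scale_psi`` the 7 pair features are min-max scaled per fold using
    training-fold statistics before the linear block is formed.
    """
    labels = pairset.labels
    if pairset.n_positive < n_folds or pairset.n_negative < n_folds:
        raise EvaluationError(
            f"need at least n_folds={n_folds} examples of each class, "
            f"got {pairset.n_positive} positives / {pairset.n_negative} negatives"
        )
    pairs = pairset.pairs
    pair_block = pair_component_gram(spec, pairs, pairs, inputs)
    Psi = psi_matrix(inputs.network, inputs.dom_table, pairs)
    folds = _fold_indices(labels, n_folds, seed)
    config = {
        "spec": spec.to_dict(), "c_pos": c_pos, "c_neg": c_neg,
        "n_folds": n_folds, "seed": seed, "scale_psi": scale_psi,
    }
    if not scale_psi:
        full = Psi @ Psi.T + spec.alpha * pair_block
        return _evaluate_folds(full, pairs, labels, folds, c_pos, c_neg, config)
    # fold-dependent linear block: rebuild per fold from scaled features
    per_fold: list[FoldResult] = []
    for tr, te in folds:
        Ps = _minmax_scale_rows(Psi, tr)
        full = Ps @ Ps.T + spec.alpha * pair_block
        rep = _evaluate_folds(full, pairs, labels, [(tr, te)], c_pos, c_neg, config)
        per_fold.extend(rep.per_fold)
    return EvaluationReport(
        per_fold=per_fold,
        mean_precision=float(np.mean([fr.precision for fr in per_fold])),
        mean_recall=float(np.mean([fr.recall for fr in per_fold])),
        mean_f=float(np.mean([fr.f_measure for fr in per_fold])),
        config=config,
    )


@dataclass
class GridResult:
    """All grid-point reports plus the argmax by mean F (deterministic ties)."""

    reports: list[EvaluationReport]
    best: EvaluationReport

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                "base\tpairwise\tfeature_source\talpha\tc_pos\tc_neg\t"
                "mean_precision\tmean_recall\tmean_f\n"
            )
            for rep in self.reports:
                s = rep.config["spec"]
                fh.write(
                    f"{s['base']}\t{s['pairwise']}\t{s['feature_source']}\t{s['alpha']!r}\t"
                    f"{rep.config['c_pos']!r}\t{rep.config['c_neg']!r}\t"
                    f"{rep.mean_precision!r}\t{rep.mean_recall!r}\t{rep.mean_f!r}\n"
                )


def grid_search(
    pairset: LabeledPairSet,
    inputs: KernelInputs,
    specs: Sequence[KernelSpec],
    alpha_grid: Sequence[float],
    cpos_grid: Sequence[float],
    cneg_grid: Sequence[float],
    n_folds: int = 10,
    seed: int = 0,
) -> GridResult:
    """Evaluate every (spec, alpha, C+, C-) grid point by CV; pick the best.

    The alpha-independent blocks (pair-feature inner products and the pair
    kernel) are computed once per spec and recombined affinely for each
    alpha. Ties on mean F break by higher mean precision, then smaller
    alpha, then smaller C+.
    """
    if not (len(specs) and len(alpha_grid) and len(cpos_grid) and len(cneg_grid)):
        raise EvaluationError("grids must be nonempty")
    labels = pairset.labels
    pairs = pairset.pairs
    Psi = psi_matrix(inputs.network, inputs.dom_table, pairs)
    lin = Psi @ Psi.T
    folds = _fold_indices(labels, n_folds, seed)
    reports: list[EvaluationReport] = []
    for spec in specs:
        pair_block = pair_component_gram(spec, pairs, pairs, inputs)
        for alpha in alpha_grid:
            spec_a = KernelSpec(spec.base, spec.pairwise, spec.feature_source, float(alpha))
            full = lin + alpha * pair_block
            for c_pos in cpos_grid:
                for c_neg in cneg_grid:
                    config = {
                        "spec": spec_a.to_dict(), "c_pos": float(c_pos),
                        "c_neg": float(c_neg), "n_folds": n_folds, "seed": seed,
                        "scale_psi": False,
                    }
                    reports.append(
                        _evaluate_folds(full, pairs, labels, folds, c_pos, c_neg, config)
                    )
    best = max(
        reports,
        key=lambda r: (
            r.mean_f,
            r.mean_precision,
            -r.config["spec"]["alpha"],
            -r.config["c_pos"],
        ),
    )
    return GridResult(reports, best)
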