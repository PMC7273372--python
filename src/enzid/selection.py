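"""ANOVA F-score feature ranking and incremental forward selection.

For a two-class dataset, each feature column is scored by the one-way ANOVA
F statistic F = MSB/MSW, the ratio of the between-group mean square to the
within-group mean square.  With two groups this equals the square of the
pooled-variance two-sample t statistic.  A larger F indicates a stronger
association between the feature and the class partition.

Degenerate cases get explicit sentinels: a column that separates the classes
perfectly (MSW = 0, MSB > 0) receives +inf and ranks first; a constant column
(MSB = MSW = 0) receives 0 and ranks last.  Ties are broken by canonical
feature name, ascending, so the ranking is deterministic.

Incremental forward selection grows the feature subset one k-spaced pair at a
time, in F-rank order, on top of the full 20-feature AAC block, scoring each
subset size by cross-validated accuracy.  By default the ranking is computed
once on the full training matrix, mirroring the published protocol; because
that leaks selection information into the CV estimate, a fold-safe mode that
re-ranks inside each training fold is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classifier import (
    SVMConfig,
    _folds,
    cross_validate,
    grid_search,
    train,
)
from .encoding import (
    EncodingSpec,
    FeatureMatrix,
    aac_descriptors,
    encode_dataset,
)
from .evaluation import confusion, metrics, pool_confusions
from .sequence_io import LabeledDataset

__all__ = [
    "FScoreTable",
    "SelectionResult",
    "anova_f",
    "rank_features",
    "incremental_selection",
]


@dataclass
class FScoreTable:
    """Per-feature F statistic with its MSB/MSW components."""

    table: pd.DataFrame  # columns: feature, F, msb, msw (input column order)

    def __getitem__(self, feature: str) -> float:
        row = self.table.loc[self.table["feature"] == feature, "F"]
        if row.empty:
            raise KeyError(feature)
        return float(row.iloc[0])

    def to_tsv(self, path, header_comment: Optional[str] = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def anova_f(
    matrix: Union[FeatureMatrix, np.ndarray],
    labels: Optional[Sequence[int]] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> FScoreTable:
    """Two-group ANOVA F statistic for every feature column.

    With group sizes n1, n2 (n = n1+n2), group means x̄1, x̄2 and grand mean x̄:

        MSB = [n1(x̄1−x̄)² + n2(x̄2−x̄)²] / (g−1),   g = 2
        MSW = Σ within-group squared deviations / (n−g)
        F   = MSB / MSW

    Each class must contribute at least 2 samples.
    """
    if isinstance(matrix, FeatureMatrix):
        if matrix.labels is None:
            raise ValueError("feature matrix carries no labels")
        X, y = matrix.values, matrix.labels
        names = matrix.column_names
    else:
        X = np.asarray(matrix, dtype=float)
        y = np.asarray(labels, dtype=int)
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
    X1, X2 = X[y == 1], X[y == 0]
    n1, n2 = len(X1), len(X2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each class needs >= 2 samples (got {n1} and {n2})")
    n = n1 + n2
    m1, m2, grand = X1.mean(axis=0), X2.mean(axis=0), X.mean(axis=0)
    msb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2  # / (g-1) with g=2
    ssw = ((X1 - m1) ** 2).sum(axis=0) + ((X2 - m2) ** 2).sum(axis=0)
    msw = ssw / (n - 2)

    # zero-detection tolerance relative to column scale: a constant column
    # yields msb, msw that are both rounding noise, not real variance
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    tol = (1e-9 * scale) ** 2
    msb_zero, msw_zero = msb <= tol, msw <= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F = np.where(~msw_zero, F, np.where(~msb_zero, math.inf, 0.0))
    F = np.where(msb_zero & msw_zero, 0.0, F)
    return FScoreTable(
        pd.DataFrame({"feature": names, "F": F, "msb": msb, "msw": msw})
    )


def rank_features(table: FScoreTable) -> list[str]:
    """Feature names by descending F; +inf first; ties by name ascending."""
    df = table.table
    order = sorted(
        range(len(df)),
        key=lambda i: (-df["F"].iloc[i], df["feature"].iloc[i]),
    )
    return [df["feature"].iloc[i] for i in order]


@dataclass
class SelectionResult:
    """Outcome of incremental forward selection at a fixed gap k."""

    k: int
    ranking: list[str]  # all CKSAAP(k) pairs, descending F
    fscores: FScoreTable
    curve: pd.DataFrame  # columns: m, acc, sp, se, log2c, log2gamma
    best_m: int
    best_features: list[str]  # AAC block + top best_m pairs
    best_accuracy: float  # fraction in [0, 1]

    @property
    def best_pairs(self) -> list[str]:
        return self.ranking[: self.best_m]


def _fold_safe_accuracy(
    aac: np.ndarray,
    pairs: np.ndarray,
    pair_names: list[str],
    y: np.ndarray,
    m: int,
    svm: SVMConfig,
    n_folds: int,
    seed: int,
    stratified: bool,
) -> tuple[float, float, float]:
    """CV accuracy for subset size m with ranking re-done inside each fold."""
    folds = _folds(y, n_folds, seed, stratified)
    cms = []
    for tr, va in folds:
        ranking = rank_features(anova_f(pairs[tr], y[tr], pair_names))
        top = [pair_names.index(nm) for nm in ranking[:m]]
        Xtr = np.hstack([aac[tr], pairs[tr][:, top]])
        Xva = np.hstack([aac[va], pairs[va][:, top]])
        model = train(Xtr, y[tr], svm)
        cms.append(confusion(y[va], model.predict(Xva)))
    ms = metrics(pool_confusions(cms))
    return ms.acc / 100.0, ms.sp_paper, ms.se_paper


def incremental_selection(
    dataset: Union[LabeledDataset, FeatureMatrix],
    k: int = 3,
    max_m: int = 30,
    convention: str = "paper",
    n_folds: int = 6,
    seed: int = 0,
    stratified: bool = True,
    svm: Optional[SVMConfig] = None,
    log2c_grid: Optional[Sequence[float]] = None,
    log2gamma_grid: Optional[Sequence[float]] = None,
    fold_safe: bool = False,
) -> SelectionResult:
    """Grow AAC + top-m CKSAAP(k) pairs for m = 1..max_m; score each by CV.

    For every subset size the feature set is the full AAC block plus the top-m
    F-ranked k-spaced pairs.  When log2 grids are given, (c, gamma) is re-tuned
    by grid search at every m; otherwise *svm* (default c=1, gamma=1) is used
    throughout.  The best m is the smallest size attaining the maximum pooled
    accuracy.  ``fold_safe=True`` re-ranks pairs inside each training fold and
    requires a fixed *svm* config.
    """
    if not 1 <= max_m <= 400:
        raise ValueError(f"max_m must be in [1, 400], got {max_m}")
    retune = log2c_grid is not None and log2gamma_grid is not None
    if fold_safe and retune:
        raise ValueError("fold_safe selection requires a fixed SVM config, not a grid")
    if svm is None:
        svm = SVMConfig(1.0, 1.0)

    if isinstance(dataset, LabeledDataset):
        dataset.require_both_classes()
        fm = encode_dataset(
            dataset, EncodingSpec(include_aac=True, k_list=(k,), convention=convention)
        )
    else:
        fm = dataset
        if fm.labels is None:
            raise ValueError("feature matrix carries no labels")
    n_aac = len(aac_descriptors())
    aac = fm.values[:, :n_aac]
    pairs = fm.values[:, n_aac:]
    pair_names = fm.column_names[n_aac:]
    y = fm.labels

    fscores = anova_f(pairs, y, pair_names)
    ranking = rank_features(fscores)
    top_idx = [pair_names.index(nm) for nm in ranking]

    rows = []
    for m in range(1, max_m + 1):
        if fold_safe:
            acc, sp, se = _fold_safe_accuracy(
                aac, pairs, pair_names, y, m, svm, n_folds, seed, stratified
            )
            a = b = math.nan
        else:
            X_m = np.hstack([aac, pairs[:, top_idx[:m]]])
            if retune:
                gs = grid_search(
                    X_m, y, log2c_grid, log2gamma_grid,
                    n_folds=n_folds, seed=seed, stratified=stratified,
                )
                acc, (a, b) = gs.best_accuracy, gs.best_log2
                row = gs.table.loc[
                    (gs.table["log2c"] == a) & (gs.table["log2gamma"] == b)
                ].iloc[0]
                sp, se = float(row["sp"]), float(row["se"])
            else:
                cv = cross_validate(
                    X_m, y, svm, n_folds=n_folds, seed=seed, stratified=stratified
                )
                acc = cv.accuracy
                sp, se = cv.metric_set.sp_paper, cv.metric_set.se_paper
                a, b = math.log2(svm.c), math.log2(svm.gamma)
        rows.append(
            {"m": m, "acc": acc, "sp": sp, "se": se, "log2c": a, "log2gamma": b}
        )

    curve = pd.DataFrame(rows)
    best_m = int(curve.loc[curve["acc"].idxmax(), "m"])  # idxmax -> first max
    best_features = [d.name for d in aac_descriptors()] + ranking[:best_m]
    return SelectionResult(
        k=k,
        ranking=ranking,
        fscores=fscores,
        curve=curve,
        best_m=best_m,
        best_features=best_features,
        best_accuracy=float(curve["acc"].max()),
    )
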