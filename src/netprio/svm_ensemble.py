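"""Linear-SVM ensembles for network-based gene function prediction.

Each functional module defines a binary classification problem: module genes
(known positives) versus an equal-sized random draw from the rest of the
genome.  A gene's feature vector is its row of the network adjacency matrix
restricted to the module genes — its connection weights to the known
positives.  An ensemble of linear SVMs (default 100), each trained on a fresh
negative sample with a cross-validation-tuned cost parameter, scores every
gene in the universe; decision values are averaged across runs.

Raw decision values are not comparable across models, so each gene's score is
calibrated to a false positive rate: the fraction of non-module genes scoring
at least as high, FPR = FP / (FP + TN), floored at 0.5/|negatives| so that
−log10(FPR) stays finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .geneset_modules import FunctionalModule
from .network_io import FunctionalNetwork, GeneLookupError

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "CostSearchResult",
    "EnsembleScores",
    "RocCurve",
    "build_feature_matrix",
    "sample_negatives",
    "tune_cost",
    "train_ensemble",
    "roc_and_auc",
    "gene_fpr",
    "write_module_scores",
]

#: initial cost grid: 1e-5 .. 1e2 by factors of 10 (8 values)
INITIAL_COST_GRID: tuple[float, ...] = tuple(float(10.0**e) for e in range(-5, 3))
GRID_SIZE = 8
DEFAULT_REFINE_TOL = 1e-3
DEFAULT_MAX_REFINEMENTS = 5


@dataclass
class FeatureMatrix:
    """Sub-matrix of the network adjacency: rows = genes, columns = positives."""

    row_genes: list[str]
    col_positives: list[str]
    values: np.ndarray
    labels: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_genes), len(self.col_positives)):
            raise ValueError("feature matrix shape mismatch")

    def label_array(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature matrix has no labels")
        try:
            return np.array([self.labels[g] for g in self.row_genes])
        except KeyError as exc:
            raise ValueError(f"missing label for gene {exc.args[0]!r}") from None


@dataclass
class CostSearchResult:
    """Outcome of iterative cost-grid refinement."""

    final_grid: list[float]
    cv_accuracy: dict[float, float]
    best_cost: float


@dataclass
class EnsembleScores:
    """Aggregated decision values and per-gene FPR for one module."""

    module: FunctionalModule
    per_run_scores: list[dict[str, float]]
    mean_score: dict[str, float]
    fpr: dict[str, float]
    n_runs: int


@dataclass
class RocCurve:
    """Empirical ROC from a descending threshold sweep."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    counts: list[tuple[float, int, int, int, int]] = field(default_factory=list)


def build_feature_matrix(
    net: FunctionalNetwork,
    rows: Sequence[str],
    positives: Sequence[str],
    labels: Mapping[str, int] | None = None,
) -> FeatureMatrix:
    """Assemble connectivity feature vectors for ``rows`` against ``positives``."""
    if not positives:
        raise ValueError("positives must be non-empty")
    rows = list(rows)
    positives = list(positives)
    for g in rows:
        if g not in net:
            raise GeneLookupError(f"row gene {g!r} not in network")
    for p in positives:
        if p not in net:
            raise GeneLookupError(f"positive {p!r} not in network")
    col_index = {p: j for j, p in enumerate(positives)}
    values = np.zeros((len(rows), len(positives)))
    for i, g in enumerate(rows):
        for nbr, w in net.neighbors(g).items():
            j = col_index.get(nbr)
            if j is not None:
                values[i, j] = w
    # self-connections are not features
    for i, g in enumerate(rows):
        j = col_index.get(g)
        if j is not None:
            values[i, j] = 0.0
    return FeatureMatrix(rows, positives, values, dict(labels) if labels else None)


def sample_negatives(
    universe: Iterable[str],
    positives: Iterable[str],
    n: int,
    rng: np.random.Generator,
) -> list[str]:
    """Draw ``n`` genes uniformly without replacement from universe \\ positives."""
    pool = sorted(set(universe) - set(positives))
    if len(pool) < n:
        raise ValueError(
            f"negative pool has {len(pool)} genes, need {n} (short by {n - len(pool)})"
        )
    picked = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in picked]


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, cost: float, folds: int, seed: int
) -> float:
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in splitter.split(X, y):
        clf = SVC(kernel="linear", C=cost)
        clf.fit(X[train_idx], y[train_idx])
        accs.append(float(np.mean(clf.predict(X[test_idx]) == y[test_idx])))
    return float(np.mean(accs))


def tune_cost(
    fm: FeatureMatrix,
    folds: int = 10,
    rng: np.random.Generator | None = None,
    tol: float = DEFAULT_REFINE_TOL,
    max_refinements: int = DEFAULT_MAX_REFINEMENTS,
) -> CostSearchResult:
    """Pick the SVM cost parameter by iterative geometric grid refinement.

    Mean 10-fold CV accuracy is evaluated on the 8-point grid 1e-5..1e2
    (factors of 10); the grid is then repeatedly re-laid as 8 geometric
    points spanning the neighbors of the current best cost, stopping when the
    best accuracy improves by less than ``tol`` or after ``max_refinements``
    rounds.  The returned grid is the one containing the winning cost.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    y = fm.label_array()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels are degenerate (single class)")
    if len(y) < folds:
        raise ValueError(f"{len(y)} labeled rows < {folds} folds")
    eff_folds = min(folds, int(counts.min()))
    if eff_folds < 2:
        raise ValueError("need ≥2 members in each class for cross-validation")
    if eff_folds < folds:
        logger.warning("folds capped at %d by smallest class", eff_folds)
    X = fm.values
    seed = int(rng.integers(2**31 - 1))  # one fold split shared across the search

    cv_accuracy: dict[float, float] = {}

    def evaluate(grid: Sequence[float]) -> tuple[float, float]:
        best_c, best_a = grid[0], -1.0
        for c in grid:
            c = float(c)
            if c not in cv_accuracy:
                cv_accuracy[c] = _cv_accuracy(X, y, c, eff_folds, seed)
            if cv_accuracy[c] > best_a:
                best_c, best_a = c, cv_accuracy[c]
        return best_c, best_a

    final_grid = list(INITIAL_COST_GRID)
    best_cost, best_acc = evaluate(final_grid)
    for _ in range(max_refinements):
        i = final_grid.index(best_cost)
        lo = final_grid[max(i - 1, 0)]
        hi = final_grid[min(i + 1, len(final_grid) - 1)]
        if np.isclose(lo, hi):
            break
        new_grid = [float(c) for c in np.geomspace(lo, hi, GRID_SIZE)]
        cand_cost, cand_acc = evaluate(new_grid)
        improvement = cand_acc - best_acc
        if cand_acc >= best_acc:
            best_cost, best_acc, final_grid = cand_cost, cand_acc, new_grid
        if improvement < tol:
            break
    return CostSearchResult(
        final_grid=list(final_grid), cv_accuracy=cv_accuracy, best_cost=best_cost
    )


def train_ensemble(
    net: FunctionalNetwork,
    module: FunctionalModule,
    universe: Iterable[str],
    n_runs: int = 100,
    rng: np.random.Generator | int | None = None,
    folds: int = 10,
    max_refinements: int = DEFAULT_MAX_REFINEMENTS,
) -> EnsembleScores:
    """Train an ensemble of linear SVMs for one module and score the universe.

    Each run draws a fresh equal-sized negative sample, tunes the cost by
    cross-validated grid refinement, fits a linear SVM on positives vs
    negatives, and records decision values for every universe gene.  Scores
    are averaged across runs and calibrated to per-gene FPRs against all
    non-module universe genes.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    positives = sorted(module.genes)
    if len(positives) < 2:
        raise ValueError(f"module {module.term}/{module.module_index} has <2 genes")
    universe = sorted(set(universe))
    score_genes = sorted(set(universe) | set(positives))
    full = build_feature_matrix(net, score_genes, positives)
    row_index = {g: i for i, g in enumerate(score_genes)}
    pos_set = set(positives)

    run_rngs = rng.spawn(n_runs)
    per_run: list[dict[str, float]] = []
    for run, run_rng in enumerate(run_rngs):
        try:
            negatives = sample_negatives(universe, pos_set, len(positives), run_rng)
            train_rows = positives + negatives
            X = full.values[[row_index[g] for g in train_rows]]
            y = np.array([1] * len(positives) + [-1] * len(negatives))
            fm = FeatureMatrix(
                train_rows,
                positives,
                X,
                labels={g: int(lbl) for g, lbl in zip(train_rows, y)},
            )
            search = tune_cost(
                fm, folds=folds, rng=run_rng, max_refinements=max_refinements
            )
            clf = SVC(kernel="linear", C=search.best_cost)
            clf.fit(X, y)
            decisions = clf.decision_function(full.values)
            per_run.append({g: float(d) for g, d in zip(score_genes, decisions)})
        except Exception:  # noqa: BLE001 - a failed run is skipped, not fatal
            logger.warning(
                "module %s/%d: run %d failed; skipped",
                module.term,
                module.module_index,
                run,
                exc_info=True,
            )
    if not per_run:
        raise RuntimeError(
            f"module {module.term}/{module.module_index}: every run failed"
        )
    stacked = np.array([[run[g] for g in score_genes] for run in per_run])
    means = stacked.mean(axis=0)
    mean_score = {g: float(m) for g, m in zip(score_genes, means)}
    negatives_all = set(score_genes) - pos_set
    fpr = gene_fpr(mean_score, pos_set, negatives_all)
    return EnsembleScores(
        module=module,
        per_run_scores=per_run,
        mean_score=mean_score,
        fpr=fpr,
        n_runs=len(per_run),
    )


def _validate_labelled(
    scores: Mapping[str, float], positives: Iterable[str], negatives: Iterable[str]
) -> tuple[set[str], set[str]]:
    pos, neg = set(positives), set(negatives)
    if not pos or not neg:
        raise ValueError("positives and negatives must be non-empty")
    overlap = pos & neg
    if overlap:
        raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:5]}")
    missing = (pos | neg) - set(scores)
    if missing:
        raise ValueError(f"unscored genes: {sorted(missing)[:5]}")
    return pos, neg


def roc_and_auc(
    scores: Mapping[str, float],
    positives: Iterable[str],
    negatives: Iterable[str],
) -> RocCurve:
    """Empirical ROC by a descending sweep over unique score thresholds.

    At threshold *t* a gene is called positive when its score ≥ *t*.  The
    curve is anchored at (0, 0) (threshold above the maximum) and ends at
    (1, 1); the AUC is the trapezoidal area, which equals the Mann–Whitney
    probability with ties counted half.
    """
    pos, neg = _validate_labelled(scores, positives, negatives)
    pos_scores = np.sort([scores[g] for g in pos])
    neg_scores = np.sort([scores[g] for g in neg])
    thresholds = np.unique(np.concatenate([pos_scores, neg_scores]))[::-1]
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    tpr = [0.0]
    fpr = [0.0]
    counts: list[tuple[float, int, int, int, int]] = []
    for t in thresholds:
        tp = int(n_pos - np.searchsorted(pos_scores, t, side="left"))
        fp = int(n_neg - np.searchsorted(neg_scores, t, side="left"))
        fn = n_pos - tp
        tn = n_neg - fp
        counts.append((float(t), tp, fp, tn, fn))
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
    tpr_a = np.array(tpr)
    fpr_a = np.array(fpr)
    auc = float(np.trapezoid(tpr_a, fpr_a))
    return RocCurve(thresholds=thresholds, tpr=tpr_a, fpr=fpr_a, auc=auc, counts=counts)


def gene_fpr(
    scores: Mapping[str, float],
    positives: Iterable[str],
    negatives: Iterable[str],
) -> dict[str, float]:
    """Per-gene FPR: fraction of negatives scoring ≥ the gene's own score.

    FPR(g) = FP / (FP + TN) with the threshold placed at g's score
    (inclusive), computed over ALL supplied negatives, and floored at
    0.5/|negatives| so downstream −log10 transforms stay finite.
    """
    _, neg = _validate_labelled(scores, positives, negatives)
    neg_scores = np.sort([scores[g] for g in neg])
    n_neg = len(neg_scores)
    floor = 0.5 / n_neg
    out: dict[str, float] = {}
    for g, s in scores.items():
        fp = n_neg - int(np.searchsorted(neg_scores, s, side="left"))
        out[g] = max(fp / n_neg, floor)
    return out


def write_module_scores(
    scores: Sequence[EnsembleScores], path: str | Path
) -> None:
    """TSV dump: (term, module_index, gene_id, mean_score, fpr)."""
    with Path(path).open("w") as fh:
        fh.write("term\tmodule_index\tgene_id\tmean_score\tfpr\n")
        for es in scores:
            for g in sorted(es.mean_score):
                fh.write(
                    f"{es.module.term}\t{es.module.module_index}\t{g}\t"
                    f"{es.mean_score[g]:.10g}\t{es.fpr[g]:.10g}\n"
                )


def write_roc(curve: RocCurve, path: str | Path) -> None:
    """TSV dump of the threshold sweep: (threshold, tp, fp, tn, fn, tpr, fpr)."""
    with Path(path).open("w") as fh:
        fh.write("threshold\ttp\tfp\ttn\tfn\ttpr\tfpr\n")
        for (t, tp, fp, tn, fn), tr, fr in zip(
            curve.counts, curve.tpr[1:], curve.fpr[1:]
        ):
            fh.write(f"{t:.10g}\t{tp}\t{fp}\t{tn}\t{fn}\t{tr:.10g}\t{fr:.10g}\n")
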