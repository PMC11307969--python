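"""Reference-cohort k-nearest-neighbour classification by Spearman correlation.

A query transcriptome is correlated (Spearman, over shared coding genes)
against every sample of a labelled reference cohort; the majority label
among the k best-correlated references is the prediction.  A tied vote is
resolved by repeatedly dropping the worst-correlated neighbour of the
current window and re-voting until the plurality is unique, which is
guaranteed at window size 1.  An agreement score — the fraction of the top
10 neighbours carrying the predicted label — quantifies how unanimous the
neighbourhood is.  k itself is chosen by leave-one-out cross-validation
over one or more metadata categories, taking the smallest k that maximises
the mean accuracy across categories.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .expression import ExpressionMatrix

__all__ = [
    "ConstantExpressionError",
    "ReferenceCohort",
    "NeighborRanking",
    "ClassificationResult",
    "LoocvReport",
    "spearman_rho",
    "pairwise_spearman",
    "rank_neighbors",
    "classify_knn",
    "agreement_score",
    "top_label_histogram",
    "loocv_select_k",
    "classify_cohort",
]

logger = logging.getLogger(__name__)


class ConstantExpressionError(ValueError):
    """Spearman correlation is undefined when a vector is constant."""


@dataclass
class ReferenceCohort:
    """A labelled expression reference with optional metadata categories.

    ``labels`` maps sample id to a class label and must cover every
    expression sample.  ``metadata`` maps a category name to a partial
    sample→subgroup map (subgroup labels need not cover all samples).
    """

    expression: ExpressionMatrix
    labels: pd.Series
    metadata: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).astype(str)
        unlabeled = [s for s in self.expression.sample_ids if s not in self.labels.index]
        if unlabeled:
            raise ValueError(f"sample {unlabeled[0]!r} has no class label")
        self.metadata = {
            name: pd.Series(sub).dropna().astype(str) for name, sub in self.metadata.items()
        }


@dataclass
class NeighborRanking:
    """All reference samples ranked by correlation to one query.

    ``neighbors`` is sorted by rho descending; exactly equal rho values are
    ordered by reference sample id so that rankings are deterministic.
    """

    query_id: str
    neighbors: list[tuple[str, float]]


@dataclass
class ClassificationResult:
    query_id: str
    predicted_label: str
    k_used: int
    agreement: float
    top_neighbor_labels: list[str]
    removed_for_tiebreak: int


@dataclass
class LoocvReport:
    """Per-(category, k) leave-one-out accuracies and the selected k."""

    k_grid: list[int]
    accuracy: dict[tuple[str, int], float]
    chosen_k: int

    def mean_accuracy(self) -> pd.Series:
        """Mean accuracy over categories, indexed by k."""
        df = pd.Series(self.accuracy).unstack(level=0)
        return df.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": cat, "k": k, "accuracy": acc}
            for (cat, k), acc in sorted(self.accuracy.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Correlation primitives


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Raises :class:`ConstantExpressionError` if either vector is constant
    (the correlation is undefined, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    rx = rankdata(x)
    ry = rankdata(y)
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = np.sqrt((sx * sx).sum() * (sy * sy).sum())
    if denom == 0:
        raise ConstantExpressionError("constant vector: Spearman rho undefined")
    return float(np.clip((sx * sy).sum() / denom, -1.0, 1.0))


def _rank_columns(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Average-rank each column; return ranks and a mask of constant columns."""
    values = df.to_numpy(dtype=float)
    ranks = rankdata(values, axis=0)
    constant = np.ptp(values, axis=0) == 0
    return ranks, constant


def pairwise_spearman(df: pd.DataFrame) -> pd.DataFrame:
    """All-against-all Spearman correlations between the columns of ``df``.

    Constant columns yield NaN rows/columns (undefined correlation).
    """
    ranks, constant = _rank_columns(df)
    with np.errstate(invalid="ignore", divide="ignore"):
        centered = ranks - ranks.mean(axis=0)
        norms = np.sqrt((centered**2).sum(axis=0))
        norms_safe = np.where(norms == 0, np.nan, norms)
        rho = (centered / norms_safe).T @ (centered / norms_safe)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    return pd.DataFrame(rho, index=df.columns, columns=df.columns)


def _sorted_ranking(query_id: str, rho: pd.Series) -> NeighborRanking:
    order = sorted(rho.index, key=lambda s: (-rho[s], s))
    return NeighborRanking(query_id, [(s, float(rho[s])) for s in order])


def rank_neighbors(query: pd.Series, reference: ReferenceCohort) -> NeighborRanking:
    """Rank every reference sample by Spearman correlation to the query.

    Query and reference are intersected on their shared genes (restrict to
    coding genes beforehand with
    :func:`pdxkit.expression.intersect_on_coding_genes` when an annotation
    is available).  Constant reference samples are excluded with a warning;
    a constant query, or fewer than 2 shared genes, is an error.
    """
    ref = reference.expression.data
    shared = query.index.intersection(ref.index)
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared gene(s); need at least 2")
    q = query.loc[shared].to_numpy(dtype=float)
    if np.ptp(q) == 0:
        raise ConstantExpressionError(
            f"query {query.name!r} is constant over shared genes"
        )
    ranks, constant = _rank_columns(ref.loc[shared])
    qc = rankdata(q) - rankdata(q).mean()
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered.T @ qc) / (norms * np.sqrt((qc**2).sum()))
    rho = pd.Series(np.clip(rho, -1.0, 1.0), index=ref.columns)
    if constant.any():
        dropped = list(ref.columns[constant])
        logger.warning(
            "excluding %d constant reference sample(s) from ranking: %s",
            len(dropped), dropped,
        )
        rho = rho.drop(dropped)
    if rho.empty:
        raise ConstantExpressionError("all reference samples constant; no ranking")
    return _sorted_ranking(str(query.name), rho)


# ---------------------------------------------------------------------------
# Voting


def classify_knn(
    ranking: NeighborRanking,
    labels: pd.Series,
    k: int,
    top_n: int = 10,
) -> ClassificationResult:
    """Majority vote among the top-k neighbours with iterated tie-break.

    If the plurality vote among the current window is tied, the single
    worst-correlated neighbour of the window is dropped and the remaining
    neighbours re-voted; this repeats until the winner is unique (always
    true at window size 1).  The agreement score is computed over the
    original top ``top_n`` neighbours against the final prediction.
    """
    n = len(ranking.neighbors)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, {n}]")
    labels = pd.Series(labels).astype(str)
    window = [labels[s] for s, _ in ranking.neighbors[:k]]
    removed = 0
    while True:
        counts = Counter(window)
        best = counts.most_common()
        if len(best) == 1 or best[0][1] > best[1][1]:
            predicted = best[0][0]
            break
        window = window[:-1]  # drop the worst-correlated neighbour
        removed += 1
    agreement = agreement_score(ranking, labels, predicted, top_n=top_n)
    head = max(k, top_n)
    return ClassificationResult(
        query_id=ranking.query_id,
        predicted_label=predicted,
        k_used=k,
        agreement=agreement,
        top_neighbor_labels=[labels[s] for s, _ in ranking.neighbors[:head]],
        removed_for_tiebreak=removed,
    )


def agreement_score(
    ranking: NeighborRanking,
    labels: pd.Series,
    predicted: str,
    top_n: int = 10,
) -> float:
    """Fraction of the best ``top_n`` neighbours sharing the predicted label.

    With fewer than ``top_n`` neighbours available, all are used.
    """
    if not ranking.neighbors:
        raise ValueError("empty ranking")
    labels = pd.Series(labels).astype(str)
    head = [labels[s] for s, _ in ranking.neighbors[:top_n]]
    return sum(lab == predicted for lab in head) / len(head)


def top_label_histogram(
    ranking: NeighborRanking, labels: pd.Series, top_n: int = 10
) -> pd.Series:
    """Label composition of the best ``top_n`` neighbours, as fractions."""
    labels = pd.Series(labels).astype(str)
    head = [labels[s] for s, _ in ranking.neighbors[:top_n]]
    return pd.Series(Counter(head)).sort_index() / len(head)


# ---------------------------------------------------------------------------
# Cross-validation and batch classification


def loocv_select_k(
    reference: ReferenceCohort,
    categories: list[str],
    k_grid: list[int],
) -> LoocvReport:
    """Choose k by leave-one-out cross-validation over metadata categories.

    Each sample carrying a subgroup label in a category is held out and
    classified against the remaining labelled samples of that category;
    the accuracy is the fraction of correct subgroup predictions.  The
    chosen k maximises the mean accuracy over categories, ties broken
    toward the smallest k.  Samples without a subgroup label in a category
    take no part in that category's cross-validation.
    """
    if not k_grid:
        raise ValueError("empty k grid")
    if not categories:
        raise ValueError("no categories given")
    k_grid = sorted(set(int(k) for k in k_grid))
    if min(k_grid) < 1:
        raise ValueError("k must be positive")
    unknown = [c for c in categories if c not in reference.metadata and c != "label"]
    if unknown:
        raise ValueError(f"unknown metadata category {unknown[0]!r}")

    rho = pairwise_spearman(reference.expression.data)
    accuracy: dict[tuple[str, int], float] = {}
    for cat in categories:
        sub = reference.labels if cat == "label" else reference.metadata[cat]
        sub = sub[sub.index.isin(reference.expression.sample_ids)]
        if sub.nunique() < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 subgroups")
        samples = list(sub.index)
        if max(k_grid) >= len(samples):
            raise ValueError(
                f"max k {max(k_grid)} not below the {len(samples)} labelled "
                f"samples of category {cat!r}"
            )
        correct = {k: 0 for k in k_grid}
        for held_out in samples:
            others = [s for s in samples if s != held_out]
            r = rho.loc[held_out, others].dropna()
            if r.empty:
                continue
            ranking = _sorted_ranking(held_out, r)
            for k in k_grid:
                result = classify_knn(ranking, sub, min(k, len(r)))
                correct[k] += result.predicted_label == sub[held_out]
        for k in k_grid:
            accuracy[(cat, k)] = correct[k] / len(samples)

    mean_acc = pd.Series(
        {k: np.mean([accuracy[(c, k)] for c in categories]) for k in k_grid}
    )
    chosen_k = int(min(mean_acc.index[mean_acc == mean_acc.max()]))
    return LoocvReport(k_grid=k_grid, accuracy=accuracy, chosen_k=chosen_k)


def classify_cohort(
    queries: ExpressionMatrix,
    reference: ReferenceCohort,
    k: int = 6,
    top_n: int = 10,
) -> tuple[list[ClassificationResult], dict[str, str]]:
    """Classify every query column; per-query failures do not abort the batch.

    Returns the list of results and a query_id → error-message map for
    queries that could not be classified (e.g. constant expression).
    """
    results: list[ClassificationResult] = []
    errors: dict[str, str] = {}
    for sample_id in queries.sample_ids:
        try:
            ranking = rank_neighbors(queries.sample(sample_id), reference)
            results.append(classify_knn(ranking, reference.labels, k, top_n=top_n))
        except (ValueError, ConstantExpressionError) as exc:
            errors[sample_id] = str(exc)
    return results, errors


def results_to_frame(results: list[ClassificationResult]) -> pd.DataFrame:
    """Tabulate classification results for TSV output."""
    return pd.DataFrame(
        {
            "query_id": [r.query_id for r in results],
            "predicted_label": [r.predicted_label for r in results],
            "k": [r.k_used for r in results],
            "agreement": [r.agreement for r in results],
            "top10_labels": [",".join(r.top_neighbor_labels[:10]) for r in results],
            "removed_for_tiebreak": [r.removed_for_tiebreak for r in results],
        }
    )
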