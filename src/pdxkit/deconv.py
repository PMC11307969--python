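"""Benchmarking of externally produced cell-type deconvolution tables.

Deconvolution tools (EPIC, CIBERSORT, ...) emit per-sample cell-type
fraction tables.  This module does not run those tools; it evaluates their
output against marker-gene evidence: renormalise fractions after dropping
an "uncharacterized" compartment, compute a marker-panel score per sample
(e.g. a fibroblast score as the mean log2(RPKM+1) of fibroblast markers),
and correlate the score with each predicted cell-type fraction.  With the
tiny cohorts typical of PDX studies, Spearman p-values are computed by
exact permutation when n <= 9 and by the t approximation otherwise.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .expression import ExpressionMatrix
from .knn import ConstantExpressionError, spearman_rho

__all__ = [
    "ProportionsTable",
    "MarkerSet",
    "ScoreCorrelationResult",
    "renormalize_excluding",
    "signature_score",
    "spearman_with_pvalue",
    "correlate_score_with_proportions",
]

logger = logging.getLogger(__name__)

_ROW_SUM_TOL = 1e-6
EXACT_PERMUTATION_MAX_N = 9  # n! <= 362880 rank permutations enumerated


@dataclass
class ProportionsTable:
    """Samples x cell types fraction table from one deconvolution tool."""

    fractions: pd.DataFrame  # rows: samples, columns: cell types
    source: str = ""

    def __post_init__(self) -> None:
        if (self.fractions.to_numpy(dtype=float) < -_ROW_SUM_TOL).any():
            raise ValueError("cell-type fractions must be non-negative")
        row_sums = self.fractions.sum(axis=1)
        if (row_sums > 1 + _ROW_SUM_TOL).any():
            bad = row_sums.index[row_sums > 1 + _ROW_SUM_TOL][0]
            raise ValueError(f"fractions of sample {bad!r} sum to more than 1")
        self.fractions = self.fractions.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)

    @classmethod
    def read_tsv(cls, path, source: str = "") -> "ProportionsTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, source=source)

    def to_tsv(self, path) -> None:
        self.fractions.to_csv(path, sep="\t", index_label="sample_id")

    def harmonize(self, mapping: dict[str, str]) -> "ProportionsTable":
        """Rename/merge cell types via a source-name → harmonised-name map.

        Columns mapping to the same harmonised name are summed; unmapped
        columns keep their name.
        """
        renamed = self.fractions.rename(columns=lambda c: mapping.get(c, c))
        merged = renamed.T.groupby(level=0).sum().T
        return ProportionsTable(merged, source=self.source)


@dataclass
class MarkerSet:
    """A named, duplicate-free panel of marker genes."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker set must contain at least one gene")
        self.genes = list(dict.fromkeys(self.genes))  # dedupe, keep order

    @classmethod
    def read_json(cls, path) -> "MarkerSet":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(name=payload["name"], genes=list(payload["genes"]))

    @classmethod
    def read_tsv(cls, path) -> "MarkerSet":
        df = pd.read_csv(path, sep="\t")
        name = str(df["name"].iloc[0]) if "name" in df.columns else "markers"
        return cls(name=name, genes=[str(g) for g in df["gene"]])


@dataclass
class ScoreCorrelationResult:
    """Marker-score vs predicted-fraction correlations for one table."""

    score_name: str
    scores: pd.Series  # per-sample marker score
    per_cell_type: dict[str, tuple[float, float] | None]  # rho, p (None if undefined)
    source: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell_type, value in self.per_cell_type.items():
            rho, p = value if value is not None else (np.nan, np.nan)
            rows.append(
                {"source": self.source, "score": self.score_name,
                 "cell_type": cell_type, "rho": rho, "p_value": p}
            )
        return pd.DataFrame(rows)


def renormalize_excluding(
    p: ProportionsTable, excluded: set[str]
) -> ProportionsTable:
    """Drop the excluded cell types and rescale each row to sum to 1.

    A row left with zero mass after the exclusion cannot be renormalised
    and raises an error naming the sample.
    """
    excluded = set(excluded)
    unknown = excluded - set(p.cell_types)
    if unknown:
        raise ValueError(f"cell type {sorted(unknown)[0]!r} not in table")
    if not excluded:
        return ProportionsTable(p.fractions.copy(), source=p.source)
    kept = p.fractions.drop(columns=list(excluded))
    mass = kept.sum(axis=1)
    if (mass <= 0).any():
        bad = mass.index[mass <= 0][0]
        raise ValueError(f"sample {bad!r} has zero mass outside the excluded types")
    return ProportionsTable(kept.div(mass, axis=0), source=p.source)


def signature_score(expr: ExpressionMatrix, markers: MarkerSet) -> pd.Series:
    """Per-sample marker-panel score: mean log2(RPKM + 1) over present markers.

    Marker genes absent from the matrix are logged and skipped; no present
    marker at all is an error.  Averaging on the log scale keeps single
    very highly expressed markers from dominating the panel.
    """
    present = [g for g in markers.genes if g in expr.data.index]
    absent = [g for g in markers.genes if g not in expr.data.index]
    if absent:
        logger.warning(
            "%d/%d marker genes of %r absent from expression matrix: %s",
            len(absent), len(markers.genes), markers.name, absent,
        )
    if not present:
        raise ValueError(f"no marker gene of {markers.name!r} present in matrix")
    score = np.log2(expr.data.loc[present] + 1.0).mean(axis=0)
    score.name = markers.name
    return score


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (small n).

    Enumerates all n! assignments of y's ranks to x's ranks and reports the
    fraction with |rho| at least the observed |rho|.
    """
    rx = rankdata(x)
    ry = rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    cx = rx - rx.mean()
    cy = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((cx**2).sum() * (cy**2).sum(axis=1))
    rho_perm = (cy @ cx) / denom
    cy_obs = ry - ry.mean()
    rho_obs = (cy_obs @ cx) / math.sqrt((cx**2).sum() * (cy_obs**2).sum())
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def spearman_with_pvalue(x, y) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    Exact permutation distribution when n <= 9 (reliable at the ~10-sample
    cohort sizes this package targets); the t approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = spearman_rho(x, y)
    n = len(x)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_spearman_p(x, y)
    else:
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def correlate_score_with_proportions(
    scores: pd.Series,
    p: ProportionsTable,
    min_n: int = 3,
) -> ScoreCorrelationResult:
    """Spearman-correlate a marker score with every predicted fraction column.

    Samples are matched by id; fewer than ``min_n`` shared samples is an
    error.  Cell types whose column (or the score) is constant get ``None``
    (undefined correlation) rather than a fabricated zero.
    """
    scores = pd.Series(scores).astype(float)
    shared = [s for s in p.sample_ids if s in scores.index]
    if len(shared) < min_n:
        raise ValueError(
            f"only {len(shared)} samples shared between scores and proportions; "
            f"need at least {min_n}"
        )
    sub_scores = scores.loc[shared].to_numpy()
    per_cell_type: dict[str, tuple[float, float] | None] = {}
    for cell_type in p.cell_types:
        column = p.fractions.loc[shared, cell_type].to_numpy()
        try:
            per_cell_type[cell_type] = spearman_with_pvalue(sub_scores, column)
        except ConstantExpressionError:
            per_cell_type[cell_type] = None
    return ScoreCorrelationResult(
        score_name=str(scores.name or "score"),
        scores=scores.loc[shared],
        per_cell_type=per_cell_type,
        source=p.source,
    )
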