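"""Signature projection onto a labelled cell atlas and genome-wide
correlation landscape ranking.

The per-cell signature score is the weighted sum of per-gene z-scores
computed across ALL cells pooled (per-type standardization would erase the
enrichment being measured). The landscape ranks every gene by Spearman
correlation with the linear predictor, rank 1 = most positively correlated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_core
from .errors import GeneNotFoundError, InsufficientDataError, ValidationError

__all__ = ["CellAtlas", "ProjectionResult", "project_signature", "landscape",
           "panel_report"]

logger = logging.getLogger(__name__)


@dataclass
class CellAtlas:
    """Cell-by-gene expression with a cell-type label per cell."""

    expression: pd.DataFrame  # cells x genes
    cell_type: pd.Series      # label per cell, aligned to expression index

    def __post_init__(self):
        self.expression = self.expression.astype(float)
        self.cell_type = self.cell_type.reindex(self.expression.index)
        if self.cell_type.isna().any():
            raise ValidationError("every cell must carry a type label")
        if self.expression.columns.duplicated().any():
            raise ValidationError("duplicated gene identifiers in atlas")

    @classmethod
    def from_files(cls, expression_path, labels_path):
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(expression=expr, cell_type=labels)


@dataclass
class ProjectionResult:
    cell_scores: pd.Series
    type_means: pd.Series      # per-type mean score, sorted descending
    fold: float | None         # top / second when both positive, else diff
    fold_mode: str             # "ratio" | "difference" | "undefined"


def project_signature(atlas, genes, weights=None):
    """Score every cell with the signature and summarize per cell type.

    The fold statistic compares the top-ranked type with the runner-up:
    their ratio when both means are positive, otherwise their difference.
    With a single cell type the fold is undefined (None, with a warning).
    """
    genes = list(genes)
    if weights is None:
        weights = [1.0] * len(genes)
    if len(weights) != len(genes):
        raise ValidationError("genes and weights must have equal length")
    missing = [g for g in genes if g not in atlas.expression.columns]
    if missing:
        raise GeneNotFoundError(f"genes absent from atlas: {missing}")
    score = np.zeros(atlas.expression.shape[0])
    for gene, w in zip(genes, weights):
        score = score + float(w) * stats_core.zscore(
            atlas.expression[gene].to_numpy())
    cell_scores = pd.Series(score, index=atlas.expression.index)
    type_means = cell_scores.groupby(atlas.cell_type).mean()
    type_means = type_means.sort_values(ascending=False)
    if len(type_means) < 2:
        warnings.warn("single cell type: fold enrichment undefined")
        return ProjectionResult(cell_scores, type_means, None, "undefined")
    top, second = float(type_means.iloc[0]), float(type_means.iloc[1])
    if top > 0 and second > 0:
        return ProjectionResult(cell_scores, type_means, top / second, "ratio")
    return ProjectionResult(cell_scores, type_means, top - second, "difference")


def landscape(expression, lp, signature_genes=()):
    """Rank every gene by Spearman correlation with the linear predictor.

    Parameters
    ----------
    expression : DataFrame, genes x samples (aligned with the LP scores)
    lp : LinearPredictor or Series of per-sample scores
    signature_genes : genes flagged ``tautological`` in the output (they are
        components of the LP, so their high rank carries no information)

    Returns a DataFrame indexed by gene with columns ``rho``, ``p``,
    ``rank`` (1 = most positive rho, ties broken by gene id) and
    ``tautological``; constant genes are skipped and counted in
    ``attrs['skipped']``.
    """
    scores = lp.scores if hasattr(lp, "scores") else pd.Series(lp)
    if list(expression.columns) != list(scores.index):
        scores = scores.reindex(expression.columns)
        if scores.isna().any():
            raise ValidationError("LP scores do not cover expression samples")
    n = expression.shape[1]
    if n < 20:
        raise InsufficientDataError(f"landscape needs >= 20 samples, got {n}")
    values = expression.to_numpy(dtype=float)
    y = scores.to_numpy(dtype=float)
    if np.isfinite(values).all() and np.isfinite(y).all():
        est, pvals, valid = stats_core.correlate_many(values, y,
                                                      method="spearman")
    else:  # pairwise fallback, gene by gene
        est = np.full(values.shape[0], np.nan)
        pvals = np.full(values.shape[0], np.nan)
        valid = np.zeros(values.shape[0], dtype=bool)
        for i in range(values.shape[0]):
            try:
                res = stats_core.correlate(values[i], y, method="spearman")
            except Exception:
                continue
            est[i], pvals[i], valid[i] = res.estimate, res.p_value, True
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("landscape: skipped %d constant/degenerate genes", n_skipped)
    out = pd.DataFrame({"rho": est, "p": pvals}, index=expression.index)
    out = out[valid]
    # rank 1 = most positive rho; ties broken by gene id for determinism
    order = np.lexsort((out.index.to_numpy(), -out["rho"].to_numpy()))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    out["tautological"] = out.index.isin(set(signature_genes))
    out.attrs["skipped"] = n_skipped
    out.attrs["n_genes_total"] = len(out)
    return out


def panel_report(landscape_table, panel_groups):
    """Extract a configured gene panel from a landscape table.

    ``panel_groups`` maps group name -> ordered gene list. Output preserves
    the configured ordering; genes absent from the landscape get missing rho
    and ``present = False``. No new statistics are computed.
    """
    rows = []
    for group, genes in panel_groups.items():
        for gene in genes:
            if gene in landscape_table.index:
                row = landscape_table.loc[gene]
                rows.append((gene, group, float(row["rho"]), int(row["rank"]),
                             True))
            else:
                rows.append((gene, group, float("nan"), -1, False))
    return pd.DataFrame(rows, columns=["gene", "group", "rho", "rank",
                                       "present"])
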