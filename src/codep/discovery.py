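"""Drug-gene co-dependency discovery.

For each drug with an annotated on-target gene, a base ordinary-least-squares
model regresses drug AUC on the on-target dependency score. Base-model
residuals are correlated against every other gene's dependency profile to
nominate candidate co-targets, a combined two-covariate model is fitted for
the leading candidates, and pairs are prioritized by the gain in explained
variance (delta R^2) with global Benjamini-Hochberg control on the partial
correlation p-values.

Orientation conventions: lower AUC means greater drug sensitivity and more
negative dependency scores mean greater essentiality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .errors import (
    AnnotationError,
    CollinearityError,
    DegenerateInputError,
    EmptyScreenError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "DependencyPanel",
    "BaseModelFit",
    "CombinedModelFit",
    "InteractionRecord",
    "DiscoveryConfig",
    "DiscoveryResult",
    "fit_base_model",
    "screen_residuals",
    "fit_combined_model",
    "run_discovery",
    "records_to_frame",
    "frame_to_records",
]

COLLINEARITY_R = 0.999


@dataclass
class DependencyPanel:
    """Matched drug-sensitivity and gene-dependency matrices.

    Attributes
    ----------
    auc : DataFrame, drugs x cell lines
    dependency : DataFrame, genes x cell lines (same ordered column axis)
    annotations : dict mapping drug id -> on-target gene id
    """

    auc: pd.DataFrame
    dependency: pd.DataFrame
    annotations: dict

    def __post_init__(self):
        self.auc = self.auc.astype(float)
        self.dependency = self.dependency.astype(float)
        if list(self.auc.columns) != list(self.dependency.columns):
            raise ValidationError("auc and dependency must share an identical, "
                                  "ordered cell-line axis")
        for name, idx in (("cell line", self.auc.columns),
                          ("drug", self.auc.index),
                          ("gene", self.dependency.index)):
            if idx.duplicated().any():
                raise ValidationError(f"duplicated {name} identifiers")
        genes = set(self.dependency.index)
        for drug, target in self.annotations.items():
            if target not in genes:
                raise ValidationError(
                    f"annotated on-target {target!r} for drug {drug!r} "
                    "absent from dependency matrix")

    @property
    def line_ids(self):
        return list(self.auc.columns)

    @property
    def drug_ids(self):
        return list(self.auc.index)

    @property
    def gene_ids(self):
        return list(self.dependency.index)

    @classmethod
    def from_files(cls, auc_path, dependency_path, annotations_path):
        """Load a panel from TSV files (rows = drugs / genes, header = lines).

        The annotations file is two-column TSV: drug_id<TAB>on_target, no
        header required (a ``drug_id`` header row is tolerated).
        """
        auc = pd.read_csv(auc_path, sep="\t", index_col=0)
        dep = pd.read_csv(dependency_path, sep="\t", index_col=0)
        ann = pd.read_csv(annotations_path, sep="\t", header=None,
                          names=["drug_id", "on_target"], dtype=str,
                          comment="#")
        if len(ann) and ann.iloc[0, 0] == "drug_id":
            ann = ann.iloc[1:]
        annotations = dict(zip(ann["drug_id"], ann["on_target"]))
        return cls(auc=auc, dependency=dep, annotations=annotations)


@dataclass(frozen=True)
class BaseModelFit:
    """OLS of AUC on the on-target dependency, with intercept."""

    drug_id: str
    on_target: str
    beta0: float
    beta1: float
    r2_base: float
    residuals: pd.Series  # indexed by the complete-case cell lines
    n: int


@dataclass(frozen=True)
class CombinedModelFit:
    r2_base: float
    r2_combo: float
    delta_r2: float
    partial_rho: float
    p_value: float
    n: int


@dataclass
class InteractionRecord:
    """One drug / co-target candidate with model and robustness metrics."""

    drug_id: str
    on_target: str
    co_target: str
    r2_base: float
    r2_combo: float
    delta_r2: float
    screen_rho: float
    partial_rho: float
    p_value: float
    q_value: float = math.nan
    perm_p: float = math.nan
    lolo_fraction: float = math.nan
    specificity_p: float = math.nan
    n: int = 0

    def __post_init__(self):
        if self.co_target == self.on_target:
            raise ValidationError("co_target must differ from on_target")
        if self.delta_r2 < -1e-10:
            raise ValidationError(f"negative delta_r2 {self.delta_r2}")


@dataclass(frozen=True)
class DiscoveryConfig:
    """Thresholds and conventions for a discovery run.

    ``top_k`` bounds the number of combined fits per drug (``None`` = all
    screened genes). ``fdr_family`` is ``global`` (one BH family across all
    fitted pairs in the run) or ``per_drug``.
    """

    delta_r2_min: float = 0.02
    fdr_max: float = 0.01
    top_k: int | None = 50
    screen_method: str = "spearman"
    screen_p_max: float | None = None
    min_lines: int = 5
    fdr_family: str = "global"

    def __post_init__(self):
        if self.screen_method not in ("spearman", "pearson"):
            raise ValidationError("screen_method must be spearman or pearson")
        if self.fdr_family not in ("global", "per_drug"):
            raise ValidationError("fdr_family must be global or per_drug")
        if self.min_lines < 3:
            raise ValidationError("min_lines must be >= 3")


@dataclass
class DiscoveryResult:
    records: list
    all_fitted: list
    skip_log: dict
    config: DiscoveryConfig
    metadata: dict = field(default_factory=dict)


def _ols_r2(X, y):
    """R^2 (and coefficients) of y ~ [1, X] by least squares."""
    design = np.column_stack([np.ones(y.shape[0]), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DegenerateInputError("constant response")
    r2 = 1.0 - float(resid @ resid) / sst
    return beta, resid, float(r2)


def fit_base_model(panel, drug_id, min_lines=5):
    """Fit AUC ~ on-target dependency for one drug on complete-case lines."""
    if drug_id not in panel.annotations:
        raise AnnotationError(f"drug {drug_id!r} has no on-target annotation")
    if drug_id not in panel.auc.index:
        raise ValidationError(f"drug {drug_id!r} absent from AUC matrix")
    on_target = panel.annotations[drug_id]
    auc = panel.auc.loc[drug_id]
    dep = panel.dependency.loc[on_target]
    mask = auc.notna() & dep.notna()
    n = int(mask.sum())
    if n < min_lines:
        raise InsufficientDataError(
            f"drug {drug_id!r}: {n} complete lines (need >= {min_lines})")
    y = auc[mask].to_numpy()
    x = dep[mask].to_numpy()
    if np.min(y) == np.max(y):
        raise DegenerateInputError(f"drug {drug_id!r}: constant AUC")
    if np.min(x) == np.max(x):
        raise DegenerateInputError(
            f"drug {drug_id!r}: constant on-target dependency")
    beta, resid, r2 = _ols_r2(x[:, None], y)
    residuals = pd.Series(resid, index=auc.index[mask])
    return BaseModelFit(drug_id=drug_id, on_target=on_target,
                        beta0=float(beta[0]), beta1=float(beta[1]),
                        r2_base=r2, residuals=residuals, n=n)


def screen_residuals(fit, panel, exclude=(), method="spearman", min_lines=5):
    """Correlate base-model residuals with every gene's dependency profile.

    The on-target gene is always excluded. Genes failing preconditions
    (constant, too few complete pairs) are skipped and tallied in the
    returned frame's ``attrs['skipped']``.

    Returns a DataFrame with columns ``gene``, ``screen_rho``, ``p``, sorted
    by \\|screen_rho\\| descending with ties broken by gene id.
    """
    if fit.n < min_lines:
        raise InsufficientDataError("base fit has too few residuals")
    excluded = set(exclude) | {fit.on_target}
    genes = [g for g in panel.dependency.index if g not in excluded]
    skipped = {"degenerate": 0, "insufficient": 0}
    rows = []
    if not genes:
        out = pd.DataFrame(columns=["gene", "screen_rho", "p"])
        out.attrs["skipped"] = skipped
        return out
    resid = fit.residuals
    auc_scale = float(np.nanmax(np.abs(panel.auc.loc[fit.drug_id].to_numpy())))
    if float(np.max(np.abs(resid.to_numpy()))) <= 1e-10 * max(1.0, auc_scale):
        # All-zero (or constant) residuals: every correlation is degenerate.
        skipped["degenerate"] = len(genes)
        out = pd.DataFrame(columns=["gene", "screen_rho", "p"])
        out.attrs["skipped"] = skipped
        return out
    sub = panel.dependency.loc[genes, resid.index]
    values = sub.to_numpy()
    fully_observed = np.isfinite(values).all()
    if fully_observed:
        est, pvals, valid = stats_core.correlate_many(values, resid.to_numpy(),
                                                      method=method)
        skipped["degenerate"] = int((~valid).sum())
        rows = [(g, float(e), float(p))
                for g, e, p, ok in zip(genes, est, pvals, valid) if ok]
    else:
        for g in genes:
            try:
                res = stats_core.correlate(sub.loc[g].to_numpy(),
                                           resid.to_numpy(), method=method)
            except DegenerateInputError:
                skipped["degenerate"] += 1
                continue
            except InsufficientDataError:
                skipped["insufficient"] += 1
                continue
            if res.n < min_lines:
                skipped["insufficient"] += 1
                continue
            rows.append((g, res.estimate, res.p_value))
    out = pd.DataFrame(rows, columns=["gene", "screen_rho", "p"])
    if len(out):
        out = out.sort_values(
            by=["screen_rho", "gene"],
            key=lambda s: -s.abs() if s.name == "screen_rho" else s,
        ).reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


def fit_combined_model(panel, drug_id, co_target, method="spearman",
                       min_lines=5):
    """Fit the two-covariate model and the nested delta R^2 for one pair.

    The base model is refitted on the exact complete-case line set of the
    combined model, so delta R^2 is a true nested gain and cannot be
    negative. The partial correlation of AUC with the co-target dependency
    controls for the on-target dependency (method per config).
    """
    if drug_id not in panel.annotations:
        raise AnnotationError(f"drug {drug_id!r} has no on-target annotation")
    on_target = panel.annotations[drug_id]
    if co_target == on_target:
        raise ValidationError("co_target equals on_target")
    if co_target not in panel.dependency.index:
        raise ValidationError(f"gene {co_target!r} absent from dependency matrix")
    auc = panel.auc.loc[drug_id]
    dep_on = panel.dependency.loc[on_target]
    dep_co = panel.dependency.loc[co_target]
    mask = auc.notna() & dep_on.notna() & dep_co.notna()
    n = int(mask.sum())
    if n < min_lines:
        raise InsufficientDataError(
            f"{drug_id!r}/{co_target!r}: {n} complete lines")
    y = auc[mask].to_numpy()
    x_on = dep_on[mask].to_numpy()
    x_co = dep_co[mask].to_numpy()
    for v, label in ((y, "AUC"), (x_on, "on-target"), (x_co, "co-target")):
        if np.min(v) == np.max(v):
            raise DegenerateInputError(f"{drug_id!r}/{co_target!r}: constant {label}")
    r_on_co = stats_core.correlate(x_on, x_co, method="pearson").estimate
    if abs(r_on_co) > COLLINEARITY_R:
        raise CollinearityError(
            f"dependency profiles of {on_target!r} and {co_target!r} are "
            f"collinear (|r| = {abs(r_on_co):.4f})",
            gene_a=on_target, gene_b=co_target)
    _, _, r2_base = _ols_r2(x_on[:, None], y)
    _, _, r2_combo = _ols_r2(np.column_stack([x_on, x_co]), y)
    partial = stats_core.partial_correlate(y, x_co, x_on, method=method)
    return CombinedModelFit(r2_base=r2_base, r2_combo=r2_combo,
                            delta_r2=r2_combo - r2_base,
                            partial_rho=partial.estimate,
                            p_value=partial.p_value, n=n)


def _corr_rows(B, a):
    """Pearson correlation of each row of B with vector a."""
    ac = a - a.mean()
    Bc = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.einsum("ij,ij->i", Bc, Bc) * (ac @ ac))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, np.clip((Bc @ ac) / denom, -1, 1), np.nan)


def _fast_candidate_stats(y, x_on, cand_raw, cand_rank, method):
    """Vectorized combined-model statistics for fully observed data.

    Uses the closed-form two-regressor R^2 and the recursive
    partial-correlation formula — algebraically identical to the per-pair
    OLS / residual path in :func:`fit_combined_model`.

    Returns (r2_base, r2_combo, delta, partial, p, collinear_mask).
    """
    from scipy import stats as _sps

    n = y.shape[0]
    r_y_on = float(_corr_rows(x_on[None, :], y)[0])
    r_y_c = _corr_rows(cand_raw, y)
    r_on_c = _corr_rows(cand_raw, x_on)
    r2_base = r_y_on ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2_combo = ((r_y_on ** 2 + r_y_c ** 2
                     - 2.0 * r_y_on * r_y_c * r_on_c)
                    / (1.0 - r_on_c ** 2))
    collinear = np.abs(r_on_c) > COLLINEARITY_R
    if method == "spearman":
        ry = _sps.rankdata(y)
        rx = _sps.rankdata(x_on)
        p_y_on = float(_corr_rows(rx[None, :], ry)[0])
        p_y_c = _corr_rows(cand_rank, ry)
        p_on_c = _corr_rows(cand_rank, rx)
    else:
        p_y_on, p_y_c, p_on_c = r_y_on, r_y_c, r_on_c
    with np.errstate(invalid="ignore", divide="ignore"):
        partial = ((p_y_c - p_y_on * p_on_c)
                   / np.sqrt((1.0 - p_y_on ** 2) * (1.0 - p_on_c ** 2)))
    partial = np.clip(partial, -1.0, 1.0)
    df = n - 3
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.maximum(1.0 - partial ** 2, 1e-300)
        t = np.abs(partial) * np.sqrt(df / denom)
    pvals = 2.0 * _sps.t.sf(t, df)
    return r2_base, r2_combo, r2_combo - r2_base, partial, pvals, collinear


def run_discovery(panel, config=None):
    """Run the full screen: base fit, residual screen, combined fits, BH.

    Returns a :class:`DiscoveryResult` whose ``records`` are the retained
    interactions (delta R^2 and FDR thresholds applied), sorted by delta R^2
    descending with deterministic (drug, gene) tie-breaking. ``all_fitted``
    holds every fitted pair with its q-value for downstream inspection.
    """
    config = config or DiscoveryConfig()
    skip_log = {}
    fitted = []
    any_drug_ok = False
    dep_values = panel.dependency.to_numpy()
    fully_observed = bool(np.isfinite(dep_values).all())
    dep_ranks = None
    gene_pos = {g: i for i, g in enumerate(panel.dependency.index)}
    for drug_id in panel.auc.index:
        if drug_id not in panel.annotations:
            skip_log[drug_id] = "unannotated"
            continue
        try:
            base = fit_base_model(panel, drug_id, min_lines=config.min_lines)
        except (InsufficientDataError, DegenerateInputError) as exc:
            skip_log[drug_id] = str(exc)
            continue
        any_drug_ok = True
        candidates = screen_residuals(base, panel, method=config.screen_method,
                                      min_lines=config.min_lines)
        if config.screen_p_max is not None and len(candidates):
            candidates = candidates[candidates["p"] <= config.screen_p_max]
        if config.top_k is not None:
            candidates = candidates.head(config.top_k)
        auc_row = panel.auc.loc[drug_id].to_numpy()
        drug_fully_observed = fully_observed and bool(
            np.isfinite(auc_row).all())
        if drug_fully_observed and len(candidates):
            if config.screen_method == "spearman" and dep_ranks is None:
                from scipy.stats import rankdata as _rankdata
                dep_ranks = _rankdata(dep_values, axis=1)
            idx = np.array([gene_pos[g] for g in candidates["gene"]])
            x_on = dep_values[gene_pos[base.on_target]]
            stats = _fast_candidate_stats(
                auc_row, x_on, dep_values[idx],
                dep_ranks[idx] if dep_ranks is not None else None,
                config.screen_method)
            r2_base, r2_combo, delta, partial, pvals, collinear = stats
            n = auc_row.shape[0]
            for j, (gene, screen_rho) in enumerate(
                    zip(candidates["gene"], candidates["screen_rho"])):
                if collinear[j] or not np.isfinite(partial[j]):
                    skip_log[f"{drug_id}/{gene}"] = "collinear or degenerate"
                    continue
                fitted.append(InteractionRecord(
                    drug_id=drug_id, on_target=base.on_target,
                    co_target=gene, r2_base=float(r2_base),
                    r2_combo=float(r2_combo[j]),
                    delta_r2=max(float(delta[j]), 0.0),
                    screen_rho=float(screen_rho),
                    partial_rho=float(partial[j]),
                    p_value=float(pvals[j]), n=n))
            continue
        for gene, screen_rho in zip(candidates["gene"], candidates["screen_rho"]):
            try:
                fit = fit_combined_model(panel, drug_id, gene,
                                         method=config.screen_method,
                                         min_lines=config.min_lines)
            except (CollinearityError, DegenerateInputError,
                    InsufficientDataError) as exc:
                skip_log[f"{drug_id}/{gene}"] = str(exc)
                continue
            fitted.append(InteractionRecord(
                drug_id=drug_id, on_target=base.on_target, co_target=gene,
                r2_base=fit.r2_base, r2_combo=fit.r2_combo,
                delta_r2=max(fit.delta_r2, 0.0), screen_rho=float(screen_rho),
                partial_rho=fit.partial_rho, p_value=fit.p_value, n=fit.n))
    if not any_drug_ok:
        raise EmptyScreenError("every drug was skipped", skip_log=skip_log)

    if fitted:
        if config.fdr_family == "global":
            qs = stats_core.bh_adjust([r.p_value for r in fitted])
            for rec, q in zip(fitted, qs):
                rec.q_value = float(q)
        else:
            by_drug = {}
            for i, rec in enumerate(fitted):
                by_drug.setdefault(rec.drug_id, []).append(i)
            for idxs in by_drug.values():
                qs = stats_core.bh_adjust([fitted[i].p_value for i in idxs])
                for i, q in zip(idxs, qs):
                    fitted[i].q_value = float(q)

    retained = [r for r in fitted
                if r.delta_r2 > config.delta_r2_min
                and np.isfinite(r.q_value) and r.q_value < config.fdr_max]
    retained.sort(key=lambda r: (-r.delta_r2, r.drug_id, r.co_target))
    metadata = {
        "n_drugs": len(panel.auc.index),
        "n_fitted_pairs": len(fitted),
        "n_retained": len(retained),
        "fdr_family": config.fdr_family,
        "screen_method": config.screen_method,
    }
    return DiscoveryResult(records=retained, all_fitted=fitted,
                           skip_log=skip_log, config=config, metadata=metadata)


_RECORD_COLUMNS = ["drug_id", "on_target", "co_target", "r2_base", "r2_combo",
                   "delta_r2", "screen_rho", "partial_rho", "p_value",
                   "q_value", "perm_p", "lolo_fraction", "specificity_p", "n"]


def records_to_frame(records):
    return pd.DataFrame(
        [{c: getattr(r, c) for c in _RECORD_COLUMNS} for r in records],
        columns=_RECORD_COLUMNS)


def frame_to_records(frame):
    records = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        records.append(InteractionRecord(**{c: d[c] for c in _RECORD_COLUMNS
                                            if c in d}))
    return records


def write_discovery(result, out_path, metadata_path=None):
    """Write retained interactions as TSV plus a run-metadata JSON."""
    records_to_frame(result.records).to_csv(out_path, sep="\t", index=False,
                                            float_format="%.10g")
    if metadata_path is not None:
        meta = dict(result.metadata)
        meta["config"] = {k: getattr(result.config, k)
                          for k in ("delta_r2_min", "fdr_max", "top_k",
                                    "screen_method", "screen_p_max",
                                    "min_lines", "fdr_family")}
        meta["skip_log"] = result.skip_log
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
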