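"""Translational validation in an expression / ex vivo drug-response cohort.

Tests whether expression of a nominated co-target predicts ex vivo drug
response (AUC; lower = more sensitive) in primary specimens, with and
without the on-target gene as a covariate. Samples missing a drug's AUC are
dropped per drug, not cohort-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats_core
from .errors import (
    ConfigError,
    DegenerateInputError,
    GeneNotFoundError,
    InsufficientDataError,
    MappingError,
    QuantileError,
    ValidationError,
)

__all__ = [
    "ExpressionCohort",
    "ValidationResult",
    "map_drug_analogs",
    "validate_interaction",
    "run_validation",
    "quartile_contrast",
    "negative_control_panel",
    "resistance_correlation",
]

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("age", "os_time", "os_event", "cytogenetic_risk")


@dataclass
class ExpressionCohort:
    """Expression, per-sample drug AUC, mutation calls and clinical data.

    All tables share one ordered sample axis (columns for the matrices,
    index for ``clinical``). ``mutations`` holds {0, 1, NaN}.
    """

    expression: pd.DataFrame   # genes x samples
    drug_auc: pd.DataFrame     # drugs x samples
    mutations: pd.DataFrame    # genes x samples
    clinical: pd.DataFrame     # samples x covariates

    def __post_init__(self):
        self.expression = self.expression.astype(float)
        self.drug_auc = self.drug_auc.astype(float)
        self.mutations = self.mutations.astype(float)
        samples = list(self.expression.columns)
        for name, cols in (("drug_auc", self.drug_auc.columns),
                           ("mutations", self.mutations.columns),
                           ("clinical", self.clinical.index)):
            if list(cols) != samples:
                raise ValidationError(
                    f"{name} sample axis does not match expression columns")
        if self.expression.index.duplicated().any():
            raise ValidationError("duplicated expression gene identifiers")

    @property
    def samples(self):
        return list(self.expression.columns)

    def expression_of(self, gene):
        if gene not in self.expression.index:
            raise GeneNotFoundError(f"gene {gene!r} absent from expression")
        return self.expression.loc[gene]

    @classmethod
    def from_dir(cls, path):
        """Load ``expression.tsv``, ``drug_auc.tsv``, ``mutations.tsv`` and
        ``clinical.tsv`` from a directory."""
        import os
        read = lambda name: pd.read_csv(os.path.join(path, name), sep="\t",
                                        index_col=0)
        return cls(expression=read("expression.tsv"),
                   drug_auc=read("drug_auc.tsv"),
                   mutations=read("mutations.tsv"),
                   clinical=read("clinical.tsv"))


@dataclass
class ValidationResult:
    """One validated drug / co-target pair in the cohort."""

    drug_id: str
    co_target: str
    on_target: str
    r_unadjusted: float
    p_unadjusted: float
    coef_joint: float          # AUC units per z-unit of co-target expression
    coef_joint_on: float       # companion on-target coefficient
    partial_pearson: float
    partial_pearson_p: float
    partial_spearman: float
    partial_spearman_p: float
    n: int
    q_value: float = float("nan")
    error_code: str = ""


def map_drug_analogs(mapping, cohort):
    """Resolve a discovery-drug -> cohort-drug analog mapping.

    ``mapping`` is a path to a two-column TSV (discovery_drug, cohort_drug)
    or an equivalent DataFrame. Every mapped cohort drug must exist in the
    cohort's AUC matrix. Returns ``(mapping_dict, unmapped)`` where
    ``unmapped`` is reserved for callers that pass a candidate drug list via
    :func:`run_validation`.
    """
    if isinstance(mapping, (str, bytes)) or hasattr(mapping, "__fspath__"):
        frame = pd.read_csv(mapping, sep="\t", header=None,
                            names=["discovery_drug", "cohort_drug"],
                            dtype=str, comment="#")
        if len(frame) and frame.iloc[0, 0] == "discovery_drug":
            frame = frame.iloc[1:]
    else:
        frame = mapping.copy()
        frame.columns = ["discovery_drug", "cohort_drug"]
    out = {}
    for disc, coh in zip(frame["discovery_drug"], frame["cohort_drug"]):
        if coh not in cohort.drug_auc.index:
            raise MappingError(f"cohort drug {coh!r} absent from AUC matrix")
        out[disc] = coh
    if not out:
        logger.warning("drug-analog mapping is empty")
    return out


def _complete_frame(cohort, genes, drug):
    cols = {g: cohort.expression_of(g) for g in genes}
    if drug not in cohort.drug_auc.index:
        raise ValidationError(f"drug {drug!r} absent from cohort AUC")
    cols["auc"] = cohort.drug_auc.loc[drug]
    return pd.DataFrame(cols).dropna()


def validate_interaction(cohort, drug_id, co_target, on_target,
                         min_samples=10):
    """Test co-target expression against ex vivo AUC for one mapped drug.

    Computes the unadjusted Pearson correlation, the joint OLS of AUC on the
    z-scored co-target and on-target expression (coefficients per z-unit),
    and partial correlations (both Pearson and Spearman) of the co-target
    controlling the on-target. A degenerate partial (e.g. duplicated
    expression) is flagged via ``error_code`` rather than dropped.
    """
    frame = _complete_frame(cohort, [co_target, on_target], drug_id)
    n = len(frame)
    if n < min_samples:
        raise InsufficientDataError(
            f"{drug_id!r}/{co_target!r}: {n} complete samples")
    expr_co = frame[co_target].to_numpy()
    expr_on = frame[on_target].to_numpy()
    auc = frame["auc"].to_numpy()
    unadj = stats_core.correlate(expr_co, auc, method="pearson")
    error_code = ""
    try:
        z_co = stats_core.zscore(expr_co)
        z_on = stats_core.zscore(expr_on)
        design = np.column_stack([np.ones(n), z_co, z_on])
        beta, *_ = np.linalg.lstsq(design, auc, rcond=None)
        coef_co, coef_on = float(beta[1]), float(beta[2])
    except DegenerateInputError:
        coef_co = coef_on = float("nan")
        error_code = "degenerate_joint"
    partials = {}
    for method in ("pearson", "spearman"):
        try:
            res = stats_core.partial_correlate(auc, expr_co, expr_on,
                                               method=method)
            if res.metadata.get("degenerate"):
                error_code = error_code or "degenerate_partial"
            partials[method] = (res.estimate, res.p_value)
        except DegenerateInputError:
            partials[method] = (float("nan"), float("nan"))
            error_code = error_code or "degenerate_partial"
    return ValidationResult(
        drug_id=drug_id, co_target=co_target, on_target=on_target,
        r_unadjusted=unadj.estimate, p_unadjusted=unadj.p_value,
        coef_joint=coef_co, coef_joint_on=coef_on,
        partial_pearson=partials["pearson"][0],
        partial_pearson_p=partials["pearson"][1],
        partial_spearman=partials["spearman"][0],
        partial_spearman_p=partials["spearman"][1],
        n=n, error_code=error_code)


def run_validation(cohort, interactions, mapping, fdr_max=0.05,
                   primary="partial_pearson", use_adjusted_p=True,
                   min_samples=10):
    """Validate each mapped discovery interaction; BH across the run.

    ``interactions`` is an iterable of objects (or a DataFrame) with
    ``drug_id``, ``co_target``, ``on_target`` fields. Discovery drugs absent
    from the mapping are counted in the returned ``skipped`` dict (the
    expected attrition from screen to testable analogs). By default the BH
    family is built on the adjusted (partial) p-values; set
    ``use_adjusted_p=False`` for the unadjusted correlation p.
    """
    if primary not in ("partial_pearson", "partial_spearman"):
        raise ConfigError("primary must be partial_pearson or partial_spearman")
    if isinstance(interactions, pd.DataFrame):
        triples = list(zip(interactions["drug_id"], interactions["co_target"],
                           interactions["on_target"]))
    else:
        triples = [(r.drug_id, r.co_target, r.on_target) for r in interactions]
    results, skipped = [], {}
    for drug, co, on in triples:
        if drug not in mapping:
            skipped[f"{drug}/{co}"] = "no cohort analog"
            continue
        try:
            results.append(validate_interaction(cohort, mapping[drug], co, on,
                                                min_samples=min_samples))
        except (GeneNotFoundError, InsufficientDataError,
                ValidationError) as exc:
            skipped[f"{drug}/{co}"] = str(exc)
    if results:
        if use_adjusted_p:
            ps = [getattr(r, primary + "_p") for r in results]
        else:
            ps = [r.p_unadjusted for r in results]
        for r, q in zip(results, stats_core.bh_adjust(ps)):
            r.q_value = float(q)
    significant = [r for r in results
                   if np.isfinite(r.q_value) and r.q_value < fdr_max]
    logger.info("validation: %d tested, %d significant, %d without analog",
                len(results), len(significant), len(skipped))
    return results, significant, skipped


def quartile_contrast(cohort, gene, drug, min_samples=40, use_t_test=False):
    """Compare drug AUC between the top and bottom expression quartiles.

    Quartile cut points use the linear-interpolation (type-7) quantile
    convention. Q1 = samples with expression <= 25th percentile, Q4 =
    samples >= 75th percentile; the two-sided rank-sum test (or Welch t-test
    when ``use_t_test``) compares Q4 against Q1.
    """
    frame = _complete_frame(cohort, [gene], drug)
    if len(frame) < min_samples:
        raise InsufficientDataError(
            f"{len(frame)} usable samples (need >= {min_samples})")
    expr = frame[gene].to_numpy()
    auc = frame["auc"].to_numpy()
    q25, q75 = np.quantile(expr, [0.25, 0.75])  # type-7 interpolation
    in_q1 = expr <= q25
    in_q4 = expr >= q75
    if q25 == q75 or not in_q1.any() or not in_q4.any() or np.all(in_q1 & in_q4):
        raise QuantileError("expression ties leave a quartile empty")
    auc_q1, auc_q4 = auc[in_q1], auc[in_q4]
    if use_t_test:
        from scipy import stats as sps
        stat, p = sps.ttest_ind(auc_q4, auc_q1, equal_var=False)
        stat, p = float(stat), float(p)
    else:
        res = stats_core.rank_sum_test(auc_q4, auc_q1)
        stat, p = res.statistic, res.p_value
    return {"q1_mean": float(auc_q1.mean()), "q4_mean": float(auc_q4.mean()),
            "statistic": stat, "p": p,
            "n_q1": int(in_q1.sum()), "n_q4": int(in_q4.sum())}


def negative_control_panel(cohort, gene, focal_drug, control_drugs,
                           method="pearson"):
    """Correlate a gene's expression with a panel of control drugs.

    Returns a DataFrame (one row per drug, focal first) with r, p, n and BH
    q across the panel, plus ``attrs['focal_strongest']`` — True iff the
    focal drug's \\|r\\| exceeds every control's.
    """
    control_drugs = list(control_drugs)
    if not control_drugs:
        raise ConfigError("control drug list is empty")
    rows = []
    for drug in [focal_drug] + control_drugs:
        frame = _complete_frame(cohort, [gene], drug)
        try:
            res = stats_core.correlate(frame[gene], frame["auc"], method=method)
            rows.append((drug, res.estimate, res.p_value, res.n))
        except (DegenerateInputError, InsufficientDataError) as exc:
            rows.append((drug, float("nan"), float("nan"), len(frame)))
            logger.warning("control drug %s skipped: %s", drug, exc)
    out = pd.DataFrame(rows, columns=["drug_id", "r", "p", "n"])
    out["q"] = stats_core.bh_adjust(out["p"].to_numpy())
    focal_r = abs(out.loc[0, "r"])
    controls_r = out.loc[1:, "r"].abs()
    out.attrs["focal_strongest"] = bool(np.isfinite(focal_r)
                                        and (focal_r > controls_r).all())
    return out


def resistance_correlation(cohort, gene, drug, method="pearson"):
    """Correlation of gene expression with a drug's AUC (positive r =
    resistance under the lower-AUC-is-sensitive convention)."""
    frame = _complete_frame(cohort, [gene], drug)
    return stats_core.correlate(frame[gene], frame["auc"], method=method)
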