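"""Composite-signature survival analysis.

Implements the linear predictor (sum of weighted per-gene z-scores), median
split, Kaplan-Meier / log-rank, Cox proportional hazards with the Efron tie
correction fitted by Newton iteration, a ladder of progressively adjusted
multivariable models, IPCW cumulative/dynamic time-dependent AUC, and
mutation-subgroup contrasts.

Times are taken in days; AUC horizons are given in years and converted with
365.25 days/year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats_core
from .errors import (
    ConvergenceError,
    DegenerateInputError,
    DegenerateSplitWarning,
    GeneNotFoundError,
    GroupError,
    HorizonError,
    InsufficientDataError,
    NoEventsError,
    SeparationError,
    ValidationError,
)

__all__ = [
    "LinearPredictor",
    "KMCurve",
    "SurvivalFit",
    "compute_lp",
    "median_split",
    "km_estimate",
    "logrank",
    "cox_fit",
    "multivariable_suite",
    "timedep_auc",
    "mutation_contrast",
]

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class LinearPredictor:
    """Per-sample composite score: weighted sum of per-gene z-scores."""

    genes: tuple
    weights: tuple
    scores: pd.Series

    def __post_init__(self):
        if len(self.genes) != len(self.weights):
            raise ValidationError("genes and weights must have equal length")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve for one group."""

    label: str
    times: np.ndarray      # sorted distinct event times
    survival: np.ndarray   # S(t) just after each event time, nonincreasing
    at_risk: np.ndarray    # subjects at risk just before each event time
    n: int
    n_events: int


@dataclass(frozen=True)
class SurvivalFit:
    """Cox proportional-hazards fit (Efron ties, Newton iteration)."""

    covariates: tuple
    coef: np.ndarray
    se: np.ndarray
    hazard_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    wald_p: np.ndarray
    n: int
    n_events: int
    ties_method: str = "efron"
    loglik: float = float("nan")

    def summary(self):
        return pd.DataFrame({
            "coef": self.coef, "se": self.se, "hazard_ratio": self.hazard_ratio,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "wald_p": self.wald_p,
        }, index=list(self.covariates))


def compute_lp(expression, genes, weights=None):
    """Build the composite linear predictor from an expression matrix.

    Each gene is z-scored across samples (sample sd) and the weighted sum is
    taken per sample. Default weights are all 1, in which case the scores
    have mean ~0 by construction.
    """
    genes = list(genes)
    if weights is None:
        weights = [1.0] * len(genes)
    weights = [float(w) for w in weights]
    if len(weights) != len(genes):
        raise ValidationError("genes and weights must have equal length")
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise GeneNotFoundError(f"genes absent from expression: {missing}")
    total = np.zeros(expression.shape[1])
    for gene, w in zip(genes, weights):
        total = total + w * stats_core.zscore(expression.loc[gene].to_numpy())
    return LinearPredictor(genes=tuple(genes), weights=tuple(weights),
                           scores=pd.Series(total, index=expression.columns))


def median_split(lp):
    """Label samples ``high`` (score > median) or ``low`` (score <= median).

    Scores exactly at the median go to ``low``. If every score is tied a
    :class:`DegenerateSplitWarning` is emitted and all samples are ``low``.
    """
    scores = lp.scores if isinstance(lp, LinearPredictor) else pd.Series(lp)
    if len(scores) < 4:
        raise InsufficientDataError("median split needs >= 4 samples")
    med = float(scores.median())
    labels = pd.Series(np.where(scores > med, "high", "low"),
                       index=scores.index)
    if (labels == "low").all():
        warnings.warn("all scores at or below the median; split is degenerate",
                      DegenerateSplitWarning)
    return labels


def _check_times_events(times, events):
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events, dtype=float).ravel()
    if times.shape != events.shape:
        raise ValidationError("times and events must have equal length")
    if np.any(~np.isfinite(times)) or np.any(times <= 0):
        raise ValidationError("times must be positive and finite")
    if not np.all(np.isin(events, (0.0, 1.0))):
        raise ValidationError("events must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events, groups=None):
    """Kaplan-Meier product-limit curves, one per group.

    Returns a dict label -> :class:`KMCurve`. With no events a curve is flat
    at 1.0 (empty step arrays).
    """
    times, events = _check_times_events(times, events)
    groups = (np.asarray(["all"] * len(times), dtype=object) if groups is None
              else np.asarray(groups, dtype=object).ravel())
    curves = {}
    for label in pd.unique(groups):
        sel = groups == label
        if not sel.any():
            raise GroupError(f"group {label!r} has no subjects")
        t, e = times[sel], events[sel]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        event_times = np.unique(t[e == 1])
        surv, risk = [], []
        s = 1.0
        for et in event_times:
            n_risk = int(np.sum(t >= et))
            d = int(np.sum((t == et) & (e == 1)))
            s *= 1.0 - d / n_risk
            surv.append(s)
            risk.append(n_risk)
        curves[label] = KMCurve(label=str(label), times=event_times,
                                survival=np.asarray(surv),
                                at_risk=np.asarray(risk, dtype=int),
                                n=int(sel.sum()), n_events=int(e.sum()))
    return curves


def logrank(times, events, groups):
    """k-sample log-rank test with hypergeometric variance.

    Returns ``(chi2, p)`` with ``k - 1`` degrees of freedom.
    """
    times, events = _check_times_events(times, events)
    groups = np.asarray(groups, dtype=object).ravel()
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise GroupError("log-rank needs at least two groups")
    if events.sum() == 0:
        raise NoEventsError("no events observed; log-rank undefined")
    k = len(labels)
    gidx = np.array([np.where(labels == g)[0][0] for g in groups])
    observed = np.zeros(k)
    expected = np.zeros(k)
    var = np.zeros((k, k))
    for et in np.unique(times[events == 1]):
        at_risk = times >= et
        n = int(at_risk.sum())
        d = int(((times == et) & (events == 1)).sum())
        n_g = np.array([(at_risk & (gidx == j)).sum() for j in range(k)],
                       dtype=float)
        d_g = np.array([((times == et) & (events == 1) & (gidx == j)).sum()
                        for j in range(k)], dtype=float)
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            frac = n_g / n
            v = d * (n - d) / (n - 1)
            var += v * (np.diag(frac) - np.outer(frac, frac))
    diff = (observed - expected)[:-1]
    vmat = var[:-1, :-1]
    try:
        chi2 = float(diff @ np.linalg.solve(vmat, diff))
    except np.linalg.LinAlgError:
        chi2 = float(diff @ np.linalg.pinv(vmat) @ diff)
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, k - 1))
    return chi2, p


def _efron_loglik(beta, times, events, X):
    """Efron partial log-likelihood with gradient and Hessian.

    Subjects are pre-sorted by descending time so risk sets are prefixes.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # stabilize exponentials; shifts cancel
    w = np.exp(eta)
    wX = X * w[:, None]
    wXX = np.einsum("ij,ik,i->ijk", X, X, w)
    # prefix sums over the descending-time order = risk-set sums
    cw = np.cumsum(w)
    cwX = np.cumsum(wX, axis=0)
    cwXX = np.cumsum(wXX, axis=0)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] == times[i]:
            j += 1
        # tie block [i, j]; risk set = rows 0..j
        d_idx = [r for r in range(i, j + 1) if events[r] == 1]
        m = len(d_idx)
        if m:
            s_r = cw[j]
            sx_r = cwX[j]
            sxx_r = cwXX[j]
            s_d = w[d_idx].sum()
            sx_d = wX[d_idx].sum(axis=0)
            sxx_d = wXX[d_idx].sum(axis=0)
            ll += float(eta[d_idx].sum())
            grad += X[d_idx].sum(axis=0)
            for l in range(m):
                f = l / m
                denom = s_r - f * s_d
                num_x = sx_r - f * sx_d
                num_xx = sxx_r - f * sxx_d
                ll -= np.log(denom)
                mu = num_x / denom
                grad -= mu
                hess -= num_xx / denom - np.outer(mu, mu)
        i = j + 1
    return ll, grad, hess


def cox_fit(times, events, covariates, ties="efron", max_iter=50, tol=1e-8):
    """Cox proportional-hazards regression via Newton iteration.

    ``covariates`` is a DataFrame (samples x covariates) or 2-D array.
    Efron tie correction; convergence when the gradient norm drops below
    ``tol``. Raises :class:`SeparationError` on monotone likelihood and
    :class:`ConvergenceError` after ``max_iter`` iterations.
    """
    if ties != "efron":
        raise ValidationError("only the efron tie method is implemented")
    times, events = _check_times_events(times, events)
    if isinstance(covariates, pd.DataFrame):
        names = tuple(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] == 1 and len(times) > 1:
            X = X.T
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    if X.shape[0] != times.shape[0]:
        raise ValidationError("covariate rows must match number of subjects")
    if np.any(~np.isfinite(X)):
        raise ValidationError("covariates must be complete (drop NaN first)")
    n_events = int(events.sum())
    if n_events == 0:
        raise NoEventsError("no events observed")
    if n_events < 5 * X.shape[1]:
        logger.warning("only %d events for %d covariates", n_events, X.shape[1])
    for j in range(X.shape[1]):
        if np.min(X[:, j]) == np.max(X[:, j]):
            raise DegenerateInputError(f"covariate {names[j]!r} is constant")
    order = np.argsort(-times, kind="stable")
    t_s, e_s, X_s = times[order], events[order], X[order]
    beta = np.zeros(X.shape[1])
    ll, grad, hess = _efron_loglik(beta, t_s, e_s, X_s)
    for _ in range(max_iter):
        # gradient tolerance scaled by the log-likelihood magnitude: the
        # achievable gradient floor grows with |ll| through rounding noise
        if np.linalg.norm(grad) < tol * (1.0 + abs(ll)):
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        if np.linalg.norm(step) < 1e-12 * (1.0 + np.linalg.norm(beta)):
            break  # floating-point noise floor; effectively converged
        # step-halving to guarantee likelihood ascent
        scale = 1.0
        for _ in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_hess = _efron_loglik(new_beta, t_s, e_s, X_s)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.any(np.abs(beta) > 30):
            raise SeparationError(
                "coefficients diverging; monotone likelihood "
                "(complete separation)")
    else:
        raise ConvergenceError(
            f"Newton iteration did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.2e})")
    if np.any(np.abs(beta) > 15):
        # a flat likelihood can satisfy the gradient tolerance while the
        # coefficient runs away; treat it as monotone likelihood
        raise SeparationError(
            "coefficient magnitude implausible (complete separation)")
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald_p = 2.0 * sps.norm.sf(np.abs(z))
    return SurvivalFit(
        covariates=names, coef=beta, se=se, hazard_ratio=np.exp(beta),
        ci_low=np.exp(beta - 1.959963984540054 * se),
        ci_high=np.exp(beta + 1.959963984540054 * se),
        wald_p=wald_p, n=int(times.shape[0]), n_events=n_events,
        ties_method="efron", loglik=float(ll))


DEFAULT_LADDER = (
    ("lp", ("lp",)),
    ("lp_age", ("lp", "age")),
    ("lp_age_cyto", ("lp", "age", "cyto")),
    ("lp_age_molecular", ("lp", "age", "FLT3", "NPM1", "TP53")),
    ("lp_age_molecular_idh", ("lp", "age", "FLT3", "NPM1", "TP53",
                              "IDH1", "IDH2")),
)


def _design_matrix(cohort, lp, covariate_names):
    """Assemble a per-model design with complete-case rows.

    ``cyto`` expands to two indicators (intermediate, poor) against the
    favorable reference; rows with missing risk category are dropped.
    Mutation covariates come from the cohort's mutation matrix.
    """
    cols = {}
    for name in covariate_names:
        if name == "lp":
            cols["lp"] = lp.scores
        elif name == "cyto":
            risk = cohort.clinical["cytogenetic_risk"].astype(object)
            risk = risk.where(risk.isin(["favorable", "intermediate", "poor"]))
            cols["cyto_intermediate"] = (risk == "intermediate").astype(float)
            cols["cyto_poor"] = (risk == "poor").astype(float)
            na = risk.isna()
            cols["cyto_intermediate"][na] = np.nan
            cols["cyto_poor"][na] = np.nan
        elif name in cohort.clinical.columns:
            cols[name] = cohort.clinical[name].astype(float)
        elif name in cohort.mutations.index:
            cols[name] = cohort.mutations.loc[name]
        else:
            raise ValidationError(f"covariate {name!r} not found in cohort")
    design = pd.DataFrame(cols)
    design["os_time"] = cohort.clinical["os_time"].astype(float)
    design["os_event"] = cohort.clinical["os_event"].astype(float)
    return design.dropna()


def multivariable_suite(cohort, lp, ladder=DEFAULT_LADDER):
    """Fit the ladder of progressively adjusted Cox models.

    Each model is complete-case; covariates that are constant after
    complete-case filtering (e.g. zero mutants) are dropped with a warning.
    Returns a list of ``(model_name, SurvivalFit)``.
    """
    fits = []
    for name, covs in ladder:
        design = _design_matrix(cohort, lp, covs)
        times = design.pop("os_time").to_numpy()
        events = design.pop("os_event").to_numpy()
        keep = []
        for col in design.columns:
            v = design[col].to_numpy()
            if np.min(v) == np.max(v):
                logger.warning("model %s: dropping constant covariate %s",
                               name, col)
                continue
            keep.append(col)
        fit = cox_fit(times, events, design[keep])
        fits.append((name, fit))
    return fits


def _censoring_km(times, events):
    """KM estimate of the censoring distribution G(t) = P(C > t)."""
    curves = km_estimate(times, 1 - events)
    curve = curves["all"]

    def G(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.ones_like(t)
        for i, ti in enumerate(t):
            idx = np.searchsorted(curve.times, ti, side="right") - 1
            out[i] = curve.survival[idx] if idx >= 0 else 1.0
        return out

    return G


def timedep_auc(times, events, marker, horizons_years, min_events=10):
    """IPCW cumulative/dynamic AUC(t) at each horizon (years).

    Cases at horizon t are subjects with an event by t; controls are
    event-free at t. Inverse-probability-of-censoring weights come from a
    Kaplan-Meier fit on the flipped event indicator. Higher marker = higher
    risk. Returns a dict ``horizon_years -> auc``.
    """
    times, events = _check_times_events(times, events)
    marker = np.asarray(marker, dtype=float).ravel()
    if marker.shape != times.shape:
        raise ValidationError("marker length must match times")
    G = _censoring_km(times, events)
    out = {}
    for h in horizons_years:
        t_h = float(h) * DAYS_PER_YEAR
        if t_h >= times.max():
            raise HorizonError(
                f"horizon {h} y ({t_h:.0f} d) beyond max follow-up "
                f"({times.max():.0f} d)")
        is_case = (times <= t_h) & (events == 1)
        is_control = times > t_h
        n_cases = int(is_case.sum())
        if n_cases < min_events:
            logger.warning("horizon %s y: only %d events", h, n_cases)
        if n_cases == 0 or not is_control.any():
            out[float(h)] = float("nan")
            continue
        # G evaluated just before the case's event time
        w_case = 1.0 / np.maximum(G(times[is_case] - 1e-9), 1e-12)
        w_ctrl = np.full(int(is_control.sum()),
                         1.0 / max(float(G(t_h)[0]), 1e-12))
        m_case = marker[is_case]
        m_ctrl = marker[is_control]
        diff = m_case[:, None] - m_ctrl[None, :]
        conc = (diff > 0) + 0.5 * (diff == 0)
        wmat = np.outer(w_case, w_ctrl)
        out[float(h)] = float((conc * wmat).sum() / wmat.sum())
    return out


def mutation_contrast(scores, mutations, gene_list, min_mutants=5):
    """Compare a per-sample score between mutated and wild-type samples.

    One rank-sum test per gene with BH across the tested genes. Genes with
    fewer than ``min_mutants`` mutants (or all-missing calls) are skipped
    with a reason. Returns ``(table, skipped)``.
    """
    scores = pd.Series(scores)
    rows, skipped = [], {}
    for gene in gene_list:
        if gene not in mutations.index:
            skipped[gene] = "no mutation calls"
            continue
        calls = mutations.loc[gene].reindex(scores.index)
        mask = calls.notna() & scores.notna()
        mut = scores[mask & (calls == 1)]
        wt = scores[mask & (calls == 0)]
        if len(mut) == 0 and len(wt) == 0:
            skipped[gene] = "all calls missing"
            continue
        if len(mut) < min_mutants:
            skipped[gene] = f"only {len(mut)} mutants (need >= {min_mutants})"
            continue
        if len(wt) < 2:
            skipped[gene] = "too few wild-type samples"
            continue
        res = stats_core.rank_sum_test(mut.to_numpy(), wt.to_numpy())
        rows.append((gene, len(mut), len(wt), float(mut.median()),
                     float(wt.median()), res.p_value))
    table = pd.DataFrame(rows, columns=["gene", "n_mut", "n_wt", "median_mut",
                                        "median_wt", "p"])
    if len(table):
        table["q"] = stats_core.bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = pd.Series(dtype=float)
        warnings.warn("no genes testable for mutation contrast")
    return table, skipped
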