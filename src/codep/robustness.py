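"""Robustness assessment of discovered interactions.

Three complementary checks per interaction: a label-permutation test on the
drug's AUC vector, leave-one-line-out refitting, and a random-drug
specificity test. Empirical p-values use the add-one estimator
``(1 + #extreme) / (1 + #null)`` and therefore can never be zero.
"""

from __future__ import annotations

import numpy as np

from . import stats_core
from .discovery import _ols_r2
from .errors import (
    ConfigError,
    DegenerateInputError,
    InsufficientDataError,
)

__all__ = ["permutation_test", "lolo", "specificity_test", "run_robustness"]


def _record_arrays(panel, record):
    """Complete-case (auc, dep_on, dep_co) arrays for a record's drug."""
    auc = panel.auc.loc[record.drug_id]
    dep_on = panel.dependency.loc[record.on_target]
    dep_co = panel.dependency.loc[record.co_target]
    mask = auc.notna() & dep_on.notna() & dep_co.notna()
    return (auc[mask].to_numpy(), dep_on[mask].to_numpy(),
            dep_co[mask].to_numpy())


def _delta_r2(y, x_on, x_co):
    _, _, r2_base = _ols_r2(x_on[:, None], y)
    _, _, r2_combo = _ols_r2(np.column_stack([x_on, x_co]), y)
    return r2_combo - r2_base


def permutation_test(panel, record, n_perm=200, seed=0, rng=None):
    """Empirical p for delta R^2 under shuffled drug-sensitivity labels.

    The drug's AUC vector is permuted across cell lines ``n_perm`` times
    with the dependency matrix fixed; the combined-versus-base gain is
    recomputed for each shuffle.
    """
    if n_perm < 20:
        raise ConfigError(f"n_perm = {n_perm} is too small (need >= 20)")
    rng = rng if rng is not None else np.random.default_rng(seed)
    y, x_on, x_co = _record_arrays(panel, record)
    observed = _delta_r2(y, x_on, x_co)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(y)
        try:
            if _delta_r2(perm, x_on, x_co) >= observed:
                exceed += 1
        except DegenerateInputError:  # pragma: no cover - constant shuffle
            continue
    return (1 + exceed) / (1 + n_perm)


def lolo(panel, record, method="spearman"):
    """Leave-one-line-out stability of an interaction.

    Each complete-case cell line is held out in turn and the base and
    combined models are refitted on the remainder. An iteration counts as
    positive iff delta R^2 > 0 AND the partial correlation keeps the
    full-panel sign. Degenerate refits count as not positive.

    Returns
    -------
    (fraction, n_iterations)
    """
    y, x_on, x_co = _record_arrays(panel, record)
    n = y.shape[0]
    if n < 6:
        raise InsufficientDataError(f"need >= 6 complete lines, got {n}")
    full_sign = np.sign(
        stats_core.partial_correlate(y, x_co, x_on, method=method).estimate)
    positives = 0
    for i in range(n):
        keep = np.arange(n) != i
        yi, oni, coi = y[keep], x_on[keep], x_co[keep]
        try:
            delta = _delta_r2(yi, oni, coi)
            sign = np.sign(
                stats_core.partial_correlate(yi, coi, oni,
                                             method=method).estimate)
        except (DegenerateInputError, InsufficientDataError):
            continue
        if delta > 0 and sign == full_sign:
            positives += 1
    return positives / n, n


def specificity_test(panel, record, n_random_drugs=100, seed=0, rng=None,
                     method="spearman"):
    """Is the co-target a nonspecific predictor of unrelated drugs?

    Samples ``n_random_drugs`` other drugs uniformly without replacement.
    For each, the |partial correlation| of its AUC with the co-target's
    dependency (controlling that drug's own on-target; plain correlation if
    unannotated) is compared with the record's observed |partial rho|.
    """
    others = [d for d in panel.auc.index if d != record.drug_id]
    if len(others) < n_random_drugs:
        raise ConfigError(
            f"panel has {len(others)} other drugs; need >= {n_random_drugs}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(others, dtype=object), size=n_random_drugs,
                        replace=False)
    dep_co = panel.dependency.loc[record.co_target]
    observed = abs(record.partial_rho)
    exceed = 0
    for drug in chosen:
        auc = panel.auc.loc[drug]
        on_target = panel.annotations.get(drug)
        try:
            if on_target is not None and on_target != record.co_target:
                dep_on = panel.dependency.loc[on_target]
                mask = auc.notna() & dep_on.notna() & dep_co.notna()
                res = stats_core.partial_correlate(
                    auc[mask].to_numpy(), dep_co[mask].to_numpy(),
                    dep_on[mask].to_numpy(), method=method)
            else:
                mask = auc.notna() & dep_co.notna()
                res = stats_core.correlate(auc[mask].to_numpy(),
                                           dep_co[mask].to_numpy(),
                                           method=method)
        except (DegenerateInputError, InsufficientDataError):
            continue
        if abs(res.estimate) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_random_drugs)


def run_robustness(panel, records, n_perm=200, n_random_drugs=None, seed=0,
                   method="spearman"):
    """Annotate records in place with perm_p, lolo_fraction, specificity_p.

    Each record gets independent RNG streams keyed by (master seed, record
    index), so per-record results do not depend on processing order. The
    specificity test is skipped (NaN) when the panel is too small for
    ``n_random_drugs``.
    """
    n_drugs = len(panel.auc.index)
    if n_random_drugs is None:
        n_random_drugs = min(100, n_drugs - 1)
    for i, record in enumerate(records):
        perm_rng = np.random.default_rng(np.random.SeedSequence([seed, i, 0]))
        spec_rng = np.random.default_rng(np.random.SeedSequence([seed, i, 1]))
        record.perm_p = permutation_test(panel, record, n_perm=n_perm,
                                         rng=perm_rng)
        record.lolo_fraction, _ = lolo(panel, record, method=method)
        try:
            record.specificity_p = specificity_test(
                panel, record, n_random_drugs=n_random_drugs, rng=spec_rng,
                method=method)
        except ConfigError:
            record.specificity_p = float("nan")
    return records
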