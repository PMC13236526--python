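"""Preranked gene-set enrichment and simplified regulon-activity scoring.

The enrichment score is the classical weighted Kolmogorov-Smirnov running
sum on a score-ranked gene list; the null distribution comes from
gene-label permutation (random member sets of matching size), NES uses
sign-matched normalization and FDR the standard sign-pooled procedure.

Regulon activity is a signed mean of z-scored target expression — a
deliberately simplified stand-in for full regulon-inference statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats_core
from .errors import InsufficientDataError, ValidationError
from .signature import landscape

__all__ = [
    "GeneSetCollection",
    "RegulonCollection",
    "read_gmt",
    "write_gmt",
    "read_regulons",
    "write_regulons",
    "rank_metric",
    "enrichment_score",
    "gsea_preranked",
    "regulon_activity",
    "correlate_activity",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. parsed from a GMT file."""

    sets: dict              # name -> list of member genes
    source: str = ""

    def filtered(self, universe, min_size=5, max_size=500):
        """Intersect with a gene universe and drop under/oversized sets."""
        universe = set(universe)
        kept, dropped = {}, {}
        for name, members in self.sets.items():
            inter = [g for g in members if g in universe]
            if len(inter) < min_size:
                dropped[name] = f"only {len(inter)} members in universe"
            elif len(inter) > max_size:
                dropped[name] = f"{len(inter)} members exceeds max {max_size}"
            else:
                kept[name] = inter
        return GeneSetCollection(kept, self.source), dropped


@dataclass
class RegulonCollection:
    """Transcription-factor regulons: target genes with +/-1 modes."""

    regulons: dict          # tf -> list of (target, mode)
    source: str = ""


def read_gmt(path):
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection, path, description="na"):
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = collection.sets[name]
            fh.write("\t".join([name, description] + list(members)) + "\n")


def read_regulons(path):
    """Read a regulon TSV: tf<TAB>target<TAB>mode (+1/-1)."""
    frame = pd.read_csv(path, sep="\t", header=None,
                        names=["tf", "target", "mode"], comment="#", dtype=str)
    if len(frame) and frame.iloc[0, 0] == "tf":
        frame = frame.iloc[1:]
    regulons = {}
    for tf, target, mode in zip(frame["tf"], frame["target"], frame["mode"]):
        m = int(float(mode))
        if m not in (1, -1):
            raise ValidationError(f"regulon mode must be +/-1, got {mode}")
        regulons.setdefault(tf, []).append((target, m))
    return RegulonCollection(regulons, source=str(path))


def write_regulons(collection, path):
    with open(path, "w") as fh:
        for tf in sorted(collection.regulons):
            for target, mode in collection.regulons[tf]:
                fh.write(f"{tf}\t{target}\t{mode:+d}\n")


def rank_metric(expression, lp):
    """Genes sorted by Spearman correlation with the LP, descending.

    Thin wrapper over :func:`codep.signature.landscape`; returns the same
    table (already sorted most-positive first).
    """
    return landscape(expression, lp)


def enrichment_score(scores, hit_positions, weight_p=1.0):
    """Weighted KS enrichment score for one set.

    Parameters
    ----------
    scores : ranking scores sorted descending (length N)
    hit_positions : 0-based positions of set members within the ranking
    weight_p : hit-increment exponent on \\|score\\|

    Returns the signed maximum deviation of the running sum (hit increments
    proportional to \\|score\\|^p, miss decrements uniform).
    """
    scores = np.asarray(scores, dtype=float)
    hits = np.asarray(sorted(hit_positions), dtype=int)
    N = scores.shape[0]
    k = hits.shape[0]
    if k == 0:
        raise ValidationError("empty hit set")
    if N == k:
        if weight_p == 0:
            return 0.0
        raise ValidationError("set spans the whole universe (no miss pool)")
    if weight_p == 0:
        w = np.ones(k)
    else:
        w = np.abs(scores[hits]) ** weight_p
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    cum_hit = np.cumsum(w) / total
    miss_step = 1.0 / (N - k)
    # running-sum extrema can only occur immediately after a hit (peak) or
    # immediately before one (valley)
    j = np.arange(k)
    peak = cum_hit - (hits - j) * miss_step
    valley = np.concatenate([[0.0], cum_hit[:-1]]) - (hits - j) * miss_step
    # after the last hit the sum decays to 0, adding no new extremum;
    # interleave valley/peak in positional order so an exact |peak|=|valley|
    # tie resolves to the earlier extremum (argmax returns the first max)
    candidates = np.empty(2 * k)
    candidates[0::2] = valley
    candidates[1::2] = peak
    es = float(candidates[np.argmax(np.abs(candidates))])
    return es


def _null_es(scores, set_size, n_perm, rng, weight_p):
    N = scores.shape[0]
    out = np.empty(n_perm)
    for i in range(n_perm):
        pos = rng.choice(N, size=set_size, replace=False)
        out[i] = enrichment_score(scores, pos, weight_p)
    return out


def gsea_preranked(ranked, sets, weight_p=1.0, n_perm=1000, seed=0,
                   min_size=5, max_size=500):
    """Preranked GSEA over a collection of gene sets.

    Parameters
    ----------
    ranked : DataFrame indexed by gene with a ``rho`` column (output of
        :func:`rank_metric`), or a Series of scores indexed by gene —
        either way sorted descending by score.
    sets : :class:`GeneSetCollection`

    Notes
    -----
    Null ES per set by gene-label permutation (n_perm random same-size
    sets); NES = ES / mean \\|null ES\\| of the matching sign; nominal p from
    the matching-sign null (add-one); FDR by the sign-pooled NES procedure.
    """
    if isinstance(ranked, pd.DataFrame):
        series = ranked["rho"]
    else:
        series = pd.Series(ranked)
    genes = list(series.index)
    scores = series.to_numpy(dtype=float)
    if len(genes) < 100:
        raise InsufficientDataError("ranked universe must have >= 100 genes")
    if np.any(np.diff(scores) > 1e-12):
        raise ValidationError("ranking scores must be sorted descending")
    position = {g: i for i, g in enumerate(genes)}
    filtered, dropped = sets.filtered(genes, min_size=min_size,
                                     max_size=max_size)
    for name, reason in dropped.items():
        logger.info("set %s skipped: %s", name, reason)
    rng = np.random.default_rng(seed)
    rows = []
    null_nes_pos, null_nes_neg = [], []
    for name in sorted(filtered.sets):
        members = filtered.sets[name]
        hits = [position[g] for g in members]
        es = enrichment_score(scores, hits, weight_p)
        size = len(hits)
        # fresh permutations per set: sharing a null sample across sets
        # would correlate their p-values and break calibration
        null = _null_es(scores, size, n_perm, rng, weight_p)
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        if es >= 0:
            same = pos_null
            mean_mag = pos_null.mean() if pos_null.size else np.nan
        else:
            same = -neg_null
            mean_mag = -neg_null.mean() if neg_null.size else np.nan
        nes = es / mean_mag if mean_mag and np.isfinite(mean_mag) else np.nan
        p = ((1 + int((same >= abs(es)).sum())) / (1 + same.size)
             if same.size else np.nan)
        if pos_null.size:
            null_nes_pos.append(pos_null / pos_null.mean())
        if neg_null.size:
            null_nes_neg.append(-(-neg_null) / (-neg_null).mean())
        rows.append((name, es, nes, p, size))
    table = pd.DataFrame(rows, columns=["set", "es", "nes", "p", "size"])
    all_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    all_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.array([])
    obs_pos = table.loc[table["nes"] >= 0, "nes"].to_numpy()
    obs_neg = table.loc[table["nes"] < 0, "nes"].to_numpy()
    fdr = np.full(len(table), np.nan)
    for i, nes in enumerate(table["nes"]):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = (all_pos >= nes).mean() if all_pos.size else np.nan
            den = (obs_pos >= nes).mean() if obs_pos.size else np.nan
        else:
            num = (all_neg <= nes).mean() if all_neg.size else np.nan
            den = (obs_neg <= nes).mean() if obs_neg.size else np.nan
        if np.isfinite(num) and np.isfinite(den) and den > 0:
            fdr[i] = min(num / den, 1.0)
    table["fdr_q"] = fdr
    table = table.sort_values(by=["nes", "set"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    table.attrs["dropped"] = dropped
    return table


def regulon_activity(expression, regulons, min_size=10):
    """TF-by-sample activity: mean of mode x z-scored target expression.

    Regulons whose target intersection with the expression matrix falls
    below ``min_size`` are skipped (logged). Returns a DataFrame TF x
    samples with ``attrs['skipped']``.
    """
    present = set(expression.index)
    rows, skipped = {}, {}
    for tf in sorted(regulons.regulons):
        entries = [(t, m) for t, m in regulons.regulons[tf] if t in present]
        if len(entries) < min_size:
            skipped[tf] = f"only {len(entries)} targets in expression"
            continue
        acc = np.zeros(expression.shape[1])
        used = 0
        for target, mode in entries:
            try:
                acc = acc + mode * stats_core.zscore(
                    expression.loc[target].to_numpy())
                used += 1
            except Exception:
                continue
        if used < min_size:
            skipped[tf] = f"only {used} non-degenerate targets"
            continue
        rows[tf] = acc / used
    out = pd.DataFrame(rows, index=expression.columns).T
    out.attrs["skipped"] = skipped
    if skipped:
        logger.info("regulon_activity: skipped %d undersized regulons",
                    len(skipped))
    return out


def correlate_activity(activity, lp, top_n=None):
    """Spearman correlation of each TF's activity with the LP.

    BH across all TFs; sorted by \\|rho\\| descending. ``top_n`` truncates the
    table (e.g. a top-15 report).
    """
    scores = lp.scores if hasattr(lp, "scores") else pd.Series(lp)
    rows = []
    for tf in activity.index:
        res = stats_core.correlate(activity.loc[tf].to_numpy(),
                                   scores.reindex(activity.columns).to_numpy(),
                                   method="spearman")
        rows.append((tf, res.estimate, res.p_value, res.n))
    out = pd.DataFrame(rows, columns=["tf", "rho", "p", "n"])
    out["q"] = stats_core.bh_adjust(out["p"].to_numpy())
    out = out.sort_values(by=["rho", "tf"],
                          key=lambda s: -s.abs() if s.name == "rho" else s
                          ).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n)
    return out
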