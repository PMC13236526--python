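"""Synthetic input generators with planted effects of known size.

Every generator is fully deterministic given its seed and returns, next to
the data object, a ground-truth manifest recording the planted parameters —
the contract consumed by the recovery tests.

Conventions mirror the analysis side: lower AUC = greater sensitivity, more
negative dependency = more essential, survival times in days.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_validation import ExpressionCohort
from .discovery import DependencyPanel
from .enrichment import (GeneSetCollection, RegulonCollection, write_gmt,
                         write_regulons)
from .errors import ValidationError
from .signature import CellAtlas

__all__ = [
    "PlantedInteraction",
    "PanelSpec",
    "CohortSpec",
    "AtlasSpec",
    "simulate_panel",
    "simulate_cohort",
    "simulate_atlas",
    "simulate_gene_sets",
    "write_panel",
    "write_cohort",
    "write_atlas",
]


@dataclass(frozen=True)
class PlantedInteraction:
    """One drug with a real on-target effect and a planted co-target effect.

    ``beta_on`` / ``beta_co`` are AUC units per dependency unit;
    ``target_partial_rho`` documents the intended population partial
    correlation (it is implied by beta_co and the panel noise sd:
    rho = -beta_co-sign * |beta_co| / sqrt(beta_co^2 + noise_sd^2) for
    independent standard-normal dependency scores).
    """

    drug: int
    on_target: int
    co_target: int
    beta_on: float
    beta_co: float
    target_partial_rho: float | None = None

    def __post_init__(self):
        if self.on_target == self.co_target:
            raise ValidationError("on_target must differ from co_target")


@dataclass(frozen=True)
class PanelSpec:
    """Parameters for a synthetic drug x gene x cell-line panel."""

    n_lines: int = 15
    n_genes: int = 100
    n_drugs: int = 10
    planted: tuple = ()
    noise_sd: float = 1.0
    seed: int = 0
    auc_baseline: float = 1.0
    essential_fraction: float = 0.0   # fraction of genes given a negative
    essential_shift: float = -1.5     # location shift (Chronos-like skew)

    def __post_init__(self):
        if self.n_lines < 5:
            raise ValidationError("n_lines must be >= 5")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0 <= self.essential_fraction <= 1:
            raise ValidationError("essential_fraction must be in [0, 1]")
        for p in self.planted:
            if not (0 <= p.drug < self.n_drugs):
                raise ValidationError(f"planted drug index {p.drug} out of range")
            for g in (p.on_target, p.co_target):
                if not (0 <= g < self.n_genes):
                    raise ValidationError(f"planted gene index {g} out of range")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters for a synthetic expression / drug-response / survival cohort.

    ``expression_drug_effects`` plants Pearson correlations of stated sign
    and magnitude between a gene's expression and a drug's AUC.
    ``mutation_genes`` entries are (gene, prevalence, lp_shift): mutated
    samples get the stated total shift spread over the signature genes'
    expression. ``age_log_hr`` adds an age effect (per sd of age) to the
    hazard so marker-plus-age models have signal to find.
    """

    n_samples: int = 200
    n_genes: int = 50
    gene_ids: tuple = ()
    expression_drug_effects: tuple = ()   # (gene, drug, target_r)
    null_drugs: tuple = ()
    signature_genes: tuple = ("SRC", "ACSL4")
    true_log_hr_per_lp_unit: float = 0.0
    age_log_hr: float = 0.0
    censoring_rate: float = 0.0
    mutation_genes: tuple = ()            # (gene, prevalence, lp_shift)
    auc_mean: float = 150.0
    auc_sd: float = 50.0
    auc_missing_rate: float = 0.0
    baseline_hazard: float = 1.0 / 500.0  # events per day
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 10:
            raise ValidationError("n_samples must be >= 10")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")
        for gene, drug, r in self.expression_drug_effects:
            if not abs(r) < 1:
                raise ValidationError(f"|target_r| must be < 1 for {drug}")
        for gene, prev, shift in self.mutation_genes:
            if not 0 < prev < 1:
                raise ValidationError("mutation prevalence must be in (0, 1)")
        if not 0 <= self.auc_missing_rate < 1:
            raise ValidationError("auc_missing_rate must be in [0, 1)")

    def resolved_gene_ids(self):
        """Gene identifier list: named genes first, auto-filled to n_genes."""
        named = list(dict.fromkeys(
            list(self.gene_ids)
            + list(self.signature_genes)
            + [g for g, _, _ in self.expression_drug_effects]))
        if len(named) > self.n_genes:
            raise ValidationError("more named genes than n_genes")
        auto = [f"G{i:05d}" for i in range(self.n_genes)]
        filler = [g for g in auto if g not in named]
        return named + filler[: self.n_genes - len(named)]


@dataclass(frozen=True)
class AtlasSpec:
    """Parameters for a labelled single-cell expression atlas."""

    cell_types: tuple = (("typeA", 200), ("typeB", 200))
    enriched_type: str = "typeA"
    enrichment_shift: float = 0.0
    n_genes: int = 50
    signature_genes: tuple = ("SRC", "ACSL4")
    seed: int = 0

    def __post_init__(self):
        labels = [t for t, _ in self.cell_types]
        if self.enriched_type not in labels:
            raise ValidationError(
                f"enriched_type {self.enriched_type!r} not among cell types")
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicated cell-type labels")

    def resolved_gene_ids(self):
        named = list(dict.fromkeys(self.signature_genes))
        if len(named) > self.n_genes:
            raise ValidationError("more signature genes than n_genes")
        auto = [f"G{i:05d}" for i in range(self.n_genes)]
        filler = [g for g in auto if g not in named]
        return named + filler[: self.n_genes - len(named)]


def _manifest(spec, extra):
    out = dataclasses.asdict(spec)
    out.update(extra)
    return out


def simulate_panel(spec):
    """Generate a :class:`DependencyPanel` with planted co-dependencies.

    Dependency scores are standard normal per gene (optionally shifted for
    an "essential" fraction); planted drugs get
    ``AUC = baseline + beta_on * dep(on) + beta_co * dep(co) + noise`` and
    every other drug is baseline plus noise. Null drugs are annotated with a
    random on-target so the discovery screen treats them like real drugs.

    Returns ``(panel, manifest)``.
    """
    rng = np.random.default_rng(spec.seed)
    lines = [f"CL{i:03d}" for i in range(spec.n_lines)]
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    drugs = [f"D{i:04d}" for i in range(spec.n_drugs)]
    dep = rng.standard_normal((spec.n_genes, spec.n_lines))
    if spec.essential_fraction > 0:
        n_ess = int(round(spec.essential_fraction * spec.n_genes))
        ess = rng.choice(spec.n_genes, size=n_ess, replace=False)
        dep[ess] += spec.essential_shift
    auc = spec.auc_baseline + spec.noise_sd * rng.standard_normal(
        (spec.n_drugs, spec.n_lines))
    planted_by_drug = {p.drug: p for p in spec.planted}
    annotations = {}
    for d in range(spec.n_drugs):
        if d in planted_by_drug:
            p = planted_by_drug[d]
            auc[d] += p.beta_on * dep[p.on_target] + p.beta_co * dep[p.co_target]
            annotations[drugs[d]] = genes[p.on_target]
        else:
            annotations[drugs[d]] = genes[int(rng.integers(spec.n_genes))]
    panel = DependencyPanel(
        auc=pd.DataFrame(auc, index=drugs, columns=lines),
        dependency=pd.DataFrame(dep, index=genes, columns=lines),
        annotations=annotations)
    manifest = _manifest(spec, {
        "kind": "panel",
        "planted": [{"drug_id": drugs[p.drug],
                     "on_target": genes[p.on_target],
                     "co_target": genes[p.co_target],
                     "beta_on": p.beta_on, "beta_co": p.beta_co,
                     "target_partial_rho": p.target_partial_rho}
                    for p in spec.planted],
    })
    return panel, manifest


def _solve_censoring_bound(t_event, censor_u, target_rate):
    """Bisect the upper bound c of C ~ U(0, c) so that the realized
    censoring fraction matches ``target_rate`` as closely as possible."""
    lo, hi = 1e-9, float(t_event.max()) * 4 + 1.0
    frac = lambda c: float(np.mean(c * censor_u < t_event))
    # widen until the bracket covers the target
    while frac(hi) > target_rate and hi < 1e12:
        hi *= 2
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohort(spec):
    """Generate an :class:`ExpressionCohort` with planted structure.

    * expression ~ N(0,1) per gene, with mutation-driven shifts applied to
      the signature genes;
    * per-effect drug AUC built so the population Pearson r with the (post
      shift) gene expression equals ``target_r``;
    * survival times exponential with hazard
      ``h0 * exp(log_hr * LP + age_log_hr * z(age))`` and independent
      uniform censoring tuned numerically to the requested rate.

    Returns ``(cohort, manifest)``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = spec.resolved_gene_ids()
    samples = [f"S{i:05d}" for i in range(spec.n_samples)]
    expr = rng.standard_normal((len(gene_ids), spec.n_samples))
    expression = pd.DataFrame(expr, index=gene_ids, columns=samples)

    mut_rows = {}
    for gene, prev, shift in spec.mutation_genes:
        calls = (rng.random(spec.n_samples) < prev).astype(float)
        mut_rows[gene] = calls
        per_gene = shift / len(spec.signature_genes)
        for sig in spec.signature_genes:
            expression.loc[sig] += per_gene * calls
    mutations = pd.DataFrame(mut_rows, index=samples).T
    if mutations.empty:
        mutations = pd.DataFrame(np.empty((0, spec.n_samples)),
                                 columns=samples)

    drug_ids = list(dict.fromkeys(
        [d for _, d, _ in spec.expression_drug_effects]
        + list(spec.null_drugs)))
    auc_rows = {}
    effects_by_drug = {}
    for gene, drug, r in spec.expression_drug_effects:
        if drug in effects_by_drug:
            raise ValidationError(f"multiple effects planted for drug {drug}")
        effects_by_drug[drug] = (gene, r)
    for drug in drug_ids:
        noise = rng.standard_normal(spec.n_samples)
        if drug in effects_by_drug:
            # plant the EXACT sample correlation: mix the standardized gene
            # with noise residualized against it (both unit-norm), so the
            # generated Pearson r equals target_r by construction
            gene, r = effects_by_drug[drug]
            g = expression.loc[gene].to_numpy()
            gz = (g - g.mean()) / g.std()
            eps = noise - (noise @ gz) / (gz @ gz) * gz
            eps = (eps - eps.mean()) / eps.std()
            z = r * gz + np.sqrt(1 - r * r) * eps
        else:
            z = noise
        auc = spec.auc_mean + spec.auc_sd * z
        if spec.auc_missing_rate > 0:
            auc = np.where(rng.random(spec.n_samples) < spec.auc_missing_rate,
                           np.nan, auc)
        auc_rows[drug] = auc
    drug_auc = pd.DataFrame(auc_rows, index=samples).T
    if drug_auc.empty:
        drug_auc = pd.DataFrame(np.empty((0, spec.n_samples)), columns=samples)

    lp = np.zeros(spec.n_samples)
    for sig in spec.signature_genes:
        g = expression.loc[sig].to_numpy()
        lp += (g - g.mean()) / g.std(ddof=1)
    age = rng.normal(60.0, 10.0, spec.n_samples)
    age_z = (age - age.mean()) / age.std(ddof=1)
    hazard = spec.baseline_hazard * np.exp(
        spec.true_log_hr_per_lp_unit * lp + spec.age_log_hr * age_z)
    t_event = rng.exponential(1.0 / hazard)
    t_event = np.maximum(t_event, 1e-3)
    if spec.censoring_rate > 0:
        u = rng.random(spec.n_samples)
        c_bound = _solve_censoring_bound(t_event, u, spec.censoring_rate)
        t_cens = c_bound * u
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        c_bound = float("inf")
        os_time = t_event
        os_event = np.ones(spec.n_samples, dtype=int)

    risk = rng.choice(["favorable", "intermediate", "poor"],
                      size=spec.n_samples, p=[0.2, 0.5, 0.3])
    clinical = pd.DataFrame({
        "age": age,
        "os_time": os_time,
        "os_event": os_event,
        "cytogenetic_risk": risk,
    }, index=samples)

    cohort = ExpressionCohort(expression=expression, drug_auc=drug_auc,
                              mutations=mutations, clinical=clinical)
    manifest = _manifest(spec, {
        "kind": "cohort",
        "censoring_bound": c_bound,
        "true_lp": list(lp),
    })
    return cohort, manifest


def simulate_atlas(spec):
    """Generate a labelled cell atlas with a planted signature enrichment.

    Per-cell expression is N(0,1); ``enrichment_shift`` is added to each
    signature gene in the enriched cell type. Returns ``(atlas, manifest)``.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = spec.resolved_gene_ids()
    labels = []
    for label, n_cells in spec.cell_types:
        labels.extend([label] * int(n_cells))
    n_cells_total = len(labels)
    cells = [f"cell{i:06d}" for i in range(n_cells_total)]
    expr = rng.standard_normal((n_cells_total, len(gene_ids)))
    expression = pd.DataFrame(expr, index=cells, columns=gene_ids)
    label_series = pd.Series(labels, index=cells, name="cell_type")
    enriched = label_series == spec.enriched_type
    for sig in spec.signature_genes:
        expression.loc[enriched, sig] += spec.enrichment_shift
    atlas = CellAtlas(expression=expression, cell_type=label_series)
    manifest = _manifest(spec, {"kind": "atlas"})
    return atlas, manifest


def simulate_gene_sets(universe, n_sets, sizes, n_true_enriched, seed,
                       true_pool=(), regulon_mode_neg_fraction=0.25):
    """Random gene sets and regulons over a gene universe.

    ``true_pool`` holds genes known to correlate with the cohort LP (e.g.
    the top of a landscape table); the first ``n_true_enriched`` sets draw
    their members preferentially (90%) from that pool, the rest are uniform.
    Regulons mirror the sets, with a fraction of repressive (-1) modes on
    null regulons and all +1 on true ones.

    Returns ``(GeneSetCollection, RegulonCollection, manifest)``.
    """
    universe = list(universe)
    sizes = list(sizes) if not np.isscalar(sizes) else [int(sizes)] * n_sets
    if len(sizes) == 1:
        sizes = sizes * n_sets
    if len(sizes) != n_sets:
        raise ValidationError("sizes must be scalar or length n_sets")
    if any(s < 5 for s in sizes):
        raise ValidationError("set sizes must be >= 5")
    if n_true_enriched > n_sets:
        raise ValidationError("n_true_enriched exceeds n_sets")
    if n_true_enriched > 0 and not true_pool:
        raise ValidationError("n_true_enriched > 0 requires a true_pool")
    rng = np.random.default_rng(seed)
    true_pool = [g for g in true_pool if g in set(universe)]
    sets, regulons, true_names = {}, {}, []
    for i in range(n_sets):
        size = sizes[i]
        is_true = i < n_true_enriched
        if is_true:
            n_from_pool = min(int(round(0.9 * size)), len(true_pool))
            members = list(rng.choice(true_pool, size=n_from_pool,
                                      replace=False))
            rest = [g for g in universe if g not in set(members)]
            members += list(rng.choice(rest, size=size - n_from_pool,
                                       replace=False))
            name = f"TRUE_SET_{i:03d}"
            true_names.append(name)
            modes = [1] * size
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            name = f"NULL_SET_{i:03d}"
            modes = [(-1 if rng.random() < regulon_mode_neg_fraction else 1)
                     for _ in range(size)]
        sets[name] = members
        regulons[name.replace("SET", "TF")] = list(zip(members, modes))
    manifest = {"kind": "gene_sets", "n_sets": n_sets,
                "n_true_enriched": n_true_enriched, "seed": seed,
                "true_sets": true_names}
    return (GeneSetCollection(sets, source="synthetic"),
            RegulonCollection(regulons, source="synthetic"), manifest)


# ---------------------------------------------------------------------------
# writers: the same plain-text formats the pipeline readers consume

def _write_manifest(manifest, out_dir):
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def write_panel(panel, manifest, out_dir):
    os.makedirs(out_dir, exist_ok=True)
    panel.auc.to_csv(os.path.join(out_dir, "auc.tsv"), sep="\t",
                     float_format="%.10g")
    panel.dependency.to_csv(os.path.join(out_dir, "dependency.tsv"), sep="\t",
                            float_format="%.10g")
    with open(os.path.join(out_dir, "annotations.tsv"), "w") as fh:
        for drug in panel.auc.index:
            fh.write(f"{drug}\t{panel.annotations[drug]}\n")
    _write_manifest(manifest, out_dir)


def write_cohort(cohort, manifest, out_dir):
    os.makedirs(out_dir, exist_ok=True)
    cohort.expression.to_csv(os.path.join(out_dir, "expression.tsv"),
                             sep="\t", float_format="%.10g")
    cohort.drug_auc.to_csv(os.path.join(out_dir, "drug_auc.tsv"), sep="\t",
                           float_format="%.10g")
    cohort.mutations.to_csv(os.path.join(out_dir, "mutations.tsv"), sep="\t",
                            float_format="%.10g")
    cohort.clinical.to_csv(os.path.join(out_dir, "clinical.tsv"), sep="\t",
                           float_format="%.10g")
    _write_manifest(manifest, out_dir)


def write_atlas(atlas, manifest, out_dir):
    os.makedirs(out_dir, exist_ok=True)
    atlas.expression.to_csv(os.path.join(out_dir, "atlas_expression.tsv"),
                            sep="\t", float_format="%.10g")
    atlas.cell_type.to_frame(name="cell_type").to_csv(
        os.path.join(out_dir, "atlas_labels.tsv"), sep="\t")
    _write_manifest(manifest, out_dir)


def write_gene_sets(collection, regulons, manifest, out_dir):
    os.makedirs(out_dir, exist_ok=True)
    write_gmt(collection, os.path.join(out_dir, "gene_sets.gmt"))
    write_regulons(regulons, os.path.join(out_dir, "regulons.tsv"))
    _write_manifest(manifest, out_dir)
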