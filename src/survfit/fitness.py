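"""Strain and gene fitness estimation from barcode counts.

A strain's fitness in a condition is the normalized log2 ratio of its barcode
counts between the post-challenge outgrowth sample and the pooled reference
samples; a gene's fitness is the weighted average of its strains' fitness
values.  Normalization subtracts the per-scaffold median gene fitness in each
sample, which removes both the depth offset between the pooled reference and
a single outgrowth sample and the compositional offset induced by sequencing
a renormalized survivor pool — under the assumption that the typical gene on
each replicon is fitness-neutral.

Quality control drops strains whose insertion lies outside the central
portion of the gene (likely not disruptive) or whose reference counts are too
low to estimate a ratio, and genes with too few supporting reference reads
overall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable, GeneFitnessTable, condition_label

__all__ = [
    "FitnessConfig",
    "QCReport",
    "strain_log_ratio",
    "strain_weight",
    "aggregate_reference",
    "gene_fitness",
    "normalize",
    "qc_filter",
    "fitness_pipeline",
]


@dataclass
class FitnessConfig:
    """Tunable parameters of the fitness pipeline.

    pseudocount
        Added to both counts of the log ratio; keeps zero-count strains
        finite while barely perturbing well-covered ones.
    min_reference_reads_per_strain / min_reference_reads_per_gene
        Read-support floors below which a strain / gene is excluded.
    central_window
        Insertion-position window (fraction of gene length) retained;
        insertions near gene ends often leave a functional protein.
    normalization_scope
        ``per-scaffold`` (default) or ``global`` median centering.
    """

    pseudocount: float = 0.1
    min_reference_reads_per_strain: int = 3
    min_reference_reads_per_gene: int = 30
    central_window: tuple[float, float] = (0.1, 0.9)
    normalization_scope: str = "per-scaffold"
    min_genes_per_scope: int = 5

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        lo, hi = self.central_window
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("central_window must satisfy 0 <= lo < hi <= 1")
        if self.normalization_scope not in ("per-scaffold", "global"):
            raise ValueError("normalization_scope must be 'per-scaffold' or 'global'")


@dataclass
class QCReport:
    """Which strains and genes survived quality control, and why not."""

    included_strains: pd.Index
    included_genes: pd.Index
    strain_exclusions: pd.DataFrame  # barcode, reason
    gene_exclusions: pd.DataFrame  # gene_id, reason

    def summary(self) -> dict:
        return {
            "n_strains_included": int(len(self.included_strains)),
            "n_strains_excluded": int(len(self.strain_exclusions)),
            "n_genes_included": int(len(self.included_genes)),
            "n_genes_excluded": int(len(self.gene_exclusions)),
            "strain_exclusion_reasons": self.strain_exclusions["reason"].value_counts().to_dict()
            if len(self.strain_exclusions)
            else {},
            "gene_exclusion_reasons": self.gene_exclusions["reason"].value_counts().to_dict()
            if len(self.gene_exclusions)
            else {},
        }


def strain_log_ratio(ref_count, out_count, pseudocount: float = 0.1):
    """Raw strain fitness: ``log2((out + psi) / (ref + psi))``.

    Accepts scalars or aligned arrays/Series.  Monotone increasing in the
    outgrowth count and decreasing in the reference count.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ref = np.asarray(ref_count, dtype=float)
    out = np.asarray(out_count, dtype=float)
    if (ref < 0).any() or (out < 0).any():
        raise ValueError("counts must be non-negative")
    result = np.log2(out + pseudocount) - np.log2(ref + pseudocount)
    if np.isscalar(ref_count) and np.isscalar(out_count):
        return float(result)
    return result


def strain_weight(ref_count, out_count):
    """Inverse-variance-style weight for a strain's log ratio.

    ``w = 1 / (1/(1 + ref) + 1/(1 + out))`` — the inverse of the approximate
    variance of a log ratio of two counts, so strains supported by few reads
    on either side contribute little to the gene average.
    """
    ref = np.asarray(ref_count, dtype=float)
    out = np.asarray(out_count, dtype=float)
    return 1.0 / (1.0 / (1.0 + ref) + 1.0 / (1.0 + out))


def aggregate_reference(table: CountTable) -> pd.Series:
    """Per-strain reference count: sum over all reference samples."""
    refs = table.reference_samples
    if not refs:
        raise ValueError("no reference samples in count table")
    return table.counts[refs].sum(axis=1)


def gene_fitness(strain_fitness, weights) -> float:
    """Weighted average of strain fitness values for one gene."""
    f = np.asarray(strain_fitness, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(f) == 0:
        raise ValueError("gene has no included strains")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("all weights are zero; gene should be QC-excluded")
    return float((w * f).sum() / total)


def qc_filter(table: CountTable, config: FitnessConfig | None = None) -> QCReport:
    """Apply strain- and gene-level quality control.

    Strains are excluded for a non-central insertion or too few reference
    reads; genes are excluded when their included strains' summed reference
    reads fall below the per-gene floor (which also drops genes with no
    included strains).
    """
    config = config or FitnessConfig()
    ref = aggregate_reference(table)
    lo, hi = config.central_window
    pos = table.strains["position_fraction"]

    noncentral = (pos < lo) | (pos > hi)
    low_ref = ref < config.min_reference_reads_per_strain

    excl = []
    for bc in table.strains.index[noncentral]:
        excl.append({"barcode": bc, "reason": "non_central_insertion"})
    for bc in table.strains.index[~noncentral & low_ref]:
        excl.append({"barcode": bc, "reason": "low_reference_count"})
    strain_excl = pd.DataFrame(excl, columns=["barcode", "reason"])
    included_strains = table.strains.index[~noncentral & ~low_ref]

    gene_ref = (
        ref.loc[included_strains]
        .groupby(table.strains.loc[included_strains, "gene_id"])
        .sum()
        .reindex(table.strains["gene_id"].unique(), fill_value=0)
    )
    low_gene = gene_ref < config.min_reference_reads_per_gene
    gene_excl = pd.DataFrame(
        [{"gene_id": g, "reason": "low_gene_reference_reads"} for g in gene_ref.index[low_gene]],
        columns=["gene_id", "reason"],
    )
    included_genes = gene_ref.index[~low_gene]
    return QCReport(
        included_strains=included_strains,
        included_genes=pd.Index(included_genes, name="gene_id"),
        strain_exclusions=strain_excl,
        gene_exclusions=gene_excl,
    )


def normalize(
    gene_values: pd.DataFrame,
    gene_scaffold: pd.Series,
    scope: str = "per-scaffold",
    min_genes: int = 5,
) -> pd.DataFrame:
    """Median-center gene fitness values within each normalization scope.

    For ``per-scaffold`` scope the median over genes on the same scaffold is
    subtracted, per sample; scaffolds carrying fewer than ``min_genes`` genes
    fall back to the global (per-sample) median with a warning.  The
    operation is idempotent and leaves every scope with median exactly 0.
    """
    if scope == "global":
        return gene_values - gene_values.median(axis=0)
    if scope != "per-scaffold":
        raise ValueError(f"unknown normalization scope {scope!r}")
    out = gene_values.copy()
    global_median = gene_values.median(axis=0)
    scaffolds = gene_scaffold.reindex(gene_values.index)
    for scaff, genes in gene_values.groupby(scaffolds).groups.items():
        if len(genes) < min_genes:
            warnings.warn(
                f"scaffold {scaff!r} has only {len(genes)} genes; "
                "falling back to global median normalization",
                stacklevel=2,
            )
            out.loc[genes] = gene_values.loc[genes] - global_median
        else:
            out.loc[genes] = gene_values.loc[genes] - gene_values.loc[genes].median(axis=0)
    return out


def fitness_pipeline(table: CountTable, config: FitnessConfig | None = None) -> GeneFitnessTable:
    """Run the full fitness calculation on a count table.

    Steps: pool reference counts, apply quality control, compute per-strain
    log ratios and weights per outgrowth sample, average into gene fitness,
    median-normalize per scaffold and sample, then average replicate vials
    within each condition.
    """
    config = config or FitnessConfig()
    out_samples = table.outgrowth_samples
    if not out_samples:
        raise ValueError("count table has no outgrowth samples")
    ref = aggregate_reference(table)
    qc = qc_filter(table, config)

    strains = table.strains.loc[qc.included_strains]
    keep = strains["gene_id"].isin(qc.included_genes)
    strains = strains[keep]
    if len(strains) == 0:
        warnings.warn("no strains passed quality control; returning empty table")
        empty = pd.DataFrame(index=pd.Index([], name="gene_id"))
        return GeneFitnessTable(empty, empty, empty, table.conditions())

    ref = ref.loc[strains.index]
    gene_ids = strains["gene_id"]
    per_sample = {}
    for sid in out_samples:
        out = table.counts.loc[strains.index, sid]
        f = strain_log_ratio(ref.to_numpy(), out.to_numpy(), config.pseudocount)
        w = strain_weight(ref.to_numpy(), out.to_numpy())
        df = pd.DataFrame({"gene_id": gene_ids.to_numpy(), "wf": w * f, "w": w})
        agg = df.groupby("gene_id").sum()
        per_sample[sid] = agg["wf"] / agg["w"]
    gene_values = pd.DataFrame(per_sample)
    gene_values.index.name = "gene_id"

    gene_scaffold = strains.groupby("gene_id")["scaffold"].agg(lambda s: s.mode().iat[0])
    normalized = normalize(
        gene_values, gene_scaffold, config.normalization_scope, config.min_genes_per_scope
    )

    cond = table.conditions()
    sample_meta = table.samples.loc[out_samples]
    fitness = {}
    for label, row in cond.iterrows():
        ids = sample_meta.index[
            (sample_meta["condition_axis"] == row["condition_axis"])
            & (sample_meta["condition_value"] == row["condition_value"])
        ]
        fitness[label] = normalized[list(ids)].mean(axis=1)
    fitness_df = pd.DataFrame(fitness)

    gene_info = pd.DataFrame(
        {
            "scaffold": gene_scaffold,
            "n_strains": strains.groupby("gene_id").size(),
            "reference_reads": ref.groupby(gene_ids).sum(),
        }
    )
    return GeneFitnessTable(
        fitness=fitness_df, per_sample=normalized, gene_info=gene_info, conditions=cond
    )
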