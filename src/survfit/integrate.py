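"""Join fitness screen hits with pangenome prevalence and genome location.

Each focal-strain gene has a genomic location (chromosome, a predicted
genomic island, or one of the plasmids) and, via its ortholog cluster, a
prevalence — the number of genomes in the pangenome containing an ortholog.
Prevalence is binned into singleton / cloud / low-shell / high-shell / core
classes, and hits are cross-tabulated by direction, location and class to
expose whether survival determinants sit in the conserved core or in the
mobile accessory genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pangenome import CLOUD_MAX_FRACTION

__all__ = [
    "PrevalenceThresholds",
    "PREVALENCE_CLASSES",
    "map_prevalence",
    "classify_prevalence",
    "crosstab",
]

#: Ordered from rarest to most conserved.
PREVALENCE_CLASSES = ["singleton", "cloud", "low_shell", "high_shell", "core"]


@dataclass
class PrevalenceThresholds:
    """Boundaries of the prevalence classes over [1, N] genomes.

    ``cloud_max_fraction``: a gene is cloud when prevalence/N is at or below
    this (and prevalence > 1).  ``low_shell_max_genomes``: upper bound
    (inclusive) of the low shell; defaults to genomes strictly below 80% of
    N — 59 of 75 genomes — generalizing the <60-of-75 boundary used for a
    75-genome pangenome.
    """

    cloud_max_fraction: float = CLOUD_MAX_FRACTION
    low_shell_max_genomes: int | None = None
    low_shell_fraction: float = 0.8

    def low_shell_max(self, n_genomes: int) -> int:
        if self.low_shell_max_genomes is not None:
            return self.low_shell_max_genomes
        return math.ceil(self.low_shell_fraction * n_genomes) - 1


def classify_prevalence(
    prevalence: int, n_genomes: int, thresholds: PrevalenceThresholds | None = None
) -> str:
    """Prevalence class of one gene.

    Singleton (prevalence 1) is checked before cloud, so the focal strain's
    unique genes are never labeled cloud; core requires presence in every
    genome.  Classes partition [1, N] and are monotone in prevalence.
    """
    thresholds = thresholds or PrevalenceThresholds()
    if not 1 <= prevalence <= n_genomes:
        raise ValueError(f"prevalence {prevalence} outside [1, {n_genomes}]")
    if prevalence == 1:
        return "singleton"
    if prevalence == n_genomes:
        return "core"
    if prevalence / n_genomes <= thresholds.cloud_max_fraction:
        return "cloud"
    if prevalence <= thresholds.low_shell_max(n_genomes):
        return "low_shell"
    return "high_shell"


def map_prevalence(context: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Attach ortholog prevalence to a gene-context table.

    ``context`` has one row per gene with columns ``gene_id``, ``location``
    and ``cluster_id`` (empty/NaN for genes with no ortholog cluster).
    Prevalence is the row sum of the gene's cluster in the presence/absence
    matrix.  Unclustered genes are their own singletons (prevalence 1);
    cluster ids absent from the matrix are flagged ``unmapped`` and treated
    the same way.
    """
    if context["gene_id"].duplicated().any():
        dups = context.loc[context["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in context table: {dups[:5]}")
    prev_by_cluster = matrix.sum(axis=1)
    out = context.copy()
    cluster = out["cluster_id"].astype("object")
    has_cluster = cluster.notna() & (cluster != "")
    mapped = has_cluster & cluster.isin(prev_by_cluster.index)
    out["unmapped"] = has_cluster & ~mapped
    out["prevalence"] = 1
    out.loc[mapped, "prevalence"] = (
        prev_by_cluster.reindex(cluster[mapped]).to_numpy().astype(int)
    )
    return out


def crosstab(
    hits: pd.DataFrame,
    context: pd.DataFrame,
    matrix: pd.DataFrame,
    fitness: pd.Series | None = None,
    thresholds: PrevalenceThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate screen hits by direction, genome location and
    prevalence class.

    Parameters
    ----------
    hits
        Screen result indexed by gene id with ``hit`` and ``direction``
        columns (from :mod:`survfit.screen`).
    context
        Gene-context table (``gene_id``, ``location``, ``cluster_id``).
    matrix
        Presence/absence matrix defining prevalence and N.
    fitness
        Optional per-gene fitness to carry into the joined table (the
        prevalence-vs-fitness scatter input).

    Returns
    -------
    joined, counts
        ``joined``: one row per input gene with prevalence, class, location,
        hit status (genes missing context get location/class ``unknown``,
        never dropped).  ``counts``: hit counts by
        direction x location x prevalence class; margins equal the input hit
        counts exactly.
    """
    thresholds = thresholds or PrevalenceThresholds()
    n_genomes = matrix.shape[1]
    ctx = map_prevalence(context, matrix).set_index("gene_id")

    joined = hits.copy()
    joined["location"] = ctx["location"].reindex(joined.index).fillna("unknown")
    joined["prevalence"] = ctx["prevalence"].reindex(joined.index)
    joined["missing_context"] = ~joined.index.isin(ctx.index)
    joined["prevalence_class"] = [
        classify_prevalence(int(p), n_genomes, thresholds) if pd.notna(p) else "unknown"
        for p in joined["prevalence"]
    ]
    if fitness is not None:
        joined["fitness"] = fitness.reindex(joined.index)

    hit_rows = joined[joined["hit"]]
    counts = (
        hit_rows.groupby(["direction", "location", "prevalence_class"], observed=False)
        .size()
        .rename("n_genes")
        .reset_index()
    )
    return joined, counts
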