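"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CountTable", "GeneFitnessTable", "condition_label"]

STRAIN_COLUMNS = ["gene_id", "scaffold", "position_fraction"]
SAMPLE_COLUMNS = ["role", "condition_axis", "condition_value", "replicate"]


def condition_label(axis: str, value: float) -> str:
    """Canonical label for a challenge condition, e.g. ``time_h:0.5``."""
    return f"{axis}:{value:g}"


@dataclass
class CountTable:
    """Barcode counts with strain annotation and per-sample metadata.

    Attributes
    ----------
    strains
        One row per insertion strain, indexed by barcode; columns
        ``gene_id``, ``scaffold``, ``position_fraction``.
    counts
        Integer read counts, rows aligned to ``strains``, one column per
        sample.
    samples
        Sample metadata indexed by sample id; columns ``role``
        (``reference`` | ``outgrowth``), ``condition_axis``,
        ``condition_value``, ``replicate``.
    """

    strains: pd.DataFrame
    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = set(STRAIN_COLUMNS) - set(self.strains.columns)
        if missing:
            raise ValueError(f"strain table missing columns: {sorted(missing)}")
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
        if not self.counts.index.equals(self.strains.index):
            raise ValueError("counts rows are not aligned to the strain table")
        if set(self.counts.columns) != set(self.samples.index):
            raise ValueError("count columns and sample metadata ids disagree")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.rint(vals)):
                raise ValueError("counts must be integers")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.samples["role"] == "reference").any():
            raise ValueError("at least one reference sample is required")
        bad = set(self.samples["role"]) - {"reference", "outgrowth"}
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")

    @property
    def reference_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "reference"])

    @property
    def outgrowth_samples(self) -> list[str]:
        return list(self.samples.index[self.samples["role"] == "outgrowth"])

    def conditions(self) -> pd.DataFrame:
        """Distinct outgrowth conditions: one row per (axis, value)."""
        out = self.samples[self.samples["role"] == "outgrowth"]
        cond = (
            out.groupby(["condition_axis", "condition_value"], sort=True)
            .size()
            .rename("n_replicates")
            .reset_index()
        )
        cond["label"] = [
            condition_label(a, v)
            for a, v in zip(cond["condition_axis"], cond["condition_value"])
        ]
        return cond.set_index("label")


@dataclass
class GeneFitnessTable:
    """Per-gene fitness values (log2 units) per condition.

    ``fitness`` has gene ids as rows and condition labels (``axis:value``)
    as columns, replicate vials already averaged.  ``per_sample`` keeps the
    normalized per-sample values the averages came from.  ``gene_info``
    records the scaffold, number of strains used and total reference reads
    supporting each gene.
    """

    fitness: pd.DataFrame
    per_sample: pd.DataFrame
    gene_info: pd.DataFrame
    conditions: pd.DataFrame

    def series(self, axis: str) -> "GradientSeries":
        from .screen import GradientSeries  # local import to avoid a cycle

        cond = self.conditions[self.conditions["condition_axis"] == axis]
        if len(cond) == 0:
            raise KeyError(f"no conditions on axis {axis!r}")
        cond = cond.sort_values("condition_value")
        return GradientSeries(
            axis=axis,
            values=cond["condition_value"].to_list(),
            fitness=self.fitness[cond.index.to_list()],
        )
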