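"""Tab-separated file formats for every pipeline artifact.

All files are UTF-8 TSV with a header row.  Counts are written as one wide
table (strain annotation columns followed by one column per sample) plus a
sample-metadata table; presence/absence matrices have cluster ids as rows
and genome ids as columns.  Floats are written with a fixed format so reruns
with the same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import CountTable, GeneFitnessTable

FLOAT_FMT = "%.10g"


def write_count_table(table: CountTable, counts_path, samples_path) -> None:
    wide = pd.concat([table.strains, table.counts], axis=1)
    wide.index.name = "barcode"
    wide.to_csv(counts_path, sep="\t", float_format=FLOAT_FMT)
    table.samples.to_csv(samples_path, sep="\t", float_format=FLOAT_FMT)


def read_count_table(counts_path, samples_path) -> CountTable:
    wide = pd.read_csv(counts_path, sep="\t", index_col="barcode")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    strain_cols = ["gene_id", "scaffold", "position_fraction"]
    sample_cols = [c for c in wide.columns if c not in strain_cols]
    samples["condition_axis"] = samples["condition_axis"].fillna("")
    return CountTable(
        strains=wide[strain_cols],
        counts=wide[sample_cols].astype(int),
        samples=samples,
    )


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gene_fitness(result: GeneFitnessTable, path, conditions_path=None) -> None:
    out = result.fitness.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if conditions_path is not None:
        result.conditions.to_csv(conditions_path, sep="\t", float_format=FLOAT_FMT)


def read_gene_fitness(path, conditions_path=None) -> GeneFitnessTable:
    fitness = pd.read_csv(path, sep="\t", index_col="gene_id")
    if conditions_path is not None:
        conditions = pd.read_csv(conditions_path, sep="\t", index_col="label")
    else:
        # reconstruct condition metadata from the axis:value column labels
        rows = []
        for label in fitness.columns:
            axis, _, value = label.rpartition(":")
            rows.append({"label": label, "condition_axis": axis,
                         "condition_value": float(value), "n_replicates": -1})
        conditions = pd.DataFrame(rows).set_index("label")
    return GeneFitnessTable(
        fitness=fitness, per_sample=pd.DataFrame(index=fitness.index),
        gene_info=pd.DataFrame(index=fitness.index), conditions=conditions,
    )


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
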