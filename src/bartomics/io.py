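"""Tab-separated on-disk formats for cohorts and count matrices.

Cohort tables are TSV with one sample per row: the first column holds the
sample id, the last column (named ``outcome``) the 0/1 label, and every column
in between one feature, with the header spelled ``name|layer`` (e.g.
``OTU7|microbiome``, ``M3|metabolome``, ``age|covariate``).  A feature header
without a ``|layer`` tag is accepted with a warning and treated as a
metabolite.  Gene count matrices are plain genes x samples TSV with gene ids
in the first column.

Reads validate eagerly: a non-numeric cell fails with an error naming the
sample row and column, and the FeatureTable invariants (binary outcome,
non-negative microbial counts, positive metabolite intensities) are enforced
on load.  write/read round-trips preserve ids, layers, values and outcomes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import METABOLOME, LAYERS, FeatureTable

logger = logging.getLogger("bartomics")

OUTCOME_COLUMN = "outcome"


def write_table(table: FeatureTable, path) -> None:
    """Write a FeatureTable as TSV with ``name|layer`` feature headers."""
    cols = [f"{f}|{l}" for f, l in zip(table.feature_ids, table.layers)]
    df = pd.DataFrame(table.values, index=pd.Index(table.sample_ids,
                                                   name="sample"),
                      columns=cols)
    df[OUTCOME_COLUMN] = table.outcome
    df.to_csv(path, sep="\t")


def read_table(path) -> FeatureTable:
    """Read a cohort TSV back into a validated FeatureTable."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least one feature column and "
                         f"a final '{OUTCOME_COLUMN}' column")
    if df.columns[-1] != OUTCOME_COLUMN:
        raise ValueError(f"{path}: last column must be '{OUTCOME_COLUMN}', "
                         f"got {df.columns[-1]!r}")
    sample_ids = [str(s) for s in df.index]
    feature_ids, layers = [], []
    for col in df.columns[:-1]:
        if "|" in col:
            name, _, layer = col.rpartition("|")
            if layer not in LAYERS:
                raise ValueError(f"{path}: unknown layer tag {layer!r} "
                                 f"in column {col!r}")
        else:
            name, layer = col, METABOLOME
            logger.warning("%s: column %r has no layer tag; assuming %s",
                           path, col, METABOLOME)
        feature_ids.append(name)
        layers.append(layer)

    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(raw[:, j]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at sample "
                    f"{sample_ids[i]!r}, column {col!r}") from None

    outcome = values[:, -1]
    if not np.array_equal(outcome, outcome.astype(int)):
        raise ValueError(f"{path}: outcome column must hold integers 0/1")
    return FeatureTable(sample_ids=sample_ids, feature_ids=feature_ids,
                        layers=np.asarray(layers, dtype=object),
                        values=values[:, :-1],
                        outcome=outcome.astype(int))


def write_counts(counts: pd.DataFrame, labels: np.ndarray, path,
                 labels_path=None) -> None:
    """Write a genes x samples count matrix (and, optionally, sample labels).

    The label file is two-column TSV (sample, label in {0, 1}); it defaults to
    ``<path stem>.labels.tsv`` next to the counts file.
    """
    path = Path(path)
    counts.to_csv(path, sep="\t", index_label="gene")
    if labels_path is None:
        labels_path = path.with_suffix("").with_suffix(".labels.tsv")
    pd.DataFrame({"sample": counts.columns,
                  "label": np.asarray(labels, dtype=int)}) \
        .to_csv(labels_path, sep="\t", index=False)


def read_counts(path, labels_path=None):
    """Read a genes x samples count matrix (+ labels when a label file exists).

    Returns (DataFrame, labels-or-None); labels align with the matrix's sample
    columns by name.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    sample_ids = [str(c) for c in df.columns]
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(sample_ids):
        for i, cell in enumerate(raw[:, j]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at gene "
                    f"{df.index[i]!r}, column {col!r}") from None
    if (values < 0).any():
        raise ValueError(f"{path}: counts must be non-negative")
    counts = pd.DataFrame(values, index=[str(g) for g in df.index],
                          columns=sample_ids)

    if labels_path is None:
        cand = path.with_suffix("").with_suffix(".labels.tsv")
        labels_path = cand if cand.exists() else None
    if labels_path is None:
        return counts, None
    lab = pd.read_csv(labels_path, sep="\t", dtype={"sample": str})
    lab = lab.set_index("sample")["label"]
    missing = [s for s in sample_ids if s not in lab.index]
    if missing:
        raise ValueError(f"{labels_path}: no label for sample {missing[0]!r}")
    labels = lab.loc[sample_ids].to_numpy(dtype=int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError(f"{labels_path}: labels must be 0/1")
    return counts, labels
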