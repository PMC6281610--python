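"""Plain-text I/O for the pipeline's tabular formats.

All formats are TSV with headers: expression (rows = genes, first column
``gene``), sample labels (``sample``, ``group``), clinical follow-up
(``sample``, ``time``, ``event``), signatures (``gene``, ``score``, ``p``),
ortholog maps (``source_gene``, ``target_gene``), and standard GMT gene-set
collections.  Readers validate the invariants the downstream stages rely on.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .signatures import GeneSignature, OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression", "write_expression",
    "read_labels", "write_labels",
    "read_clinical", "write_clinical",
    "read_signature", "write_signature",
    "read_ortholog_map", "write_ortholog_map",
    "read_gmt",
]


class GMTParseError(ValueError):
    pass


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate gene ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    if df.shape[0] < 2:
        raise ValueError(f"{path}: need at least 2 genes")
    if not np.isfinite(df.to_numpy(float)).all():
        raise ValueError(f"{path}: non-finite expression values")
    return df


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample", "group"]:
        raise ValueError(f"{path}: expected columns sample, group")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df.set_index("sample")["group"]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("group").rename_axis("sample").to_csv(path, sep="\t")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["sample", "time", "event"]:
        raise ValueError(f"{path}: expected columns sample, time, event")
    df = df.set_index("sample")
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids")
    if (df["time"] <= 0).any():
        raise ValueError(f"{path}: follow-up times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event flags must be 0 or 1")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical[["time", "event"]].rename_axis("sample").to_csv(path, sep="\t")


def read_signature(path) -> GeneSignature:
    df = pd.read_csv(path, sep="\t")
    pv = df["p"] if "p" in df.columns else None
    return GeneSignature.from_scores(df["gene"], df["score"], pvalues=pv)


def write_signature(sig: GeneSignature, path) -> None:
    sig.to_frame().to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["source_gene", "target_gene"]:
        raise ValueError(f"{path}: expected columns source_gene, target_gene")
    return OrthologMap.from_pairs(df.itertuples(index=False))


def write_ortholog_map(omap: OrthologMap, path) -> None:
    df = pd.DataFrame(omap.pairs(), columns=["source_gene", "target_gene"])
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict:
    """Read a GMT gene-set collection: name, description, genes...

    Duplicate set names and record lines without any gene are parse errors;
    set names map to frozensets of gene ids.
    """
    sets: dict[str, frozenset] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}, line {lineno}: need name, description and >= 1 gene"
                )
            name = fields[0]
            if name in sets:
                raise GMTParseError(f"{path}, line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise GMTParseError(f"{path}, line {lineno}: empty gene set {name!r}")
            sets[name] = genes
    if not sets:
        raise GMTParseError(f"{path}: no gene sets found")
    return sets
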