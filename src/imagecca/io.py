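"""Readers and writers for the tabular interchange formats.

Expression and genotype matrices travel as TSV with the feature id in the
first column and sample ids as the header row; gene sets as GMT; fitted
decompositions as a directory of TSVs plus a JSON config.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .sparse_cca import CCAConfig, CCADecomposition

__all__ = [
    "read_matrix_tsv",
    "read_covariates_tsv",
    "read_eqtl_tsv",
    "read_gmt",
    "save_decomposition",
    "load_decomposition",
]


def read_matrix_tsv(path) -> pd.DataFrame:
    """Features x samples TSV (first column = feature id, header = samples)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_eqtl_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "gene_id", "tissue"}
    if not required <= set(df.columns):
        raise ValueError(f"eQTL table must have columns {sorted(required)}")
    return df


def read_gmt(path) -> dict:
    """GMT gene sets: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def save_decomposition(decomp: CCADecomposition, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_index = decomp.gene_ids or [f"g{i}" for i in range(decomp.U.shape[0])]
    comp_cols = [f"component_{k + 1}" for k in range(decomp.n_components)]
    pd.DataFrame(decomp.U, index=gene_index, columns=comp_cols) \
        .to_csv(out / "gene_weights.tsv", sep="\t", index_label="gene_id")
    pd.DataFrame(decomp.V, columns=comp_cols) \
        .to_csv(out / "feature_weights.tsv", sep="\t", index_label="feature_index")
    sample_index = decomp.sample_ids or [f"s{i}" for i in range(len(decomp.gene_scores))]
    pd.DataFrame(decomp.gene_scores, index=sample_index, columns=comp_cols) \
        .to_csv(out / "gene_scores.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame(decomp.image_scores, index=sample_index, columns=comp_cols) \
        .to_csv(out / "image_scores.tsv", sep="\t", index_label="sample_id")
    pd.DataFrame({"component": comp_cols, "d": decomp.d, "pve": decomp.pve}) \
        .to_csv(out / "singular_values.tsv", sep="\t", index=False)
    (out / "config.json").write_text(json.dumps(decomp.config.__dict__, indent=1))


def load_decomposition(in_dir) -> CCADecomposition:
    src = Path(in_dir)
    U = pd.read_csv(src / "gene_weights.tsv", sep="\t", index_col=0)
    V = pd.read_csv(src / "feature_weights.tsv", sep="\t", index_col=0)
    gs = pd.read_csv(src / "gene_scores.tsv", sep="\t", index_col=0)
    zs = pd.read_csv(src / "image_scores.tsv", sep="\t", index_col=0)
    dv = pd.read_csv(src / "singular_values.tsv", sep="\t")
    config = CCAConfig(**json.loads((src / "config.json").read_text()))
    return CCADecomposition(
        U=U.to_numpy(), V=V.to_numpy(), d=dv["d"].to_numpy(),
        gene_scores=gs.to_numpy(), image_scores=zs.to_numpy(),
        pve=dv["pve"].to_numpy(), config=config,
        gene_ids=list(U.index), sample_ids=list(gs.index),
    )
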