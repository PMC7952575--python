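"""End-to-end orchestration: bundle -> tiles -> codes -> CCA -> imQTLs.

This wires the individual stages together for the common case of a fixture
bundle (or any directory with the same layout).  Every stage is also
usable on its own; the pipeline only handles plumbing and bookkeeping.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import io as icio
from .cae import CAE, CAEConfig, build_cae, encode, train_cae
from .features import (EmbeddingMatrix, ExpressionMatrix, average_embeddings,
                       pca_whiten, preprocess_expression)
from .imqtl import (GenotypeTable, association_scan, build_test_set,
                    quantile_normalize_features)
from .interpretation import rank_extreme_samples
from .sparse_cca import CCAConfig, CCADecomposition, fit_sparse_cca
from .tiling import sample_windows, select_tiles

__all__ = ["PipelineResult", "load_bundle", "run_pipeline"]


@dataclass
class PipelineResult:
    embedding: EmbeddingMatrix           # whitened image features
    expression: ExpressionMatrix
    decomposition: CCADecomposition
    associations: pd.DataFrame
    test_pairs: pd.DataFrame
    extremes: tuple                      # (low ids, high ids) of component 1
    cae_history: list
    tiles_per_sample: dict


def load_bundle(bundle_dir):
    """Read a fixture-bundle directory back into memory."""
    root = Path(bundle_dir)
    expression = icio.read_matrix_tsv(root / "expression.tsv")
    covariates = icio.read_covariates_tsv(root / "covariates.tsv")
    eqtl = icio.read_eqtl_tsv(root / "eqtl.tsv")
    genotypes = GenotypeTable.from_tsv(root / "genotypes.tsv")
    images = {}
    for sid in expression.columns:
        p = root / "images" / f"{sid}.png"
        if p.exists():
            images[sid] = np.asarray(Image.open(p))
    return images, expression, genotypes, covariates, eqtl


def run_pipeline(bundle_dir, tile_size: int = 128, threshold: float = 180.0,
                 m_windows: int = 100, window: int = 128,
                 cae_config: CAEConfig | None = None,
                 cca_config: CCAConfig | None = None,
                 train_windows_per_sample: int = 2,
                 min_samples: int = 20, fdr_threshold: float = 0.1,
                 seed: int = 0) -> PipelineResult:
    """Run the full analysis on a bundle directory.

    Defaults are sized for the synthetic fixtures (small slides, compact
    autoencoder); on real slides one would raise ``tile_size`` to 1000 and
    train a larger autoencoder for longer.  The 100 windows per sample
    matter: the bag-of-features average sharpens as 1/sqrt(m), and the
    association scan depends on that precision.
    """
    images, expr_raw, genotypes, covariates, eqtl = load_bundle(bundle_dir)
    sample_ids = [s for s in expr_raw.columns if s in images]
    rng = np.random.default_rng(seed)

    # 1. tile selection and window sampling per sample
    batches, tiles_per_sample = {}, {}
    for sid in sample_ids:
        tiles = select_tiles(images[sid], tile_size=tile_size,
                             threshold=threshold, slide_id=sid)
        tiles_per_sample[sid] = len(tiles)
        batches[sid] = sample_windows(images[sid], tiles, m=m_windows,
                                      window=window, augment=True,
                                      seed=int(rng.integers(2 ** 31 - 1)))

    # 2. train the autoencoder on a window subsample pooled across samples
    cae_config = cae_config or CAEConfig(base_filters=4, code_dim=1024,
                                         epochs=3, batch_size=32,
                                         input_size=window, seed=seed)
    train_stack = np.concatenate([
        b.windows[:train_windows_per_sample] for b in batches.values()])
    model, history = train_cae(train_stack, cae_config)

    # 3. bag-of-features averaging and PCA whitening
    rows = [average_embeddings(encode(batches[sid], model)) for sid in sample_ids]
    embedding = pca_whiten(EmbeddingMatrix(sample_ids=sample_ids,
                                           values=np.stack(rows)))

    # 4. expression preprocessing, aligned to the imaged samples
    expression = preprocess_expression(expr_raw, sample_ids=sample_ids)

    # 5. sparse CCA
    cca_config = cca_config or CCAConfig(K=10, lambda_images=0.15,
                                         lambda_genes=0.10, seed=seed)
    decomp = fit_sparse_cca(expression, embedding, cca_config)

    # 6. interpretation: extreme samples of component 1 (image side)
    extremes = rank_extreme_samples(decomp.image_scores[:, 0], sample_ids)

    # 7. imQTL scan over cis-eQTL-restricted pairs
    tissue_labels = covariates.loc[sample_ids, "tissue"]
    normalized = quantile_normalize_features(embedding.values)
    pairs = build_test_set(decomp, eqtl, expr_raw, tissue_labels,
                           min_samples=min_samples,
                           top_components=cca_config.K)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        associations = association_scan(
            genotypes, normalized, pairs, tissue_labels,
            sample_ids=sample_ids, min_samples=min_samples,
            fdr_threshold=fdr_threshold)

    return PipelineResult(
        embedding=embedding, expression=expression, decomposition=decomp,
        associations=associations, test_pairs=pairs, extremes=extremes,
        cae_history=history, tiles_per_sample=tiles_per_sample)
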