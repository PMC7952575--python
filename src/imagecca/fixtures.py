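"""Synthetic paired histology / expression / genotype data.

The generator plants a small number of shared latent factors: each factor
loads on a disjoint block of genes (in log-expression space), drives one
morphological parameter of the rendered tissue images (nucleus density,
nucleus radius or background tint), and can be shifted by a designated SNP
at a fixed per-allele effect.  Images emulate stained tissue as dark
elliptical nuclei scattered on a pale background — enough structure for an
autoencoder to learn, with no pretence of realistic histology texture.

All randomness flows through independent child streams of one seed, so the
expression noise, genotype draws and image rendering never share a stream.
"""
from __future__ import annotations

import json
import shutil
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse

__all__ = [
    "FixtureTruth",
    "PairedDataset",
    "generate_tissue_image",
    "planted_cca_matrices",
    "generate_paired_dataset",
    "write_fixture_bundle",
]

NUCLEUS_RGB = np.array([64, 36, 110], dtype=float)   # dark purple stain
DEFAULT_HUE = (195, 155, 185)                        # pale eosin background


@dataclass
class FixtureTruth:
    """Ground truth of a planted dataset, for recovery tests."""

    latent_factors: np.ndarray            # (n, K_true)
    gene_support: list                    # per factor: list of gene indices
    feature_drivers: dict                 # per factor: rendering parameter info
    snp_effects: list                     # (snp_index, factor_index, beta_per_allele)
    seed: int
    gene_ids: list = field(default_factory=list)
    snp_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "latent_factors": self.latent_factors.tolist(),
            "gene_support": [list(map(int, s)) for s in self.gene_support],
            "feature_drivers": self.feature_drivers,
            "snp_effects": [[int(s), int(f), float(b)] for s, f, b in self.snp_effects],
            "seed": self.seed,
            "gene_ids": self.gene_ids,
            "snp_ids": self.snp_ids,
            "sample_ids": self.sample_ids,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        d = json.loads(text)
        return cls(
            latent_factors=np.array(d["latent_factors"]),
            gene_support=d["gene_support"],
            feature_drivers=d["feature_drivers"],
            snp_effects=[tuple(e) for e in d["snp_effects"]],
            seed=d["seed"],
            gene_ids=d.get("gene_ids", []),
            snp_ids=d.get("snp_ids", []),
            sample_ids=d.get("sample_ids", []),
        )


@dataclass
class PairedDataset:
    """In-memory bundle of images and matched molecular data."""

    images: list                       # n uint8 (H, W, 3) arrays
    expression: pd.DataFrame           # genes x samples, raw TPM-like
    genotypes: pd.DataFrame            # snps x samples, dosages 0/1/2
    covariates: pd.DataFrame           # samples x covariates (incl. tissue)
    eqtl_table: pd.DataFrame           # snp_id, gene_id, tissue
    truth: FixtureTruth

    @property
    def sample_ids(self) -> list:
        return list(self.expression.columns)


def generate_tissue_image(density: float, radius_px: float = 3.0,
                          hue=DEFAULT_HUE, size=(512, 512),
                          seed: int = 0) -> np.ndarray:
    """Render a stained-tissue-like image.

    ``density`` is the expected nucleus count per 10^4 px^2; nuclei are
    filled ellipses with Gaussian-jittered radii in a dark nuclear stain
    colour, drawn on the uniform background ``hue`` and lightly smoothed
    for anti-aliasing.  Deterministic under ``seed``.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    h, w = size
    if h < 128 or w < 128:
        raise ValueError(f"image size {size} smaller than the 128px window")
    rng = np.random.default_rng(seed)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = np.asarray(hue, dtype=float)
    count = rng.poisson(density * h * w / 1e4)
    if count:
        rows = rng.uniform(0, h, size=count)
        cols = rng.uniform(0, w, size=count)
        rad_a = radius_px * np.exp(rng.normal(0, 0.15, size=count))
        rad_b = radius_px * np.exp(rng.normal(0, 0.15, size=count))
        angles = rng.uniform(0, np.pi, size=count)
        shade = rng.normal(0, 8, size=count)
        for i in range(count):
            rr, cc = ellipse(rows[i], cols[i], rad_a[i], rad_b[i],
                             shape=(h, w), rotation=angles[i])
            img[rr, cc] = np.clip(NUCLEUS_RGB + shade[i], 0, 255)
    for ch in range(3):  # mild blur: anti-aliased nucleus edges
        img[:, :, ch] = ndimage.gaussian_filter(img[:, :, ch], sigma=0.6)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _loading(signal: float, support_size: int) -> float:
    """Per-variable loading so the view's best linear combination correlates
    with the latent factor at sqrt(signal); two such views then share a
    canonical correlation of ``signal``."""
    return float(np.sqrt(signal / ((1.0 - signal) * support_size)))


def planted_cca_matrices(n: int, p_genes: int, q_features: int,
                         genes_per_factor: int = 10,
                         features_per_factor: int = 5,
                         K_true: int = 1, signal: float = 0.8,
                         seed: int = 0):
    """Two paired matrices with a planted sparse canonical structure.

    Returns ``(X, Z, truth)`` where X is (n, p_genes), Z is (n, q_features),
    and ``truth`` holds the factor values and the disjoint gene / feature
    support index lists per factor.  Unsupported columns are pure noise.
    """
    if not 0 < signal < 1:
        raise ValueError("signal must lie strictly in (0, 1)")
    if K_true * genes_per_factor > p_genes or K_true * features_per_factor > q_features:
        raise ValueError("supports exceed matrix dimensions")
    rng = np.random.default_rng(seed)
    F = rng.standard_normal((n, K_true))
    X = rng.standard_normal((n, p_genes))
    Z = rng.standard_normal((n, q_features))
    a = _loading(signal, genes_per_factor)
    b = _loading(signal, features_per_factor)
    gene_support, feature_support = [], []
    for k in range(K_true):
        gs = np.arange(k * genes_per_factor, (k + 1) * genes_per_factor)
        fs = np.arange(k * features_per_factor, (k + 1) * features_per_factor)
        X[:, gs] += a * F[:, [k]]
        Z[:, fs] += b * F[:, [k]]
        gene_support.append(gs)
        feature_support.append(fs)
    truth = {"factors": F, "gene_support": gene_support,
             "feature_support": feature_support,
             "gene_loading": a, "feature_loading": b}
    return X, Z, truth


def generate_paired_dataset(n: int = 100, p_genes: int = 500,
                            q_features_true: int = 5, K_true: int = 1,
                            signal: float = 0.8, maf: float = 0.3,
                            seed: int = 0, n_tissues: int = 3,
                            genes_per_factor: int = 10,
                            image_size=(512, 512), n_null_snps: int = 5,
                            snp_beta: float = 0.8,
                            density_base: float = 60.0,
                            density_log_slope: float = 0.25,
                            radius_px: float = 3.0) -> PairedDataset:
    """Generate a full paired fixture: images, expression, genotypes.

    Each of ``K_true`` factors loads on ``genes_per_factor`` genes (log2
    scale, unit noise) at a strength set by the target canonical
    correlation ``signal``; factor 1 drives nucleus density multiplicatively
    (strictly increasing), factor 2 nucleus radius, factor 3 background
    tint.  One SNP per factor shifts it by ``snp_beta`` per alternate
    allele; ``n_null_snps`` SNPs have no effect.  Tissue labels add small
    per-gene shifts so per-tissue logic is exercised.
    """
    if n < 20:
        raise ValueError("need n >= 20 samples")
    if K_true < 1:
        raise ValueError("K_true must be >= 1")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if not 0 < signal < 1:
        raise ValueError("signal must lie strictly in (0, 1)")
    ss = np.random.SeedSequence(seed)
    rng_geno, rng_expr, rng_img, rng_cov = [np.random.default_rng(s)
                                            for s in ss.spawn(4)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{j:04d}" for j in range(p_genes)]
    n_snps = K_true + n_null_snps
    snp_ids = [f"snp{s:03d}" for s in range(n_snps)]
    tissues = [f"tissue{t}" for t in range(n_tissues)]
    tissue_labels = [tissues[i % n_tissues] for i in range(n)]

    dosages = rng_geno.binomial(2, maf, size=(n, n_snps)).astype(float)
    F = rng_expr.standard_normal((n, K_true))
    snp_effects = []
    for k in range(K_true):
        F[:, k] += snp_beta * dosages[:, k]
        snp_effects.append((k, k, snp_beta))

    # expression in log2 space: baseline + factor loading + tissue shift + noise
    a = _loading(signal, genes_per_factor)
    base = rng_expr.uniform(2, 8, size=p_genes)
    tissue_shift = rng_expr.normal(0, 0.3, size=(p_genes, n_tissues))
    t_idx = np.array([tissues.index(t) for t in tissue_labels])
    log_expr = base[:, None] + tissue_shift[:, t_idx] + \
        rng_expr.standard_normal((p_genes, n))
    gene_support = []
    for k in range(K_true):
        gs = np.arange(k * genes_per_factor, (k + 1) * genes_per_factor)
        log_expr[gs, :] += a * F[:, k][None, :]
        gene_support.append(gs)
    expression = pd.DataFrame(2.0 ** log_expr, index=gene_ids, columns=sample_ids)

    # images: morphology parameters monotone in the factors
    densities = density_base * np.exp(density_log_slope * F[:, 0])
    radii = radius_px * (np.exp(0.12 * F[:, 1]) if K_true > 1 else np.ones(n))
    hue = np.asarray(DEFAULT_HUE, dtype=float)
    hues = np.tile(hue, (n, 1))
    if K_true > 2:
        hues = np.clip(hue[None, :] * (1.0 + 0.03 * np.tanh(F[:, [2]])), 0, 240)
    img_seeds = rng_img.integers(0, 2 ** 31 - 1, size=n)
    images = [generate_tissue_image(densities[i], radii[i], tuple(hues[i]),
                                    size=image_size, seed=int(img_seeds[i]))
              for i in range(n)]

    covariates = pd.DataFrame({
        "tissue": tissue_labels,
        "age": rng_cov.integers(25, 71, size=n),
        "ischemic_time": np.round(0.3 * F[:, 0] + rng_cov.standard_normal(n), 4),
    }, index=sample_ids)

    eqtl_rows = []
    for s_idx, k, _beta in snp_effects:
        for g in gene_support[k]:
            for t in tissues:
                eqtl_rows.append((snp_ids[s_idx], gene_ids[g], t))
    decoy_genes = rng_geno.choice(
        np.arange(K_true * genes_per_factor, p_genes), size=n_null_snps, replace=False)
    for j in range(n_null_snps):
        eqtl_rows.append((snp_ids[K_true + j], gene_ids[decoy_genes[j]], tissues[0]))
    eqtl_table = pd.DataFrame(eqtl_rows, columns=["snp_id", "gene_id", "tissue"])

    truth = FixtureTruth(
        latent_factors=F,
        gene_support=[list(map(int, g)) for g in gene_support],
        feature_drivers={
            "0": {"parameter": "nucleus_density", "base": density_base,
                  "log_slope": density_log_slope},
            **({"1": {"parameter": "nucleus_radius", "base": radius_px,
                      "log_slope": 0.12}} if K_true > 1 else {}),
            **({"2": {"parameter": "background_tint", "scale": 0.03}}
               if K_true > 2 else {}),
        },
        snp_effects=snp_effects, seed=seed,
        gene_ids=gene_ids, snp_ids=snp_ids, sample_ids=sample_ids,
    )
    genotypes = pd.DataFrame(dosages.T, index=snp_ids, columns=sample_ids)
    return PairedDataset(images=images, expression=expression,
                         genotypes=genotypes, covariates=covariates,
                         eqtl_table=eqtl_table, truth=truth)


def _write_vcf(genotypes: pd.DataFrame, path: Path) -> None:
    """Minimal VCF v4.2 with GT genotypes; one synthetic locus per SNP."""
    samples = list(genotypes.columns)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i, (snp, row) in enumerate(genotypes.iterrows()):
            gts = "\t".join(gt_map[int(v)] if v == v else "./." for v in row)
            fh.write(f"1\t{10_000 * (i + 1)}\t{snp}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_fixture_bundle(dataset: PairedDataset, out_dir) -> dict:
    """Write a dataset to disk: PNG images, TSV matrices, a minimal VCF,
    the cis-eQTL table and the truth JSON.  Returns a manifest of files
    with row/column counts.  On failure all files written so far are
    removed before the error propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for sid, img in zip(dataset.sample_ids, dataset.images):
            p = img_dir / f"{sid}.png"
            Image.fromarray(img).save(p)
            created.append(p)

        def _tsv(df, name, index_label):
            p = out / name
            df.to_csv(p, sep="\t", index_label=index_label)
            created.append(p)
            return p

        _tsv(dataset.expression, "expression.tsv", "gene_id")
        _tsv(dataset.genotypes, "genotypes.tsv", "snp_id")
        _tsv(dataset.covariates, "covariates.tsv", "sample_id")
        p = out / "eqtl.tsv"
        dataset.eqtl_table.to_csv(p, sep="\t", index=False)
        created.append(p)
        vcf_path = out / "genotypes.vcf"
        _write_vcf(dataset.genotypes, vcf_path)
        created.append(vcf_path)
        truth_path = out / "truth.json"
        truth_path.write_text(dataset.truth.to_json())
        created.append(truth_path)

        manifest = {
            "n_samples": len(dataset.sample_ids),
            "images": [f"images/{s}.png" for s in dataset.sample_ids],
            "expression.tsv": list(dataset.expression.shape),
            "genotypes.tsv": list(dataset.genotypes.shape),
            "covariates.tsv": list(dataset.covariates.shape),
            "eqtl.tsv": list(dataset.eqtl_table.shape),
            "genotypes.vcf": [len(dataset.genotypes), len(dataset.sample_ids)],
            "truth.json": "truth.json",
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=1))
        created.append(mpath)
        return manifest
    except Exception:
        for p in created:
            p.unlink(missing_ok=True)
        if (out / "images").exists() and not any((out / "images").iterdir()):
            (out / "images").rmdir()
        raise
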