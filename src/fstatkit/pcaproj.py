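"""Principal components from complete modern panels with least-squares
projection of missing-data ancient samples.

Normalization follows the smartpca convention: per-SNP centering by the
fitting-panel mean genotype ``2 p_hat`` and scaling by ``sqrt(p_hat (1 -
p_hat))`` with ``p_hat = mean/2``; monomorphic SNPs are dropped.  Residual
missingness in the fitting panel is mean-imputed (zero after centering).
Projection solves an ordinary least-squares fit of a sample's normalized,
non-missing genotypes onto the loadings restricted to those SNPs; no
shrinkage correction for projection bias is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .eigendata import MISSING, GenotypeDataset


@dataclass
class PCAModel:
    snp_ids: list[str]
    snp_indices: np.ndarray  # indices into the fitting dataset's SNP list
    mean_genotype: np.ndarray  # 2 * p_hat per kept SNP
    scale: np.ndarray  # sqrt(p_hat (1 - p_hat)) per kept SNP
    loadings: np.ndarray  # (n_kept_snps, K), orthonormal columns
    scores: np.ndarray  # (n_fit, K) fitting-panel coordinates
    fitting_ids: list[str]
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_text(self, path: str | Path) -> None:
        """Serialize the model to a plain-text file."""
        with open(path, "w") as fh:
            fh.write(f"#fstatkit-pca K={self.n_components}\n")
            fh.write("#snp_id\tmean\tscale\t" + "\t".join(
                f"loading{k+1}" for k in range(self.n_components)) + "\n")
            for i, sid in enumerate(self.snp_ids):
                row = "\t".join(format(v, ".10g") for v in self.loadings[i])
                fh.write(f"{sid}\t{self.mean_genotype[i]:.10g}\t{self.scale[i]:.10g}\t{row}\n")


def fit_pca(
    dataset: GenotypeDataset,
    fitting_ids: Sequence[str],
    n_components: int,
    min_completeness: float = 0.9,
) -> PCAModel:
    """Principal components of a (mostly) complete fitting panel.

    Raises if any fitting individual's genotype completeness falls below
    ``min_completeness``; the tolerated residual missingness is mean-imputed.
    """
    idx = dataset.indices_of(fitting_ids)
    g = dataset.genotypes[:, idx].astype(float)
    g[g == MISSING] = np.nan

    completeness = 1.0 - np.isnan(g).mean(axis=0)
    low = completeness < min_completeness
    if low.any():
        bad = [fitting_ids[i] for i in np.flatnonzero(low)]
        raise ValueError(
            f"fitting individuals below completeness {min_completeness}: {bad}"
        )
    if n_components > min(len(idx) - 1, dataset.n_snps):
        raise ValueError(
            f"K={n_components} exceeds min(n_individuals - 1, n_snps) "
            f"= {min(len(idx) - 1, dataset.n_snps)}"
        )

    mean_g = np.nanmean(g, axis=1)
    p_hat = mean_g / 2.0
    keep = (p_hat > 0.0) & (p_hat < 1.0) & ~np.isnan(p_hat)
    if not keep.any():
        raise ValueError("all SNPs monomorphic in the fitting panel")
    g = g[keep]
    mean_g = mean_g[keep]
    scale = np.sqrt(p_hat[keep] * (1.0 - p_hat[keep]))

    norm = (g - mean_g[:, None]) / scale[:, None]
    norm[np.isnan(norm)] = 0.0  # mean imputation

    # samples-by-SNPs orientation for the decomposition
    u, s, vt = np.linalg.svd(norm.T, full_matrices=False)
    loadings = vt[:n_components].T
    scores = u[:, :n_components] * s[:n_components]
    explained = (s[:n_components] ** 2) / (len(idx) - 1)

    return PCAModel(
        snp_ids=[dataset.snps[i].snp_id for i in np.flatnonzero(keep)],
        snp_indices=np.flatnonzero(keep),
        mean_genotype=mean_g,
        scale=scale,
        loadings=loadings,
        scores=scores,
        fitting_ids=list(fitting_ids),
        explained_variance=explained,
    )


def lsq_project(
    model: PCAModel,
    genotypes: np.ndarray,
    min_overlap: int = 1,
) -> tuple[np.ndarray, int]:
    """Project one sample (alt-count genotypes over the model's SNPs).

    ``genotypes`` must be aligned to ``model.snp_indices`` order (use
    :func:`project_dataset` for dataset columns); missing values are skipped
    and the coordinates solve the least-squares fit on the remaining SNPs.
    Returns (coordinates, n_snps_used).
    """
    gv = np.asarray(genotypes, dtype=float)
    if gv.shape != (len(model.snp_ids),):
        raise ValueError(
            f"expected genotype vector of length {len(model.snp_ids)}, got {gv.shape}"
        )
    observed = gv != MISSING
    n_used = int(observed.sum())
    if n_used < min_overlap:
        raise ValueError(
            f"sample overlaps the model at {n_used} SNPs; minimum is {min_overlap}"
        )
    y = (gv[observed] - model.mean_genotype[observed]) / model.scale[observed]
    coords, *_ = np.linalg.lstsq(model.loadings[observed], y, rcond=None)
    return coords, n_used


def project_dataset(
    dataset: GenotypeDataset,
    model: PCAModel,
    individual_ids: Sequence[str],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Project dataset individuals onto the model; one row per individual."""
    rows = []
    for iid in individual_ids:
        col = dataset.indices_of([iid])[0]
        gv = dataset.genotypes[model.snp_indices, col]
        coords, n_used = lsq_project(model, gv, min_overlap=min_overlap)
        row = {"individual_id": iid, "n_snps_used": n_used}
        row.update({f"PC{k+1}": coords[k] for k in range(model.n_components)})
        rows.append(row)
    return pd.DataFrame(rows)
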