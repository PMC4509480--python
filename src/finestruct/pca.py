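"""Principal component analysis of the genotype matrix.

Standardization follows the smartPCA convention: each SNP column is
centered on its observed mean and scaled by sqrt(phat(1-phat)) with the
pseudocount estimate phat = (1 + count_b) / (2 + 2 n_genotyped); missing
entries are imputed to the column mean (0 after centering); monomorphic
columns are dropped with a warning.  Scores are eigenvectors of the
sample-by-sample covariance of the standardized matrix, scaled by the
square root of their eigenvalues, with the sign of each PC fixed so its
largest-magnitude entry is positive (the sign is arbitrary in theory; the
convention makes results reproducible).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset, SampleMetadata

__all__ = [
    "PCAResult",
    "GenotypePCA",
    "standardize_genotypes",
    "compute_pca",
    "detect_outliers",
    "average_pc_by_group",
]


def standardize_genotypes(ds: GenotypeDataset, return_kept: bool = False):
    """Standardized (samples x SNPs) matrix; constant SNPs dropped.

    Returns the matrix, or ``(matrix, kept_columns, means, scales)`` when
    ``return_kept`` is true.
    """
    if ds.n_samples == 0 or ds.n_snps == 0:
        raise ValueError("empty dataset")
    g = ds.genotypes.astype(float)
    valid = g != MISSING
    n = valid.sum(axis=0)
    count_b = np.where(valid, g, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, count_b / n, np.nan)
        phat = (1.0 + count_b) / (2.0 + 2.0 * n)
    scale = np.sqrt(phat * (1.0 - phat))

    observed_var = np.zeros(ds.n_snps)
    for_var = np.where(valid, g, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        observed_var = np.nanvar(for_var, axis=0)
    keep = (n > 0) & (observed_var > 0) & (scale > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} constant/monomorphic SNP(s) before PCA",
            stacklevel=2,
        )
    x = (g[:, keep] - mean[keep]) / scale[keep]
    x[~valid[:, keep]] = 0.0  # missing -> column mean after centering
    if return_kept:
        return x, np.nonzero(keep)[0], mean[keep], scale[keep]
    return x


@dataclass
class PCAResult:
    """Fitted PCA: per-sample scores, eigenvalues, variance fractions."""

    samples: list[str]
    pc_scores: np.ndarray  # samples x k, PC1 first
    eigenvalues: np.ndarray  # k, descending
    variance_explained: np.ndarray  # k fractions of total variance
    snp_means: np.ndarray
    snp_scales: np.ndarray
    model: "GenotypePCA | None" = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.pc_scores.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.pc_scores[:, i] for i in range(self.k)}
        return pd.DataFrame({"sample_id": self.samples, **cols})

    def score_of(self, sample_id: str, pc_index: int = 0) -> float:
        return float(self.pc_scores[self.samples.index(sample_id), pc_index])

    def summary(self) -> str:
        lines = [f"Genotype PCA: {len(self.samples)} samples, k={self.k}", ""]
        for i in range(self.k):
            lines.append(
                f"PC{i + 1}: eigenvalue {self.eigenvalues[i]:.4f}, "
                f"{100 * self.variance_explained[i]:.2f}% of variance"
            )
        return "\n".join(lines)

    def plot_scores(self, pc_x: int = 0, pc_y: int = 1, labels=None, ax=None):
        """Scatter of two PCs, optionally colored by a per-sample label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if labels is None:
            ax.scatter(self.pc_scores[:, pc_x], self.pc_scores[:, pc_y], s=10)
        else:
            labels = np.asarray(labels)
            for lab in np.unique(labels):
                m = labels == lab
                ax.scatter(
                    self.pc_scores[m, pc_x], self.pc_scores[m, pc_y], s=10, label=lab
                )
            ax.legend()
        ax.set_xlabel(f"PC{pc_x + 1}")
        ax.set_ylabel(f"PC{pc_y + 1}")
        return ax


class GenotypePCA:
    """PCA model over a genotype dataset; ``fit(k)`` returns a PCAResult."""

    def __init__(self, ds: GenotypeDataset):
        self.ds = ds

    def fit(self, k: int = 10) -> PCAResult:
        ds = self.ds
        if k > min(ds.n_samples - 1, ds.n_snps):
            raise ValueError(
                f"k={k} exceeds min(n_samples - 1, n_snps) = "
                f"{min(ds.n_samples - 1, ds.n_snps)}"
            )
        x, kept, means, scales = standardize_genotypes(ds, return_kept=True)
        L = x.shape[1]
        cov = x @ x.T / L
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.maximum(evals[order], 0.0)
        evecs = evecs[:, order]
        total = np.trace(cov)
        scores = np.empty((ds.n_samples, k))
        for i in range(k):
            v = evecs[:, i]
            if v[np.argmax(np.abs(v))] < 0:  # sign convention
                v = -v
            scores[:, i] = v * np.sqrt(evals[i])
        return PCAResult(
            samples=list(ds.samples),
            pc_scores=scores,
            eigenvalues=evals[:k].copy(),
            variance_explained=evals[:k] / total if total > 0 else evals[:k] * 0,
            snp_means=means,
            snp_scales=scales,
            model=self,
        )


def compute_pca(ds: GenotypeDataset, k: int = 10) -> PCAResult:
    """Top-k PCA of the standardized genotype matrix."""
    return GenotypePCA(ds).fit(k)


def detect_outliers(
    result: PCAResult, n_sigma: float = 6.0, n_iter: int = 0
) -> list[str]:
    """Iterative PC-score outlier detection (disabled by default).

    Each iteration flags samples with |score| > n_sigma * SD on any computed
    PC, removes them, and refits the PCA on the remainder.  ``n_iter=0``
    returns an empty list.  Requires the result to carry its model.
    """
    if n_sigma <= 0:
        raise ValueError("n_sigma must be > 0")
    if n_iter == 0:
        return []
    if result.model is None:
        raise ValueError("result has no attached model; refit via GenotypePCA")
    k = result.k
    ds = result.model.ds
    flagged: list[str] = []
    current = result
    for _ in range(n_iter):
        sd = current.pc_scores.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        out = np.abs(current.pc_scores) > n_sigma * sd
        hits = [current.samples[i] for i in np.nonzero(out.any(axis=1))[0]]
        if not hits:
            break
        flagged.extend(hits)
        remaining = [s for s in ds.samples if s not in set(flagged)]
        ds_sub = result.model.ds.subset_samples(remaining)
        if ds_sub.n_samples <= k:
            break
        current = GenotypePCA(ds_sub).fit(k)
    return flagged


def average_pc_by_group(
    result: PCAResult,
    metadata: Sequence[SampleMetadata],
    pc_index: int = 0,
    by: str = "state",
) -> pd.DataFrame:
    """Group means and standard errors of one PC.

    Returns columns (group, mean, se, n); SE is SD/sqrt(n), NaN for n=1.
    Every sample in the result must appear in the metadata.
    """
    meta = {m.sample_id: m for m in metadata}
    missing = [s for s in result.samples if s not in meta]
    if missing:
        raise ValueError(f"metadata missing for {len(missing)} samples: {missing[:5]}")
    labels = np.array([getattr(meta[s], by) for s in result.samples])
    scores = result.pc_scores[:, pc_index]
    rows = []
    for g in sorted(set(labels)):
        v = scores[labels == g]
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append({"group": g, "mean": float(v.mean()), "se": se, "n": int(v.size)})
    return pd.DataFrame(rows)
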