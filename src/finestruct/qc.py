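"""Genotype quality control: missingness filters, MAF, Hardy-Weinberg
exact test, and LD pruning.

Boundary conventions are strict in the stated direction: samples/SNPs with
missing fraction strictly above the threshold are removed, SNPs with MAF
strictly below ``min_maf`` are removed, and SNPs with exact HWE p strictly
below ``hwe_p_min`` are removed.  LD pruning slides a window of
``ld_window`` SNPs advancing by ``ld_step`` over (chrom, pos)-ordered
variants and greedily removes, from any pair with genotype r^2 above
``ld_r2_max``, the member with the lower MAF (ties: later position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genodata import MISSING, GenotypeDataset

__all__ = [
    "QCParams",
    "QCStage",
    "QCReport",
    "filter_sample_missingness",
    "filter_snp_missingness",
    "filter_maf",
    "hwe_exact_p",
    "filter_hwe",
    "ld_r2",
    "ld_prune",
    "run_qc",
]


@dataclass
class QCParams:
    max_sample_missing: float = 0.10
    max_snp_missing: float = 0.10
    min_maf: float = 0.05
    hwe_p_min: float = 0.002
    ld_r2_max: float = 0.8
    ld_window: int = 50
    ld_step: int = 5

    def __post_init__(self):
        for name in ("max_sample_missing", "max_snp_missing", "min_maf", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.ld_r2_max <= 1.0:
            raise ValueError("ld_r2_max must be in [0, 1]")
        if not self.ld_window >= self.ld_step >= 1:
            raise ValueError("require ld_window >= ld_step >= 1")


@dataclass
class QCStage:
    name: str
    removed_samples: int
    removed_snps: int
    retained_samples: int
    retained_snps: int


@dataclass
class QCReport:
    stages: list[QCStage] = field(default_factory=list)

    def add(self, name: str, ds: GenotypeDataset, rm_samples: int, rm_snps: int):
        self.stages.append(
            QCStage(name, rm_samples, rm_snps, ds.n_samples, ds.n_snps)
        )

    def as_dict(self) -> dict:
        return {
            "stages": [vars(s) for s in self.stages],
            "final_samples": self.stages[-1].retained_samples if self.stages else None,
            "final_snps": self.stages[-1].retained_snps if self.stages else None,
        }


# ---------------------------------------------------------------------------
# missingness / MAF
# ---------------------------------------------------------------------------

def filter_sample_missingness(ds: GenotypeDataset, threshold: float):
    """Remove samples whose missing fraction is strictly > threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    frac = ds.missing_mask().mean(axis=1)
    keep = frac <= threshold
    removed = [s for s, k in zip(ds.samples, keep) if not k]
    return ds.subset_samples([s for s, k in zip(ds.samples, keep) if k]), removed


def filter_snp_missingness(ds: GenotypeDataset, threshold: float):
    """Remove SNPs whose missing fraction is strictly > threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    frac = ds.missing_mask().mean(axis=0)
    keep = np.nonzero(frac <= threshold)[0]
    removed = [ds.variants[j].snp_id for j in np.nonzero(frac > threshold)[0]]
    return ds.subset_variants(keep), removed


def filter_maf(ds: GenotypeDataset, min_maf: float):
    """Remove SNPs with minor allele frequency strictly < min_maf.

    MAF is computed over non-missing genotypes; all-missing SNPs have
    undefined MAF and are removed for any min_maf > 0.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = ds.maf()
    with np.errstate(invalid="ignore"):
        keep_mask = maf >= min_maf  # NaN (all-missing) compares False
    if min_maf == 0.0:
        keep_mask |= np.isnan(maf)  # nothing is strictly below 0
    keep = np.nonzero(keep_mask)[0]
    removed = [ds.variants[j].snp_id for j in np.nonzero(~keep_mask)[0]]
    return ds.subset_variants(keep), removed


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts compatible with them, the probabilities of configurations whose
    conditional (hypergeometric-type) probability does not exceed that of
    the observed one.  Probability-mass ordering, no mid-p.  n = 0 returns
    1 (untestable).

    Uses the standard stable recurrence on unnormalized probabilities:
    P(het+2)/P(het) = hom_r * hom_c * 4 / ((het+2)(het+1)) where hom_r,
    hom_c are the rare/common homozygote counts at het.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    het_max = min(n_rare, 2 * n - n_rare)
    # feasible het counts share the parity of the rare-allele total
    het0 = n_rare % 2
    m = (het_max - het0) // 2 + 1
    probs = np.empty(m)
    probs[0] = 1.0
    het = het0
    for i in range(1, m):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[i] = probs[i - 1] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
    probs /= probs.sum()
    obs = (n_Aa - het0) // 2
    # tolerance guards against rounding ties in the mass comparison
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def filter_hwe(ds: GenotypeDataset, p_min: float):
    """Remove SNPs with exact HWE p strictly < p_min (all samples pooled)."""
    if not 0.0 <= p_min <= 1.0:
        raise ValueError("p_min must be in [0, 1]")
    g = ds.genotypes
    valid = g != MISSING
    n_het = ((g == 1) & valid).sum(axis=0)
    n_bb = ((g == 2) & valid).sum(axis=0)
    n_aa = ((g == 0) & valid).sum(axis=0)
    keep, removed = [], []
    for j in range(ds.n_snps):
        p = hwe_exact_p(int(n_aa[j]), int(n_het[j]), int(n_bb[j]))
        if p < p_min:
            removed.append(ds.variants[j].snp_id)
        else:
            keep.append(j)
    return ds.subset_variants(keep), removed


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of genotype codes over pairwise-complete
    samples; 0 when undefined (constant vector or <2 complete pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy)
    return float(r * r)


def _window_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise r^2 matrix for a (samples x m) genotype block with missing
    entries handled pairwise-complete."""
    m = g.shape[1]
    out = np.zeros((m, m))
    valid = g != MISSING
    if valid.all():
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(g.astype(float).T)
        c = np.nan_to_num(c, nan=0.0)
        return c * c
    for a in range(m):
        for b in range(a + 1, m):
            out[a, b] = out[b, a] = ld_r2(g[:, a], g[:, b])
    return out


def ld_prune(ds: GenotypeDataset, params: QCParams):
    """Greedy sliding-window LD pruning.

    Variants must be sorted by (chrom, pos).  Within each window, while any
    retained pair has r^2 > ``ld_r2_max``, the pair member with the lower
    MAF is removed (ties: the later position).  Deterministic.
    """
    order = sorted(
        range(ds.n_snps), key=lambda j: (ds.variants[j].chrom, ds.variants[j].pos)
    )
    if order != list(range(ds.n_snps)):
        raise ValueError("variants must be ordered by (chrom, pos) before pruning")
    maf = ds.maf()
    removed_mask = np.zeros(ds.n_snps, dtype=bool)
    start = 0
    while True:
        stop = min(start + params.ld_window, ds.n_snps)
        idx = [j for j in range(start, stop) if not removed_mask[j]]
        if len(idx) > 1:
            block = ds.genotypes[:, idx]
            r2 = _window_r2(block)
            alive = list(range(len(idx)))
            while True:
                worst = None
                for ai in range(len(alive)):
                    for bi in range(ai + 1, len(alive)):
                        a, b = alive[ai], alive[bi]
                        if r2[a, b] > params.ld_r2_max:
                            worst = (a, b)
                            break
                    if worst:
                        break
                if worst is None:
                    break
                a, b = worst
                ja, jb = idx[a], idx[b]
                # drop the lower-MAF member; tie -> later position
                drop = jb if (maf[jb] < maf[ja] or maf[jb] == maf[ja]) else ja
                removed_mask[drop] = True
                alive.remove(a if drop == ja else b)
        if stop == ds.n_snps:
            break
        start += params.ld_step
    keep = np.nonzero(~removed_mask)[0]
    removed = [ds.variants[j].snp_id for j in np.nonzero(removed_mask)[0]]
    return ds.subset_variants(keep), removed


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def run_qc(ds: GenotypeDataset, params: QCParams | None = None):
    """Apply the full QC chain in order: sample missingness -> SNP
    missingness -> MAF -> HWE -> LD pruning.  Returns (dataset, QCReport)."""
    params = params or QCParams()
    report = QCReport()

    ds1, rm_s = filter_sample_missingness(ds, params.max_sample_missing)
    report.add("sample_missingness", ds1, len(rm_s), 0)
    ds2, rm = filter_snp_missingness(ds1, params.max_snp_missing)
    report.add("snp_missingness", ds2, 0, len(rm))
    ds3, rm = filter_maf(ds2, params.min_maf)
    report.add("maf", ds3, 0, len(rm))
    ds4, rm = filter_hwe(ds3, params.hwe_p_min)
    report.add("hwe", ds4, 0, len(rm))
    ds5, rm = ld_prune(ds4, params)
    report.add("ld_prune", ds5, 0, len(rm))
    return ds5, report
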