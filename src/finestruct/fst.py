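"""Weir-Cockerham variance-components F_ST for two populations, with
SNP-bootstrap confidence intervals, pairwise population matrices,
top-percentile scans, and minor-allele discordance detection.

Per SNP, with r = 2 populations of n_i genotyped diploids, allele-b
frequencies p_i and observed heterozygote frequencies h_i:

    nbar = sum(n_i)/r
    nc   = (r*nbar - sum(n_i^2)/(r*nbar)) / (r-1)
    pbar = sum(n_i p_i) / (r*nbar)
    s2   = sum(n_i (p_i - pbar)^2) / ((r-1) nbar)
    hbar = sum(n_i h_i) / (r*nbar)
    a = (nbar/nc) [s2 - (pbar(1-pbar) - s2 (r-1)/r - hbar/4) / (nbar-1)]
    b = (nbar/(nbar-1)) [pbar(1-pbar) - s2 (r-1)/r - hbar (2 nbar-1)/(4 nbar)]
    c = hbar/2
    theta = a / (a+b+c)

a is the between-population component, b between-individual-within-
population, c within-individual.  The genome-wide estimate combines SNPs as
a ratio of sums, sum(a) / sum(a+b+c) — not a mean of per-SNP ratios — and
negative estimates are reported as-is: the estimator is unbiased around
F = 0 and tiny true differentiation demands the negative tail.

When only allele frequencies are available (no genotype table), hbar
defaults to its Hardy-Weinberg expectation sum(n_i * 2 p_i (1-p_i))/(r*nbar)
via :func:`per_snp_fst_from_frequencies`.

The bootstrap resamples SNPs (the genome), not individuals, with
replacement; individual resampling is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genodata import MISSING, AlleleCounts, GenotypeDataset

__all__ = [
    "FstComponents",
    "GenomewideFst",
    "per_snp_fst",
    "per_snp_fst_from_frequencies",
    "per_snp_fst_table",
    "genomewide_fst",
    "bootstrap_fst",
    "pairwise_fst_matrix",
    "top_differentiated",
    "minor_allele_discordance",
    "PairwiseFst",
    "FstResults",
]


@dataclass(frozen=True)
class FstComponents:
    a: float
    b: float
    c: float
    theta: float  # NaN when a+b+c <= 0
    nbar: float
    nc: float
    s2: float
    hbar: float
    pbar: float


@dataclass(frozen=True)
class GenomewideFst:
    point: float
    ci_lower: float | None = None
    ci_upper: float | None = None
    boot_se: float | None = None
    n_boot: int = 0
    n_snps_used: int = 0


# ---------------------------------------------------------------------------
# per-SNP components
# ---------------------------------------------------------------------------

def _components_arrays(n1, p1, h1, n2, p2, h2):
    """Vectorized variance components for two populations (r = 2).

    All inputs are broadcastable arrays; n_i are genotyped-diploid counts,
    p_i allele-b frequencies, h_i heterozygote frequencies.  Returns
    (a, b, c) arrays.
    """
    r = 2.0
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    inner = pbar * (1.0 - pbar) - s2 * (r - 1.0) / r
    a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b = (nbar / (nbar - 1.0)) * (inner - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar))
    c = hbar / 2.0
    return a, b, c, nbar, nc, s2, hbar, pbar


def _make_components(n1, p1, h1, n2, p2, h2) -> FstComponents:
    a, b, c, nbar, nc, s2, hbar, pbar = _components_arrays(n1, p1, h1, n2, p2, h2)
    denom = a + b + c
    theta = a / denom if denom > 0 else float("nan")
    return FstComponents(
        a=float(a), b=float(b), c=float(c), theta=float(theta),
        nbar=float(nbar), nc=float(nc), s2=float(s2), hbar=float(hbar),
        pbar=float(pbar),
    )


def per_snp_fst(counts_pop1: AlleleCounts, counts_pop2: AlleleCounts) -> FstComponents:
    """Variance components from observed genotype counts of two populations."""
    for c in (counts_pop1, counts_pop2):
        if c.n_genotyped < 2:
            raise ValueError("each population needs n_genotyped >= 2")
    return _make_components(
        counts_pop1.n_genotyped, counts_pop1.freq_b, counts_pop1.het_freq,
        counts_pop2.n_genotyped, counts_pop2.freq_b, counts_pop2.het_freq,
    )


def per_snp_fst_from_frequencies(
    p1: float, n1: int, p2: float, n2: int
) -> FstComponents:
    """Variance components from allele frequencies alone.

    Heterozygote frequencies are taken at their Hardy-Weinberg expectation
    2 p_i (1 - p_i).  Frequencies must be oriented to a common allele in
    both populations before calling.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs n >= 2")
    return _make_components(
        n1, p1, 2.0 * p1 * (1.0 - p1), n2, p2, 2.0 * p2 * (1.0 - p2)
    )


# ---------------------------------------------------------------------------
# dataset-level machinery
# ---------------------------------------------------------------------------

def _group_stats(ds: GenotypeDataset, sample_ids: Sequence[str]):
    g = ds.genotypes[ds.sample_rows(sample_ids)]
    valid = g != MISSING
    n = valid.sum(axis=0).astype(float)
    count_b = np.where(valid, g, 0).sum(axis=0).astype(float)
    het = (g == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, count_b / (2 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def _dataset_components(ds, group1, group2):
    """Per-SNP (a, den, usable) arrays for two sample groups."""
    n1, p1, h1 = _group_stats(ds, group1)
    n2, p2, h2 = _group_stats(ds, group2)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, c, *_ = _components_arrays(n1, p1, h1, n2, p2, h2)
    a = np.where(usable, np.nan_to_num(a, nan=0.0), 0.0)
    den = a + np.where(usable, np.nan_to_num(b, nan=0.0), 0.0) + np.where(
        usable, np.nan_to_num(c, nan=0.0), 0.0
    )
    return a, den, usable


def per_snp_fst_table(
    ds: GenotypeDataset, group1: Sequence[str], group2: Sequence[str]
) -> pd.DataFrame:
    """Per-SNP component table: snp_id, chrom, pos, p1, p2, a, b, c, theta."""
    n1, p1, h1 = _group_stats(ds, group1)
    n2, p2, h2 = _group_stats(ds, group2)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, c, *_ = _components_arrays(n1, p1, h1, n2, p2, h2)
        den = a + b + c
        theta = np.where(usable & (den > 0), a / den, np.nan)
    vf = ds.variant_frame()
    return pd.DataFrame(
        {
            "snp_id": vf["snp_id"],
            "chrom": vf["chrom"],
            "pos": vf["pos"],
            "p1": p1,
            "p2": p2,
            "a": np.where(usable, a, np.nan),
            "b": np.where(usable, b, np.nan),
            "c": np.where(usable, c, np.nan),
            "theta": theta,
        }
    )


def genomewide_fst(
    ds: GenotypeDataset, group1: Sequence[str], group2: Sequence[str]
) -> GenomewideFst:
    """Ratio-of-sums genome-wide estimate sum(a)/sum(a+b+c) over usable SNPs."""
    a, den, usable = _dataset_components(ds, group1, group2)
    if not usable.any():
        raise ValueError("no usable SNPs (need >= 2 genotyped samples per group)")
    total = den[usable].sum()
    if total == 0:
        raise ValueError("zero total variance across usable SNPs")
    return GenomewideFst(
        point=float(a[usable].sum() / total), n_snps_used=int(usable.sum())
    )


def bootstrap_fst(
    ds: GenotypeDataset,
    group1: Sequence[str],
    group2: Sequence[str],
    n_boot: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
    resample: str = "snps",
    return_replicates: bool = False,
):
    """Genome-wide F_ST with percentile bootstrap CI.

    The resampling unit is the SNP (``resample='snps'``, default): each
    replicate draws L SNP indices with replacement and recomputes the ratio
    of sums.  ``resample='individuals'`` instead resamples samples within
    each group (documented alternative).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    point = genomewide_fst(ds, group1, group2)

    if resample == "snps":
        a, den, usable = _dataset_components(ds, group1, group2)
        a_u, den_u = a[usable], den[usable]
        L = a_u.size
        reps = np.empty(n_boot)
        chunk = max(1, min(n_boot, int(4e6) // max(L, 1) + 1))
        done = 0
        while done < n_boot:
            m = min(chunk, n_boot - done)
            idx = rng.integers(0, L, size=(m, L))
            num = a_u[idx].sum(axis=1)
            dem = den_u[idx].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                reps[done : done + m] = num / dem
            done += m
    elif resample == "individuals":
        reps = np.empty(n_boot)
        g1 = list(group1)
        g2 = list(group2)
        rows_a, rows_b = ds.sample_rows(g1), ds.sample_rows(g2)
        for t in range(n_boot):
            # resampled individuals may repeat: recompute stats on row indices
            rows1 = rows_a[rng.integers(0, len(g1), len(g1))]
            rows2 = rows_b[rng.integers(0, len(g2), len(g2))]
            reps[t] = _rowwise_point(ds, rows1, rows2)
    else:
        raise ValueError("resample must be 'snps' or 'individuals'")

    reps = reps[np.isfinite(reps)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    est = GenomewideFst(
        point=point.point,
        ci_lower=float(lo),
        ci_upper=float(hi),
        boot_se=float(reps.std(ddof=1)) if reps.size > 1 else 0.0,
        n_boot=n_boot,
        n_snps_used=point.n_snps_used,
    )
    if return_replicates:
        return est, reps
    return est


def _rowwise_point(ds: GenotypeDataset, rows1: np.ndarray, rows2: np.ndarray) -> float:
    def stats(rows):
        g = ds.genotypes[rows]
        valid = g != MISSING
        n = valid.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(valid, g, 0).sum(axis=0) / (2 * n), np.nan)
            h = np.where(n > 0, (g == 1).sum(axis=0) / n, np.nan)
        return n, p, h

    n1, p1, h1 = stats(rows1)
    n2, p2, h2 = stats(rows2)
    usable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a, b, c, *_ = _components_arrays(n1, p1, h1, n2, p2, h2)
    a = np.nan_to_num(np.where(usable, a, 0.0))
    den = a + np.nan_to_num(np.where(usable, b, 0.0)) + np.nan_to_num(
        np.where(usable, c, 0.0)
    )
    return float(a.sum() / den.sum())


def pairwise_fst_matrix(
    ds: GenotypeDataset,
    grouping: Mapping[str, str],
    n_boot: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """All unordered group pairs.  Returns a long-format DataFrame with one
    row per pair (group_a, group_b, point, ci_lower, ci_upper, boot_se);
    use :func:`point_matrix` for the symmetric wide layout."""
    groups: dict[str, list[str]] = {}
    for s, g in grouping.items():
        groups.setdefault(g, []).append(s)
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(names) * (len(names) - 1) // 2)
    k = 0
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            if n_boot > 0:
                est = bootstrap_fst(
                    ds, groups[ga], groups[gb], n_boot=n_boot,
                    seed=ss[k].generate_state(1)[0] & 0x7FFFFFFF,
                )
            else:
                est = genomewide_fst(ds, groups[ga], groups[gb])
            k += 1
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "point": est.point,
                    "ci_lower": est.ci_lower,
                    "ci_upper": est.ci_upper,
                    "boot_se": est.boot_se,
                    "n_snps_used": est.n_snps_used,
                }
            )
    return pd.DataFrame(rows)


def point_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    """Symmetric wide-format matrix of point estimates (diagonal empty)."""
    names = sorted(set(pairs["group_a"]) | set(pairs["group_b"]))
    m = pd.DataFrame(np.nan, index=names, columns=names)
    for _, r in pairs.iterrows():
        m.loc[r["group_a"], r["group_b"]] = r["point"]
        m.loc[r["group_b"], r["group_a"]] = r["point"]
    return m


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def top_differentiated(
    theta_table: pd.DataFrame,
    top_fraction: float = 0.01,
    abs_threshold: float | None = None,
) -> pd.DataFrame:
    """Rank SNPs by descending theta and cut.

    With ``abs_threshold`` set, returns all SNPs with theta strictly above
    it.  Otherwise the top ``top_fraction`` of finite-theta SNPs is
    returned, including every SNP tied with the boundary value.
    """
    if theta_table.empty:
        raise ValueError("theta table is empty")
    t = theta_table.dropna(subset=["theta"]).sort_values(
        "theta", ascending=False, kind="mergesort"
    )
    if abs_threshold is not None:
        return t[t["theta"] > abs_threshold].reset_index(drop=True)
    k = max(1, int(np.ceil(len(t) * top_fraction)))
    boundary = t["theta"].iloc[k - 1]
    return t[t["theta"] >= boundary].reset_index(drop=True)


def minor_allele_discordance(
    ds: GenotypeDataset, group1: Sequence[str], group2: Sequence[str]
):
    """Count SNPs whose within-group minor allele differs between groups.

    A group's minor allele is allele_b when its allele_b frequency is
    <= 0.5 (exact 0.5 resolves to allele_b), else allele_a.  Returns
    (count, snp_id list).
    """
    p1 = ds.allele_freq(ds.sample_rows(group1))
    p2 = ds.allele_freq(ds.sample_rows(group2))
    minor_is_b_1 = p1 <= 0.5
    minor_is_b_2 = p2 <= 0.5
    disc = (minor_is_b_1 != minor_is_b_2) & ~np.isnan(p1) & ~np.isnan(p2)
    snps = [ds.variants[j].snp_id for j in np.nonzero(disc)[0]]
    return int(disc.sum()), snps


# ---------------------------------------------------------------------------
# model/results facade
# ---------------------------------------------------------------------------

class PairwiseFst:
    """Pairwise-F_ST model over a grouped genotype dataset.

    Parameters
    ----------
    ds : GenotypeDataset
    grouping : mapping of sample_id -> group label (e.g. region).

    ``fit(n_boot=1000, seed=None)`` estimates every unordered pair with
    SNP-bootstrap CIs and returns an :class:`FstResults`.
    """

    def __init__(self, ds: GenotypeDataset, grouping: Mapping[str, str]):
        self.ds = ds
        self.grouping = dict(grouping)

    @classmethod
    def from_metadata(cls, ds: GenotypeDataset, metadata, by: str = "region"):
        grouping = {m.sample_id: getattr(m, by) for m in metadata}
        return cls(ds, {s: grouping[s] for s in ds.samples if s in grouping})

    def fit(self, n_boot: int = 1000, seed: int | None = None) -> "FstResults":
        pairs = pairwise_fst_matrix(self.ds, self.grouping, n_boot=n_boot, seed=seed)
        return FstResults(self, pairs, n_boot=n_boot, seed=seed)


class FstResults:
    def __init__(self, model: PairwiseFst, pairs: pd.DataFrame, n_boot: int, seed):
        self.model = model
        self.pairs = pairs
        self.n_boot = n_boot
        self.seed = seed

    def point_matrix(self) -> pd.DataFrame:
        return point_matrix(self.pairs)

    def summary(self) -> str:
        lines = [
            "Pairwise F_ST (Weir-Cockerham, ratio of sums; "
            f"{self.n_boot} SNP-bootstrap replicates)",
            "",
        ]
        for _, r in self.pairs.iterrows():
            ci = (
                f"  95% CI [{r['ci_lower']:.3e}, {r['ci_upper']:.3e}]"
                f"  SE {r['boot_se']:.3e}"
                if r["ci_lower"] is not None and not pd.isna(r["ci_lower"])
                else ""
            )
            lines.append(
                f"{r['group_a']:>8s} vs {r['group_b']:<8s} "
                f"theta = {r['point']: .6e}{ci}"
            )
        return "\n".join(lines)
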