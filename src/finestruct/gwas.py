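"""Case-control association testing and the effect of population
substructure on it: type-I error, power, and genomic inflation.

The default per-SNP test is the 1-df allelic chi-square on the 2x2
case/control allele-count table; the Cochran-Armitage trend test (weights
0,1,2) is available as an alternative.  :func:`run_gwas_simulation`
repeatedly simulates stratified case-control cohorts, tests every SNP, and
accumulates the false-positive rate over null SNPs and power over causal
SNPs at each significance level, plus the genomic inflation factor
lambda_GC = median(chi^2) / 0.4549 over null SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .genodata import MISSING
from .synthetic import CaseControlConfig, simulate_case_control

__all__ = [
    "AssociationResult",
    "GwasSimMetrics",
    "allelic_chisq",
    "allelic_chisq_array",
    "trend_test",
    "genomic_control",
    "run_gwas_simulation",
]

# median of the 1-df chi-square distribution, to 4 decimals
CHI2_1DF_MEDIAN = 0.4549


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    chi_square: float
    p_value: float
    test: str
    counts: tuple
    testable: bool = True


def allelic_chisq(
    case_b: int, case_a: int, ctrl_b: int, ctrl_a: int, snp_id: str = ""
) -> AssociationResult:
    """1-df Pearson chi-square on the 2x2 allele-count table.

    A zero margin (monomorphic site or empty group) is untestable and
    reported as chi^2 = 0, p = 1 with ``testable=False``.
    """
    n = case_b + case_a + ctrl_b + ctrl_a
    r1, r2 = case_b + case_a, ctrl_b + ctrl_a
    c1, c2 = case_b + ctrl_b, case_a + ctrl_a
    if min(r1, r2, c1, c2) == 0:
        return AssociationResult(
            snp_id, 0.0, 1.0, "allelic", (case_b, case_a, ctrl_b, ctrl_a), False
        )
    chi2 = n * (case_b * ctrl_a - case_a * ctrl_b) ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return AssociationResult(
        snp_id, float(chi2), p, "allelic", (case_b, case_a, ctrl_b, ctrl_a)
    )


def allelic_chisq_array(g: np.ndarray, phenotype: np.ndarray):
    """Vectorized allelic chi-square across all SNPs of a genotype matrix.

    Returns (chi_square, p_value, testable) arrays.  Missing genotypes are
    dropped per SNP.
    """
    phen = np.asarray(phenotype).astype(bool)
    gc_ = g[phen]  # cases
    gt_ = g[~phen]  # controls
    vc, vt = gc_ != MISSING, gt_ != MISSING
    case_b = np.where(vc, gc_, 0).sum(axis=0).astype(float)
    case_a = (2.0 * vc.sum(axis=0)) - case_b
    ctrl_b = np.where(vt, gt_, 0).sum(axis=0).astype(float)
    ctrl_a = (2.0 * vt.sum(axis=0)) - ctrl_b
    n = case_b + case_a + ctrl_b + ctrl_a
    r1, r2 = case_b + case_a, ctrl_b + ctrl_a
    c1, c2 = case_b + ctrl_b, case_a + ctrl_a
    denom = r1 * r2 * c1 * c2
    testable = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(
            testable, n * (case_b * ctrl_a - case_a * ctrl_b) ** 2 / denom, 0.0
        )
    p = np.where(testable, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p, testable


def trend_test(genotype_counts: np.ndarray, snp_id: str = "") -> AssociationResult:
    """Cochran-Armitage trend test on a 2x3 (case/control x genotype) table
    with weights (0, 1, 2), 1 df."""
    t = np.asarray(genotype_counts, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("expected a 2x3 table (rows: cases, controls)")
    n = t.sum()
    if n == 0:
        raise ValueError("empty table")
    w = np.array([0.0, 1.0, 2.0])
    r = t[0].sum()  # cases
    col = t.sum(axis=0)
    # score statistic: U = sum_j w_j (case_j - r * col_j / n)
    u = float(w @ (t[0] - r * col / n))
    pbar = r / n
    var = pbar * (1 - pbar) * (
        float(w**2 @ col) - float(w @ col) ** 2 / n
    )
    if var <= 0 or r == 0 or r == n:
        return AssociationResult(snp_id, 0.0, 1.0, "trend", tuple(map(tuple, t)), False)
    chi2 = u * u / var
    return AssociationResult(
        snp_id, float(chi2), float(stats.chi2.sf(chi2, df=1)), "trend",
        tuple(map(tuple, t)),
    )


def genomic_control(chi_square: np.ndarray):
    """Genomic-control inflation factor and adjusted p-values.

    lambda = median(chi^2) / 0.4549; the adjustment divides every statistic
    by max(lambda, 1) — deflation is never applied.  Returns
    (lambda, adjusted_p).
    """
    x = np.asarray(chi_square, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one statistic")
    lam = float(np.median(x) / CHI2_1DF_MEDIAN)
    adj = x / max(lam, 1.0)
    return lam, stats.chi2.sf(adj, df=1)


@dataclass
class GwasSimMetrics:
    """Averaged simulation metrics (with across-replicate SDs)."""

    fpr_per_alpha: dict[float, float]
    power_per_alpha: dict[float, float]
    lambda_gc: float
    n_null: int
    n_causal: int
    n_replicates: int
    seed: int | None
    fpr_sd_per_alpha: dict[float, float] = field(default_factory=dict)
    power_sd_per_alpha: dict[float, float] = field(default_factory=dict)
    lambda_gc_sd: float = float("nan")
    scenario: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"GWAS simulation: {self.n_replicates} replicate(s), "
            f"{self.n_null} null / {self.n_causal} causal SNPs",
            f"lambda_GC = {self.lambda_gc:.4f}",
        ]
        for a in sorted(self.fpr_per_alpha):
            lines.append(f"FPR @ alpha={a:g}: {self.fpr_per_alpha[a]:.4g}")
        for a in sorted(self.power_per_alpha):
            lines.append(f"power @ alpha={a:g}: {self.power_per_alpha[a]:.4g}")
        return "\n".join(lines)


def run_gwas_simulation(
    cfg: CaseControlConfig,
    n_replicates: int = 1,
    seed: int | None = None,
    test: str = "allelic",
) -> GwasSimMetrics:
    """Simulate, test and score ``n_replicates`` case-control cohorts."""
    if test != "allelic":
        raise ValueError("only the allelic test is wired into the simulator")
    alphas = list(cfg.alpha_levels)
    streams = np.random.SeedSequence(seed).spawn(n_replicates)
    fpr = {a: [] for a in alphas}
    power = {a: [] for a in alphas}
    lams = []
    n_null = n_causal = 0
    for ss in streams:
        rep_cfg = CaseControlConfig(**{**cfg.__dict__})
        rep_cfg.seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
        ds, phen, truth = simulate_case_control(rep_cfg)
        chi2, p, testable = allelic_chisq_array(ds.genotypes, phen)
        null = ~truth["is_causal"] & testable
        causal = truth["is_causal"] & testable
        n_null, n_causal = int(null.sum()), int(causal.sum())
        for a in alphas:
            if n_null:
                fpr[a].append(float((p[null] < a).mean()))
            if n_causal:
                power[a].append(float((p[causal] < a).mean()))
        if n_null:
            lams.append(float(np.median(chi2[null]) / CHI2_1DF_MEDIAN))

    def _mean(d):
        return {a: float(np.mean(v)) if v else float("nan") for a, v in d.items()}

    def _sd(d):
        return {
            a: float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
            for a, v in d.items()
        }

    return GwasSimMetrics(
        fpr_per_alpha=_mean(fpr),
        power_per_alpha=_mean(power),
        lambda_gc=float(np.mean(lams)) if lams else float("nan"),
        n_null=n_null,
        n_causal=n_causal,
        n_replicates=n_replicates,
        seed=seed,
        fpr_sd_per_alpha=_sd(fpr),
        power_sd_per_alpha=_sd(power),
        lambda_gc_sd=float(np.std(lams, ddof=1)) if len(lams) > 1 else float("nan"),
        scenario={
            "n_cases": cfg.n_cases,
            "n_controls": cfg.n_controls,
            "case_pop_fractions": list(cfg.case_pop_fractions),
            "control_pop_fractions": list(cfg.control_pop_fractions),
            "fst_true": cfg.fst_true,
            "n_snps": cfg.n_snps,
            "causal_snps": list(cfg.causal_snps),
        },
    )
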