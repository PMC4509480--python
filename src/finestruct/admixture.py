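"""Maximum-likelihood admixture-proportion inference via EM.

The model: individual i carries ancestry fractions q_i (summing to 1 over K
latent components), component k has allele-b frequency f_kj at SNP j, and
genotype g_ij ~ Binomial(2, sum_k q_ik f_kj).  The log-likelihood over
non-missing genotypes is

    sum_ij g_ij log(P_ij) + (2 - g_ij) log(1 - P_ij),   P = Q F,

with P clamped to [1e-10, 1 - 1e-10].  Fitting uses plain EM (FRAPPE-style
expected-allele-count updates), which increases the likelihood monotonically;
the quasi-Newton acceleration of the dedicated tools is out of scope — the
scientific content is the fitted Q, not the optimizer.  Initialization is
random (Dirichlet(1) rows of Q, Uniform(0.05, 0.95) entries of F) with
multiple seeded restarts, keeping the best final likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeDataset, SampleMetadata

__all__ = [
    "AdmixtureResult",
    "AdmixtureModel",
    "admixture_loglik",
    "em_step",
    "fit_admixture",
    "compare_components_by_region",
]

_EPS = 1e-10


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1.0 - _EPS)


def admixture_loglik(genotypes: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial mixture log-likelihood over non-missing genotypes."""
    g = np.asarray(genotypes)
    if Q.shape[0] != g.shape[0] or F.shape[1] != g.shape[1] or Q.shape[1] != F.shape[0]:
        raise ValueError(
            f"dimension mismatch: genotypes {g.shape}, Q {Q.shape}, F {F.shape}"
        )
    obs = g != MISSING
    if not obs.any():
        return 0.0
    P = _clamp(Q @ F)
    gf = np.where(obs, g, 0).astype(float)
    ll = gf * np.log(P) + (2.0 - gf) * np.log1p(-P)
    return float(ll[obs].sum())


def em_step(genotypes: np.ndarray, Q: np.ndarray, F: np.ndarray):
    """One EM update of (Q, F); never decreases the log-likelihood.

    E-step: partition each observed allele-b copy (and allele-a copy) over
    components by Bayes' rule.  M-step: Q rows are the normalized expected
    ancestry counts; F entries the ratio of expected allele-b counts to
    expected totals.
    """
    g = np.asarray(genotypes)
    obs = g != MISSING
    gf = np.where(obs, g, 0).astype(float)
    comp = np.where(obs, 2.0 - gf, 0.0)  # allele-a copies

    return _em_step_inner(gf, comp, Q, F)[:2]


def _em_step_inner(gf: np.ndarray, comp: np.ndarray, Q: np.ndarray, F: np.ndarray):
    """Core update on precomputed b-copy/a-copy count matrices.

    Returns (Q', F', loglik(Q, F)) — the likelihood of the *incoming*
    parameters, a free byproduct of the shared P = QF evaluation.
    """
    P = _clamp(Q @ F)
    Pc = _clamp(1.0 - P)
    ll = float((gf * np.log(P)).sum() + (comp * np.log(Pc)).sum())

    # With A = gf/P and B = comp/Pc, the expected-count updates collapse to
    # matrix products:
    #   Q'_ik  propto  q_ik * (A F^T + B (1-F)^T)_ik
    #   F'_kj  =  f_kj (Q^T A)_kj / (f_kj (Q^T A)_kj + (1-f_kj)(Q^T B)_kj)
    A = gf / P
    B = comp / Pc
    Fc = 1.0 - F
    Q_new = Q * (A @ F.T + B @ Fc.T)
    tot = Q_new.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    Q_new /= tot

    F_num = F * (Q.T @ A)
    F_den = F_num + Fc * (Q.T @ B)
    with np.errstate(invalid="ignore", divide="ignore"):
        F_new = np.where(F_den > 0, F_num / F_den, F)
    return Q_new, _clamp(F_new), ll


@dataclass
class AdmixtureResult:
    """Fitted ancestry proportions Q (rows sum to 1) and component allele
    frequencies F, with the per-iteration log-likelihood trace."""

    Q: np.ndarray  # samples x K
    F: np.ndarray  # K x SNPs
    loglik_trace: list[float]
    K: int
    seed: int | None
    n_iter: int
    converged: bool
    samples: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def q_frame(self) -> pd.DataFrame:
        cols = {f"Q{k + 1}": self.Q[:, k] for k in range(self.K)}
        ids = self.samples or [f"s{i}" for i in range(self.Q.shape[0])]
        return pd.DataFrame({"sample_id": ids, **cols})

    def summary(self) -> str:
        return (
            f"Admixture EM fit: K={self.K}, {self.Q.shape[0]} samples, "
            f"{self.F.shape[1]} SNPs\n"
            f"log-likelihood {self.loglik:.2f} after {self.n_iter} iterations "
            f"({'converged' if self.converged else 'max_iter reached'})\n"
            "mean ancestry fractions: "
            + ", ".join(
                f"Q{k + 1}={self.Q[:, k].mean():.3f}" for k in range(self.K)
            )
        )

    def plot_bar(self, order=None, ax=None):
        """Stacked per-sample ancestry bar plot."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        q = self.Q if order is None else self.Q[np.asarray(order)]
        bottom = np.zeros(q.shape[0])
        x = np.arange(q.shape[0])
        for k in range(self.K):
            ax.bar(x, q[:, k], bottom=bottom, width=1.0, label=f"Q{k + 1}")
            bottom += q[:, k]
        ax.set_xlim(-0.5, q.shape[0] - 0.5)
        ax.set_ylim(0, 1)
        ax.set_ylabel("ancestry fraction")
        ax.legend(ncol=self.K)
        return ax


class AdmixtureModel:
    """Admixture model for a genotype dataset; ``fit`` runs restarted EM."""

    def __init__(self, ds: GenotypeDataset, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.ds = ds
        self.K = K

    def fit(
        self,
        seed: int | None = None,
        tol: float = 1e-6,
        max_iter: int = 2000,
        restarts: int = 3,
    ) -> AdmixtureResult:
        import warnings

        ds, K = self.ds, self.K
        if K > ds.n_samples:
            warnings.warn(
                f"K={K} exceeds the number of samples ({ds.n_samples})",
                stacklevel=2,
            )
        g = ds.genotypes
        best: AdmixtureResult | None = None
        streams = np.random.SeedSequence(seed).spawn(max(restarts, 1))
        for rep, ss in enumerate(streams):
            rng = np.random.default_rng(ss)
            if K == 1:
                # closed form: Q is all ones, F the observed frequencies
                obs = g != MISSING
                n = obs.sum(axis=0)
                cb = np.where(obs, g, 0).sum(axis=0)
                with np.errstate(invalid="ignore", divide="ignore"):
                    f = np.where(n > 0, cb / (2.0 * n), 0.5)
                Q = np.ones((ds.n_samples, 1))
                F = _clamp(f[None, :])
                res = AdmixtureResult(
                    Q=Q, F=F, loglik_trace=[admixture_loglik(g, Q, F)], K=1,
                    seed=seed, n_iter=0, converged=True, samples=list(ds.samples),
                )
            else:
                Q = rng.dirichlet(np.ones(K), size=ds.n_samples)
                F = rng.uniform(0.05, 0.95, size=(K, ds.n_snps))
                obs = g != MISSING
                gf = np.where(obs, g, 0).astype(float)
                comp = np.where(obs, 2.0 - gf, 0.0)
                trace: list[float] = []
                converged = False
                it = 0
                for it in range(1, max_iter + 1):
                    Q, F, ll_prev = _em_step_inner(gf, comp, Q, F)
                    trace.append(ll_prev)
                    if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
                        converged = True
                        break
                trace.append(admixture_loglik(g, Q, F))  # final parameters
                res = AdmixtureResult(
                    Q=Q, F=F, loglik_trace=trace, K=K, seed=seed,
                    n_iter=it, converged=converged, samples=list(ds.samples),
                )
            if best is None or res.loglik > best.loglik:
                best = res
        return best


def fit_admixture(
    ds: GenotypeDataset,
    K: int,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    restarts: int = 3,
) -> AdmixtureResult:
    """Fit ancestry proportions with restarted EM (best likelihood kept)."""
    return AdmixtureModel(ds, K).fit(
        seed=seed, tol=tol, max_iter=max_iter, restarts=restarts
    )


def compare_components_by_region(
    Q: np.ndarray,
    metadata: Sequence[SampleMetadata],
    component: int,
    region_a: str,
    region_b: str,
    samples: Sequence[str] | None = None,
):
    """Per-region means of one ancestry component and a Welch t-test.

    Returns (mean_a, mean_b, p_value); p is NaN when a region has fewer
    than 2 samples.  ``samples`` gives the row order of Q (defaults to
    metadata order).
    """
    ids = list(samples) if samples is not None else [m.sample_id for m in metadata]
    region_of = {m.sample_id: m.region for m in metadata}
    vals = {region_a: [], region_b: []}
    for i, s in enumerate(ids):
        r = region_of.get(s)
        if r in vals:
            vals[r].append(Q[i, component])
    va, vb = np.array(vals[region_a]), np.array(vals[region_b])
    if va.size == 0 or vb.size == 0:
        raise ValueError("both regions must be present in the metadata")
    mean_a, mean_b = float(va.mean()), float(vb.mean())
    if va.size < 2 or vb.size < 2:
        return mean_a, mean_b, float("nan")
    t = stats.ttest_ind(va, vb, equal_var=False)
    return mean_a, mean_b, float(t.pvalue)
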