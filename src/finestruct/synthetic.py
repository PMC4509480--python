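"""Synthetic genotype generators with the statistical structure the
downstream analyses assume.

The differentiation model is Balding-Nichols: an ancestral allele frequency
p is drawn per SNP, and each subpopulation's frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean p and variance
``F * p(1-p)`` — so F is exactly the estimand of the variance-components
F_ST estimator applied downstream.  Genotypes are Binomial(2, subpop
frequency), i.e. Hardy-Weinberg within subpopulations, no linkage
disequilibrium, no relatedness.

Three generators build on this:

* :func:`simulate_balding_nichols` — discrete subpopulations;
* :func:`simulate_cline` — demes on a latitudinal gradient, where each
  deme's frequencies are shifted by ``slope * (latitude - mean latitude)``
  on top of residual Balding-Nichols noise;
* :func:`simulate_case_control` — case/control samples whose subpopulation
  of origin depends on phenotype (the stratification confounder), with an
  optional multiplicative per-allele risk model at causal SNPs.

All randomness flows from a single integer seed via
``numpy.random.SeedSequence`` substreams, so a fixed seed reproduces every
dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genodata import (
    MISSING,
    GenotypeDataset,
    SampleMetadata,
    VariantRecord,
)

__all__ = [
    "BaldingNicholsConfig",
    "ClineConfig",
    "CaseControlConfig",
    "simulate_balding_nichols",
    "simulate_cline",
    "inject_missingness",
    "simulate_case_control",
]

# Regime defaults mirror the study's post-QC data: ~41,400 independent SNPs
# with MAF >= 0.05 and genome-wide regional F_ST of order 1e-3.
DEFAULT_N_SNPS = 41_400
DEFAULT_FST = 0.001
DEFAULT_MAF_RANGE = (0.05, 0.5)


@dataclass
class BaldingNicholsConfig:
    """Configuration for the discrete-subpopulation generator.

    n_per_pop : diploid sample size of each subpopulation.
    fst_true : differentiation parameter F in [0, 1).
    ancestral_maf_range : interval within (0, 0.5] for the ancestral
        frequency (uniform draw).
    missing_rate : per-genotype missingness probability.
    """

    n_per_pop: Sequence[int]
    n_snps: int = DEFAULT_N_SNPS
    fst_true: float = DEFAULT_FST
    ancestral_maf_range: tuple[float, float] = DEFAULT_MAF_RANGE
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_pop) < 1 or any(n < 1 for n in self.n_per_pop):
            raise ValueError("n_per_pop entries must be >= 1")
        fvals = np.atleast_1d(np.asarray(self.fst_true, dtype=float))
        if fvals.size not in (1, len(self.n_per_pop)):
            raise ValueError("fst_true must be a scalar or one value per population")
        if ((fvals < 0.0) | (fvals >= 1.0)).any():
            raise ValueError("fst_true must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


@dataclass
class ClineConfig(BaldingNicholsConfig):
    """Latitudinal-cline generator: one deme per entry of ``latitudes``.

    slope : allele-frequency change per degree latitude.  Frequencies are
        clipped to [0.01, 0.99] after the cline shift.
    states / regions : optional labels per deme for the emitted metadata;
        default deme_1..deme_k with regions assigned by latitude terciles.
    """

    latitudes: Sequence[float] = ()
    slope: float = 0.005
    states: Sequence[str] | None = None
    regions: Sequence[str] | None = None
    longitudes: Sequence[float] | None = None

    @property
    def n_demes(self) -> int:
        return len(self.latitudes)

    def validate(self) -> None:
        super().validate()
        if len(self.latitudes) != len(self.n_per_pop):
            raise ValueError("latitudes must match n_per_pop in length")
        if any(abs(x) > 90 for x in self.latitudes):
            raise ValueError("|latitude| must be <= 90")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass
class CaseControlConfig(BaldingNicholsConfig):
    """Case-control generator with phenotype-dependent subpopulation mixing.

    case_pop_fractions / control_pop_fractions : mixing proportions over the
        subpopulations for cases and controls (each sums to 1).  Unequal
        fractions create population stratification confounding.
    causal_snps : list of (snp index, per-allele relative risk) pairs; risk
        is multiplicative on the odds of disease per copy of allele_b.
    """

    n_cases: int = 1000
    n_controls: int = 1000
    case_pop_fractions: Sequence[float] = ()
    control_pop_fractions: Sequence[float] = ()
    causal_snps: Sequence[tuple[int, float]] = ()
    baseline_prevalence: float = 0.1
    alpha_levels: Sequence[float] = (0.05, 1e-4)

    def validate(self) -> None:
        super().validate()
        k = len(self.n_per_pop)
        for name, frac in (
            ("case_pop_fractions", self.case_pop_fractions),
            ("control_pop_fractions", self.control_pop_fractions),
        ):
            if len(frac) != k:
                raise ValueError(f"{name} must have one entry per subpopulation")
            if abs(sum(frac) - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1 (got {sum(frac)})")
            if any(f < 0 for f in frac):
                raise ValueError(f"{name} entries must be >= 0")
        for j, rr in self.causal_snps:
            if not 0 <= j < self.n_snps:
                raise ValueError(f"causal SNP index {j} out of range")
            if rr <= 0:
                raise ValueError("relative risk must be > 0")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must be in (0, 1)")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _make_variants(n_snps: int) -> list[VariantRecord]:
    width = len(str(n_snps))
    return [
        VariantRecord(f"snp{j + 1:0{width}d}", "1", 10_000 * (j + 1), "A", "C")
        for j in range(n_snps)
    ]


def _draw_subpop_freqs(
    rng: np.random.Generator, p: np.ndarray, fst, n_pops: int
) -> np.ndarray:
    """(n_pops, L) Balding-Nichols frequencies; F=0 degenerates to p.

    ``fst`` may be a scalar (shared drift) or a per-population sequence,
    in which case population k drifts with its own F_k (pairwise
    differentiation is then approximately (F_i + F_j) / 2).
    """
    fst_per_pop = np.broadcast_to(np.asarray(fst, dtype=float), (n_pops,))
    out = np.empty((n_pops, p.size))
    for k, f in enumerate(fst_per_pop):
        if f == 0.0:
            out[k] = p
        else:
            scale = (1.0 - f) / f
            out[k] = rng.beta(p * scale, (1.0 - p) * scale)
    return out


def _genotypes_from_freqs(
    rng: np.random.Generator, pop_of: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Binomial(2, f_pop) genotypes; rows follow ``pop_of`` assignments."""
    return rng.binomial(2, freqs[pop_of, :]).astype(np.int8)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_balding_nichols(cfg: BaldingNicholsConfig):
    """Simulate discrete subpopulations under the Balding-Nichols model.

    Returns ``(dataset, truth)`` where truth records the ancestral
    frequencies, per-subpopulation frequencies, population label of every
    sample, and the configured F.
    """
    cfg.validate()
    r_anc, r_sub, r_geno, r_miss = _substreams(cfg.seed, 4)
    lo, hi = cfg.ancestral_maf_range
    p = r_anc.uniform(lo, hi, size=cfg.n_snps)
    freqs = _draw_subpop_freqs(r_sub, p, cfg.fst_true, len(cfg.n_per_pop))
    pop_of = np.repeat(np.arange(len(cfg.n_per_pop)), cfg.n_per_pop)
    g = _genotypes_from_freqs(r_geno, pop_of, freqs)
    samples = [
        f"pop{k + 1}_s{i + 1:04d}"
        for k, nk in enumerate(cfg.n_per_pop)
        for i in range(nk)
    ]
    ds = GenotypeDataset(samples, _make_variants(cfg.n_snps), g)
    if cfg.missing_rate > 0:
        ds = _inject_missingness_rng(ds, cfg.missing_rate, r_miss)
    truth = {
        "model": "balding_nichols",
        "fst_true": cfg.fst_true,
        "ancestral_freq": p,
        "subpop_freqs": freqs,
        "pop_of_sample": pop_of,
        "seed": cfg.seed,
    }
    return ds, truth


def simulate_cline(cfg: ClineConfig):
    """Simulate demes along a latitudinal allele-frequency cline.

    Each deme's frequencies are the Balding-Nichols draw plus
    ``slope * (latitude - mean latitude)``, clipped to [0.01, 0.99].
    Returns ``(dataset, metadata, truth)``; metadata assigns every sample
    its deme's state/region/latitude (and longitude when configured).
    """
    cfg.validate()
    r_anc, r_sub, r_geno, r_miss = _substreams(cfg.seed, 4)
    lo, hi = cfg.ancestral_maf_range
    p = r_anc.uniform(lo, hi, size=cfg.n_snps)
    base = _draw_subpop_freqs(r_sub, p, cfg.fst_true, cfg.n_demes)
    lats = np.asarray(cfg.latitudes, dtype=float)
    shift = cfg.slope * (lats - lats.mean())
    freqs = np.clip(base + shift[:, None], 0.01, 0.99)

    pop_of = np.repeat(np.arange(cfg.n_demes), cfg.n_per_pop)
    g = _genotypes_from_freqs(r_geno, pop_of, freqs)

    states = list(cfg.states) if cfg.states is not None else [
        f"deme_{k + 1}" for k in range(cfg.n_demes)
    ]
    if cfg.regions is not None:
        regions = list(cfg.regions)
    else:
        # default: latitude terciles, highest third = North
        order = np.argsort(-lats)
        regions = [""] * cfg.n_demes
        third = max(1, cfg.n_demes // 3)
        for rank, k in enumerate(order):
            regions[k] = (
                "North" if rank < third
                else ("South" if rank >= cfg.n_demes - third else "Centre")
            )
    lons = list(cfg.longitudes) if cfg.longitudes is not None else [None] * cfg.n_demes

    samples, metadata = [], []
    counter = 0
    for k, nk in enumerate(cfg.n_per_pop):
        for _ in range(nk):
            counter += 1
            sid = f"s{counter:04d}"
            samples.append(sid)
            metadata.append(
                SampleMetadata(sid, states[k], regions[k], float(lats[k]), lons[k])
            )
    ds = GenotypeDataset(samples, _make_variants(cfg.n_snps), g)
    if cfg.missing_rate > 0:
        ds = _inject_missingness_rng(ds, cfg.missing_rate, r_miss)
    truth = {
        "model": "cline",
        "fst_true": cfg.fst_true,
        "slope": cfg.slope,
        "ancestral_freq": p,
        "deme_freqs": freqs,
        "latitudes": lats,
        "pop_of_sample": pop_of,
        "seed": cfg.seed,
    }
    return ds, metadata, truth


def _inject_missingness_rng(
    ds: GenotypeDataset, rate: float, rng: np.random.Generator
) -> GenotypeDataset:
    g = ds.genotypes.copy()
    mask = rng.random(g.shape) < rate
    g[mask] = MISSING
    return GenotypeDataset(ds.samples, ds.variants, g)


def inject_missingness(ds: GenotypeDataset, rate: float, seed: int) -> GenotypeDataset:
    """Set each genotype missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return ds.copy()
    return _inject_missingness_rng(ds, rate, np.random.default_rng(seed))


def simulate_case_control(cfg: CaseControlConfig, max_attempt_factor: int = 200):
    """Simulate a stratified case-control cohort.

    Each candidate individual's subpopulation is drawn from the
    phenotype-specific mixing fractions and genotypes from that
    subpopulation's Balding-Nichols frequencies.  With causal SNPs the
    disease probability is ``baseline_prevalence * prod(rr^g)`` (capped at
    1) and candidates are rejection-sampled until the configured numbers of
    cases and controls accept; without causal SNPs acceptance is immediate.

    Returns ``(dataset, phenotype, truth)``; phenotype is 1 for cases and
    0 for controls.  truth marks causal vs null SNP indices and records each
    sample's subpopulation.
    """
    cfg.validate()
    r_anc, r_sub, r_assign, r_geno = _substreams(cfg.seed, 4)
    lo, hi = cfg.ancestral_maf_range
    p = r_anc.uniform(lo, hi, size=cfg.n_snps)
    freqs = _draw_subpop_freqs(r_sub, p, cfg.fst_true, len(cfg.n_per_pop))

    causal_idx = np.array([j for j, _ in cfg.causal_snps], dtype=int)
    log_rr = np.log(np.array([rr for _, rr in cfg.causal_snps], dtype=float))

    def _collect(n_needed: int, fractions, want_case: bool):
        rows, pops = [], []
        n_attempts, cap = 0, max_attempt_factor * max(n_needed, 1)
        fractions = np.asarray(fractions, dtype=float)
        batch = max(64, n_needed)
        while len(rows) < n_needed:
            if n_attempts >= cap:
                raise RuntimeError(
                    f"could not sample {n_needed} "
                    f"{'cases' if want_case else 'controls'} in {cap} attempts; "
                    "prevalence/risk configuration is infeasible"
                )
            m = min(batch, cap - n_attempts)
            n_attempts += m
            pop = r_assign.choice(len(fractions), size=m, p=fractions)
            g = _genotypes_from_freqs(r_geno, pop, freqs)
            if causal_idx.size:
                risk = np.minimum(
                    cfg.baseline_prevalence
                    * np.exp(g[:, causal_idx].astype(float) @ log_rr),
                    1.0,
                )
                u = r_assign.random(m)
                accept = (u < risk) if want_case else (u >= risk)
            else:
                accept = np.ones(m, dtype=bool)
            for i in np.nonzero(accept)[0]:
                if len(rows) == n_needed:
                    break
                rows.append(g[i])
                pops.append(pop[i])
        return np.array(rows, dtype=np.int8), np.array(pops)

    g_cases, pop_cases = _collect(cfg.n_cases, cfg.case_pop_fractions, True)
    g_ctrls, pop_ctrls = _collect(cfg.n_controls, cfg.control_pop_fractions, False)

    g = np.vstack([g_cases, g_ctrls])
    phen = np.concatenate(
        [np.ones(cfg.n_cases, dtype=int), np.zeros(cfg.n_controls, dtype=int)]
    )
    samples = [f"case_{i + 1:05d}" for i in range(cfg.n_cases)] + [
        f"ctrl_{i + 1:05d}" for i in range(cfg.n_controls)
    ]
    ds = GenotypeDataset(samples, _make_variants(cfg.n_snps), g)
    is_causal = np.zeros(cfg.n_snps, dtype=bool)
    if causal_idx.size:
        is_causal[causal_idx] = True
    truth = {
        "model": "case_control",
        "fst_true": cfg.fst_true,
        "ancestral_freq": p,
        "subpop_freqs": freqs,
        "pop_of_sample": np.concatenate([pop_cases, pop_ctrls]),
        "causal_snps": list(cfg.causal_snps),
        "is_causal": is_causal,
        "seed": cfg.seed,
    }
    return ds, phen, truth
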