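"""QC filters, exact HWE test, LD pruning and the full chain."""

import numpy as np
import pytest
from scipy.special import gammaln

from finestruct.genodata import MISSING, GenotypeDataset, VariantRecord
from finestruct.qc import (
    QCParams,
    filter_hwe,
    filter_maf,
    filter_sample_missingness,
    filter_snp_missingness,
    hwe_exact_p,
    ld_prune,
    ld_r2,
    run_qc,
)

from .conftest import random_dataset


def make_ds(g, chrom=None):
    g = np.array(g, dtype=np.int8)
    variants = [
        VariantRecord(f"snp{j}", chrom[j] if chrom else "1", 100 * (j + 1), "A", "C")
        for j in range(g.shape[1])
    ]
    return GenotypeDataset([f"s{i}" for i in range(g.shape[0])], variants, g)


def hwe_enumeration_oracle(n_AA, n_Aa, n_aa):
    """Independent log-gamma enumeration of the conditional distribution."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    nA = 2 * n_AA + n_Aa
    rare = min(nA, 2 * n - nA)
    hets = list(range(rare % 2, min(rare, 2 * n - rare) + 1, 2))

    def logprob(het):
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        # P(het | n, rare) up to a constant: n! 2^het / (hom_r! het! hom_c!)
        return (
            het * np.log(2.0)
            - gammaln(hom_r + 1)
            - gammaln(het + 1)
            - gammaln(hom_c + 1)
        )

    lp = np.array([logprob(h) for h in hets])
    pr = np.exp(lp - lp.max())
    pr /= pr.sum()
    obs = hets.index(n_Aa)
    return float(pr[pr <= pr[obs] * (1 + 1e-12)].sum())


class TestMissingnessFilters:
    def test_sample_boundary(self):
        g = np.zeros((3, 100), dtype=np.int8)
        g[0, :11] = MISSING  # 11% -> removed
        g[1, :10] = MISSING  # exactly 10% -> retained
        g[2, 1] = 1
        ds = make_ds(g)
        out, removed = filter_sample_missingness(ds, 0.10)
        assert removed == ["s0"]
        assert out.samples == ["s1", "s2"]

    def test_snp_filters_match_scan_oracle(self, rng):
        ds = random_dataset(rng, 30, 60, missing_rate=0.12)
        out, removed = filter_snp_missingness(ds, 0.10)
        expected = {
            ds.variants[j].snp_id
            for j in range(ds.n_snps)
            if (ds.genotypes[:, j] == MISSING).mean() > 0.10
        }
        assert set(removed) == expected
        assert out.n_snps == ds.n_snps - len(expected)

    def test_sample_filter_matches_scan_oracle(self, rng):
        ds = random_dataset(rng, 40, 50, missing_rate=0.12)
        _, removed = filter_sample_missingness(ds, 0.10)
        expected = {
            ds.samples[i]
            for i in range(ds.n_samples)
            if (ds.genotypes[i] == MISSING).mean() > 0.10
        }
        assert set(removed) == expected

    def test_all_missing_snp_removed(self):
        g = np.zeros((4, 2), dtype=np.int8)
        g[:, 0] = MISSING
        g[1, 1] = 1
        _, removed = filter_snp_missingness(make_ds(g), 0.5)
        assert removed == ["snp0"]


class TestMafFilter:
    def test_boundary(self):
        # 1000 samples: count_b 98 -> MAF .049 removed; 100 -> .05 retained
        g = np.zeros((1000, 2), dtype=np.int8)
        g[:98, 0] = 1
        g[:100, 1] = 1
        out, removed = filter_maf(make_ds(g), 0.05)
        assert removed == ["snp0"]
        assert out.snp_ids == ["snp1"]

    def test_monomorphic_removed(self):
        g = np.zeros((10, 1), dtype=np.int8)
        _, removed = filter_maf(make_ds(g), 0.05)
        assert removed == ["snp0"]

    def test_matches_tally_oracle(self, rng):
        ds = random_dataset(rng, 50, 80, missing_rate=0.05, maf_range=(0.01, 0.5))
        _, removed = filter_maf(ds, 0.05)
        expected = set()
        for j in range(ds.n_snps):
            col = ds.genotypes[:, j]
            m = col != MISSING
            p = col[m].sum() / (2 * m.sum())
            if min(p, 1 - p) < 0.05:
                expected.add(ds.variants[j].snp_id)
        assert set(removed) == expected


class TestHweExact:
    def test_single_configuration(self):
        assert hwe_exact_p(5, 0, 0) == 1.0

    def test_all_het_matches_enumeration(self):
        assert hwe_exact_p(0, 10, 0) == pytest.approx(
            hwe_enumeration_oracle(0, 10, 0), abs=1e-12
        )

    def test_zero_samples(self):
        assert hwe_exact_p(0, 0, 0) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_random_counts_match_enumeration(self, seed):
        r = np.random.default_rng(seed)
        for _ in range(60):
            counts = r.integers(0, 68, size=3)  # n up to ~200
            got = hwe_exact_p(*map(int, counts))
            want = hwe_enumeration_oracle(*map(int, counts))
            assert got == pytest.approx(want, abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_allele_relabel_symmetry(self, rng):
        for _ in range(30):
            a, h, b = map(int, rng.integers(0, 50, size=3))
            assert hwe_exact_p(a, h, b) == pytest.approx(hwe_exact_p(b, h, a), abs=1e-14)


class TestHweFilter:
    def test_extreme_het_removed(self):
        g = np.ones((100, 1), dtype=np.int8)  # all het: p << 0.002
        _, removed = filter_hwe(make_ds(g), 0.002)
        assert removed == ["snp0"]

    def test_matches_per_snp_oracle(self, rng):
        ds = random_dataset(rng, 60, 40, missing_rate=0.05)
        _, removed = filter_hwe(ds, 0.05)
        expected = set()
        for j in range(ds.n_snps):
            col = ds.genotypes[:, j]
            m = col != MISSING
            trip = (int((col[m] == 0).sum()), int((col[m] == 1).sum()),
                    int((col[m] == 2).sum()))
            if hwe_enumeration_oracle(*trip) < 0.05:
                expected.add(ds.variants[j].snp_id)
        assert set(removed) == expected


class TestLdR2:
    def test_identical_columns(self):
        x = np.array([0, 1, 2, 0, 1], dtype=np.int8)
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([0, 1, 2, 0], dtype=np.int8)
        y = np.array([2, 1, 0, 2], dtype=np.int8)
        assert ld_r2(x, y) == pytest.approx(1.0)

    def test_constant_column_flagged_zero(self):
        x = np.zeros(5, dtype=np.int8)
        y = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        assert ld_r2(x, y) == 0.0

    def test_matches_formula_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 3, 30).astype(np.int8)
            y = rng.integers(0, 3, 30).astype(np.int8)
            x[rng.random(30) < 0.1] = MISSING
            y[rng.random(30) < 0.1] = MISSING
            ok = (x != MISSING) & (y != MISSING)
            xs, ys = x[ok].astype(float), y[ok].astype(float)
            if xs.std() == 0 or ys.std() == 0:
                continue
            want = np.corrcoef(xs, ys)[0, 1] ** 2
            assert ld_r2(x, y) == pytest.approx(want, abs=1e-12)


class TestLdPrune:
    def test_duplicate_adjacent_removed(self, rng):
        base = rng.binomial(2, 0.3, size=(40, 1)).astype(np.int8)
        other = rng.binomial(2, 0.3, size=(40, 1)).astype(np.int8)
        ds = make_ds(np.hstack([base, base, other]))
        out, removed = ld_prune(ds, QCParams())
        assert len(removed) == 1
        assert removed[0] in ("snp0", "snp1")

    def test_independent_snps_untouched(self, rng):
        ds = random_dataset(rng, 100, 30)
        out, removed = ld_prune(ds, QCParams())
        assert removed == []
        assert out.n_snps == 30

    def test_matches_greedy_oracle(self, rng):
        # 50 SNPs with planted duplicate/near-duplicate runs
        cols = []
        j = 0
        while j < 50:
            c = rng.binomial(2, rng.uniform(0.2, 0.5), size=(60, 1)).astype(np.int8)
            cols.append(c)
            j += 1
            if rng.random() < 0.3 and j < 50:
                dup = c.copy()
                flip = rng.random(60) < 0.05
                dup[flip, 0] = rng.integers(0, 3, flip.sum()).astype(np.int8)
                cols.append(dup)
                j += 1
        g = np.hstack(cols)
        ds = make_ds(g)
        params = QCParams(ld_window=10, ld_step=3)
        _, removed = ld_prune(ds, params)

        # exhaustive greedy oracle: same window walk, quadratic scans
        maf = ds.maf()
        gone = set()
        start = 0
        n = ds.n_snps
        while True:
            stop = min(start + params.ld_window, n)
            idx = [j for j in range(start, stop) if j not in gone]
            changed = True
            while changed:
                changed = False
                for ai in range(len(idx)):
                    for bi in range(ai + 1, len(idx)):
                        a, b = idx[ai], idx[bi]
                        if a in gone or b in gone:
                            continue
                        if ld_r2(g[:, a], g[:, b]) > params.ld_r2_max:
                            drop = b if maf[b] <= maf[a] else a
                            gone.add(drop)
                            idx = [x for x in idx if x != drop]
                            changed = True
                            break
                    if changed:
                        break
            if stop == n:
                break
            start += params.ld_step
        expected = {ds.variants[j].snp_id for j in gone}
        assert set(removed) == expected


class TestRunQc:
    def test_clean_dataset_untouched(self, rng):
        ds = random_dataset(rng, 80, 40, maf_range=(0.2, 0.5))
        out, report = run_qc(ds)
        for stage in report.stages:
            assert stage.removed_samples == 0 and stage.removed_snps == 0
        assert out.n_snps == 40 and out.n_samples == 80

    def test_planted_violations_counted_once_each(self):
        rng = np.random.default_rng(99)
        n = 200
        base = rng.binomial(2, 0.3, size=(n, 8)).astype(np.int8)
        g = base.copy()
        # snp8: >10% missing
        miss = rng.binomial(2, 0.3, size=(n, 1)).astype(np.int8)
        miss[: int(0.15 * n)] = MISSING
        # snp9: rare (MAF ~ 0.01)
        rare = np.zeros((n, 1), dtype=np.int8)
        rare[:4] = 1
        # snp10: all het -> HWE failure
        het = np.ones((n, 1), dtype=np.int8)
        # snp11: duplicate of snp0 -> LD prune
        dup = base[:, [0]].copy()
        g = np.hstack([g, miss, rare, het, dup])
        # sample with 20% missing
        g[0, rng.choice(g.shape[1], size=max(3, int(0.2 * g.shape[1])),
                        replace=False)] = MISSING
        ds = make_ds(g)
        out, report = run_qc(ds)
        by_name = {s.name: s for s in report.stages}
        assert by_name["sample_missingness"].removed_samples == 1
        assert by_name["snp_missingness"].removed_snps == 1
        assert by_name["maf"].removed_snps == 1
        assert by_name["hwe"].removed_snps == 1
        assert by_name["ld_prune"].removed_snps == 1
        assert out.n_samples == n - 1 and out.n_snps == 8 + 4 - 4

    def test_idempotent(self, rng):
        ds = random_dataset(rng, 60, 50, missing_rate=0.08)
        once, _ = run_qc(ds)
        twice, report2 = run_qc(once)
        assert twice.equals(once)
        for stage in report2.stages:
            assert stage.removed_samples == 0 and stage.removed_snps == 0
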