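"""Core data model and I/O for diploid biallelic SNP genotypes.

Genotypes are stored as an ``int8`` matrix of counts of ``allele_b`` per
individual (0, 1 or 2), with :data:`MISSING` (-1) marking an untyped call.
``allele_b`` is, by convention, the dataset-wide minor allele (ties broken
lexicographically), so genotype codes count copies of the minor allele —
the orientation used throughout the differentiation analyses.

I/O covers PLINK text PED/MAP and a delimited sample-metadata table
(sample_id, state, region, latitude[, longitude]).  A packaged lookup maps
each Peninsular Malaysian state (plus Singapore) to its region
(North/Centre/South) and latitude in decimal degrees.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
REGIONS = ("North", "Centre", "South")

__all__ = [
    "MISSING",
    "REGIONS",
    "VariantRecord",
    "GenotypeDataset",
    "SampleMetadata",
    "AlleleCounts",
    "PedFormatError",
    "IncompatibleSiteError",
    "read_ped_map",
    "write_ped_map",
    "read_metadata",
    "merge_datasets",
    "allele_counts",
    "state_reference",
    "state_to_region",
    "load_reference_differentiated_snps",
]


class PedFormatError(ValueError):
    """Raised for malformed PED/MAP input (ragged lines, >2 alleles)."""


class IncompatibleSiteError(ValueError):
    """Raised when datasets disagree on a site's allele pair beyond a swap."""

    def __init__(self, snp_ids: Sequence[str]):
        self.snp_ids = list(snp_ids)
        super().__init__(
            "incompatible allele pairs at: " + ", ".join(self.snp_ids)
        )


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic site. ``allele_b`` is the counted (minor) allele."""

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: allele_a == allele_b")
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    state: str
    region: str
    latitude: float
    longitude: float | None = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(
                f"{self.sample_id}: unknown region {self.region!r}; "
                f"expected one of {REGIONS}"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(
                f"{self.sample_id}: latitude {self.latitude} out of [-90, 90]"
            )


@dataclass(frozen=True)
class AlleleCounts:
    """Per-SNP counts over a sample subset (non-missing genotypes only)."""

    n_genotyped: int
    count_b: int
    count_het: int

    def __post_init__(self):
        if self.count_b > 2 * self.n_genotyped:
            raise ValueError("count_b exceeds 2*n_genotyped")
        if self.count_het > self.n_genotyped:
            raise ValueError("count_het exceeds n_genotyped")
        if self.count_het > self.count_b or self.count_het > 2 * self.n_genotyped - self.count_b:
            raise ValueError("count_het inconsistent with count_b")

    @property
    def freq_b(self) -> float:
        """Frequency of allele_b; NaN when no genotyped samples."""
        if self.n_genotyped == 0:
            return float("nan")
        return self.count_b / (2 * self.n_genotyped)

    @property
    def het_freq(self) -> float:
        if self.n_genotyped == 0:
            return float("nan")
        return self.count_het / self.n_genotyped


class GenotypeDataset:
    """Samples x variants genotype matrix with variant records.

    Parameters
    ----------
    samples : sequence of str
        Unique sample identifiers, row order of ``genotypes``.
    variants : sequence of VariantRecord
        Column order of ``genotypes``; snp_ids must be unique.
    genotypes : array-like of int
        Counts of ``allele_b`` in {0,1,2}, or :data:`MISSING`.
    """

    def __init__(self, samples, variants, genotypes):
        self.samples: list[str] = list(samples)
        self.variants: list[VariantRecord] = list(variants)
        g = np.asarray(genotypes, dtype=np.int8)
        if g.ndim != 2 or g.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {g.shape} does not match "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2} or MISSING")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_ids")
        self.genotypes: np.ndarray = g
        self._snp_index = {v.snp_id: j for j, v in enumerate(self.variants)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self._snp_index[snp_id]
        except KeyError:
            raise KeyError(f"unknown snp_id: {snp_id}") from None

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [v.snp_id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "allele_a": [v.allele_a for v in self.variants],
                "allele_b": [v.allele_b for v in self.variants],
            }
        )

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def sample_rows(self, sample_ids: Iterable[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([index[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample ID: {e.args[0]}") from None

    # -- statistics ----------------------------------------------------------
    def allele_freq(self, sample_rows: np.ndarray | None = None) -> np.ndarray:
        """Per-SNP frequency of allele_b over non-missing genotypes."""
        g = self.genotypes if sample_rows is None else self.genotypes[sample_rows]
        valid = g != MISSING
        n = valid.sum(axis=0)
        count_b = np.where(valid, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, count_b / (2.0 * n), np.nan)

    def maf(self, sample_rows: np.ndarray | None = None) -> np.ndarray:
        p = self.allele_freq(sample_rows)
        return np.minimum(p, 1.0 - p)

    # -- subsetting ----------------------------------------------------------
    def subset_samples(self, sample_ids: Iterable[str]) -> "GenotypeDataset":
        rows = self.sample_rows(sample_ids)
        return GenotypeDataset(
            [self.samples[i] for i in rows], self.variants, self.genotypes[rows]
        )

    def subset_variants(self, keep: Sequence[int] | Sequence[str]) -> "GenotypeDataset":
        if len(keep) and isinstance(keep[0], str):
            cols = np.array([self.snp_index(s) for s in keep], dtype=int)
        else:
            cols = np.asarray(keep, dtype=int)
        return GenotypeDataset(
            self.samples, [self.variants[j] for j in cols], self.genotypes[:, cols]
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(self.samples, self.variants, self.genotypes.copy())

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.samples == other.samples
            and self.variants == other.variants
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def __repr__(self) -> str:
        return f"<GenotypeDataset {self.n_samples} samples x {self.n_snps} SNPs>"


# ---------------------------------------------------------------------------
# PED/MAP I/O
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> GenotypeDataset:
    """Read PLINK text PED/MAP into a :class:`GenotypeDataset`.

    ``allele_b`` is assigned per site as the dataset-wide minor allele
    (lexicographically first on a 50/50 tie); "0 0" genotypes become
    missing.  A site with more than two observed alleles raises
    :class:`PedFormatError`.
    """
    variants_raw = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (3, 4):
                raise PedFormatError(f"{map_path}: line {ln}: expected 3-4 fields")
            chrom, snp_id = fields[0], fields[1]
            pos = int(fields[-1])
            variants_raw.append((snp_id, chrom, pos))
    n_snps = len(variants_raw)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PedFormatError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])

    n = len(sample_ids)
    genotypes = np.full((n, n_snps), MISSING, dtype=np.int8)
    variants: list[VariantRecord] = []
    for j, (snp_id, chrom, pos) in enumerate(variants_raw):
        counts: dict[str, int] = {}
        for row in allele_rows:
            for a in (row[2 * j], row[2 * j + 1]):
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        if len(counts) > 2:
            raise PedFormatError(
                f"{ped_path}: site {snp_id} has {len(counts)} alleles: "
                + ",".join(sorted(counts))
            )
        if len(counts) == 2:
            # minor allele -> allele_b; lexicographic tie-break
            (a1, c1), (a2, c2) = sorted(counts.items())
            if c1 <= c2:
                allele_b, allele_a = a1, a2
            else:
                allele_b, allele_a = a2, a1
        elif len(counts) == 1:
            allele_a = next(iter(counts))
            allele_b = "0"  # placeholder: monomorphic, no minor allele observed
        else:
            allele_a, allele_b = "0", "N"  # fully missing column
        variants.append(VariantRecord(snp_id, chrom, pos, allele_a, allele_b))
        for i, row in enumerate(allele_rows):
            x, y = row[2 * j], row[2 * j + 1]
            if x == "0" or y == "0":
                continue
            genotypes[i, j] = (x == allele_b) + (y == allele_b)
    return GenotypeDataset(sample_ids, variants, genotypes)


def write_ped_map(ds: GenotypeDataset, ped_path, map_path) -> None:
    """Write PED/MAP re-readable by :func:`read_ped_map` (code round-trip)."""
    with open(map_path, "w") as fh:
        for v in ds.variants:
            fh.write(f"{v.chrom}\t{v.snp_id}\t0\t{v.pos}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(ds.samples):
            fields = [sid, sid, "0", "0", "0", "0"]
            for j, v in enumerate(ds.variants):
                g = ds.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [v.allele_a, v.allele_a]
                elif g == 1:
                    fields += [v.allele_a, v.allele_b]
                else:
                    fields += [v.allele_b, v.allele_b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> list[SampleMetadata]:
    """Read a delimited metadata table with a header.

    Required columns: sample_id, state, region, latitude; optional longitude.
    Region labels are validated against {North, Centre, South} and latitudes
    against [-90, 90] (both enforced by :class:`SampleMetadata`).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sample_id", "state", "region", "latitude"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"{path}: missing columns {sorted(missing_cols)}")
    out = []
    for rec in df.to_dict("records"):
        lat = float(rec["latitude"])
        lon = rec.get("longitude")
        lon = None if lon is None or pd.isna(lon) else float(lon)
        out.append(
            SampleMetadata(
                sample_id=str(rec["sample_id"]),
                state=str(rec["state"]),
                region=str(rec["region"]),
                latitude=lat,
                longitude=lon,
            )
        )
    return out


def write_metadata(records: Sequence[SampleMetadata], path) -> None:
    df = metadata_frame(records)
    df.to_csv(path, sep="\t", index=False)


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in records],
            "state": [m.state for m in records],
            "region": [m.region for m in records],
            "latitude": [m.latitude for m in records],
            "longitude": [m.longitude for m in records],
        }
    )


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return importlib.resources.files("finestruct.data").joinpath(name)


def state_reference() -> pd.DataFrame:
    """Reference table of Peninsular Malaysian states (plus Singapore).

    Columns: state, region (North/Centre/South), latitude (decimal degrees),
    n_subjects (post-QC study sample counts; a single printed count of 7
    spans Perlis/Kedah/Pulau Pinang and is recorded on the Perlis row, the
    other two left missing, mirroring the source table).
    """
    with importlib.resources.as_file(_data_path("state_latitudes.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def state_to_region() -> dict[str, str]:
    df = state_reference()
    return dict(zip(df["state"], df["region"]))


def load_reference_differentiated_snps() -> pd.DataFrame:
    """Published reference list of SNPs highly differentiated between
    northern and southern Peninsular Malaysian Malays.

    Columns: snp_id, chrom, pos, minor_allele, fst (Weir-Cockerham theta),
    maf_north, maf_south (each region's own minor-allele frequency), gene,
    category.  Rows are sorted by descending fst; all printed rows have
    fst >= 0.05.
    """
    with importlib.resources.as_file(
        _data_path("differentiated_snps_north_south.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# Merge + counts
# ---------------------------------------------------------------------------

def merge_datasets(datasets: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Merge >=2 datasets on the intersection of their snp_ids.

    Sample lists are concatenated (must be disjoint); allele codes are
    harmonized: when a later dataset has allele_a/allele_b exchanged at a
    site its codes are flipped (g -> 2-g).  An allele pair that differs
    beyond a swap raises :class:`IncompatibleSiteError`.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets to merge")
    all_ids = [s for ds in datasets for s in ds.samples]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("sample IDs must be disjoint across datasets")

    first = datasets[0]
    shared = [
        s
        for s in first.snp_ids
        if all(s in ds._snp_index for ds in datasets[1:])
    ]
    ref = {s: first.variants[first.snp_index(s)] for s in shared}

    bad: list[str] = []
    blocks: list[np.ndarray] = []
    for ds in datasets:
        cols = np.array([ds.snp_index(s) for s in shared], dtype=int)
        g = ds.genotypes[:, cols].copy()
        for k, s in enumerate(shared):
            v, rv = ds.variants[ds.snp_index(s)], ref[s]
            pair, rpair = {v.allele_a, v.allele_b}, {rv.allele_a, rv.allele_b}
            # "0" marks a monomorphic placeholder: only the observed allele
            # needs to be consistent
            if "0" in pair or "0" in rpair:
                obs = pair - {"0"}
                robs = rpair - {"0"}
                if obs and robs and not (obs & rpair or robs & pair):
                    bad.append(s)
                continue
            if pair != rpair:
                bad.append(s)
            elif (v.allele_a, v.allele_b) != (rv.allele_a, rv.allele_b):
                m = g[:, k] != MISSING
                g[m, k] = 2 - g[m, k]
        blocks.append(g)
    if bad:
        raise IncompatibleSiteError(sorted(set(bad)))
    return GenotypeDataset(all_ids, [ref[s] for s in shared], np.vstack(blocks))


def allele_counts(
    ds: GenotypeDataset, sample_subset: Iterable[str], snp_id: str
) -> AlleleCounts:
    """Tally allele_b copies and heterozygotes over non-missing genotypes."""
    rows = ds.sample_rows(sample_subset)
    if rows.size == 0:
        raise ValueError("sample_subset must be non-empty")
    col = ds.genotypes[rows, ds.snp_index(snp_id)]
    valid = col != MISSING
    return AlleleCounts(
        n_genotyped=int(valid.sum()),
        count_b=int(col[valid].sum()),
        count_het=int((col == 1).sum()),
    )
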