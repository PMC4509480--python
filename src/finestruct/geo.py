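"""Genetic-geographic correlation: PC scores versus latitude/longitude and
pairwise F_ST versus great-circle distance.

The default analysis unit for the latitude correlation is the state-level
mean PC1 (one point per sampling location, matching the small-n regime in
which such clines are usually reported); a per-sample mode is available.
For F_ST-versus-distance a simple Pearson correlation over unordered pairs
is reported, with an optional Mantel permutation p-value alongside — pairs
sharing a population are not independent, so the parametric p is
anti-conservative and the permutation test is the honest alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import SampleMetadata
from .pca import PCAResult, average_pc_by_group

__all__ = [
    "CorrelationResult",
    "pearson_correlation",
    "pc_vs_latitude",
    "haversine_km",
    "fst_vs_distance",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p_value: float
    n: int
    mantel_p: float | None = None

    def summary(self) -> str:
        s = (
            f"Pearson r = {self.r:.4f} (r^2 = {self.r_squared:.4f}), "
            f"two-sided P = {self.p_value:.4g}, n = {self.n}"
        )
        if self.mantel_p is not None:
            s += f"; Mantel permutation P = {self.mantel_p:.4g}"
        return s


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 for a defined p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(
        r=r, r_squared=r * r, p_value=float(res.pvalue), n=int(x.size)
    )


def pc_vs_latitude(
    result: PCAResult,
    metadata: Sequence[SampleMetadata],
    axis: str = "latitude",
    pc_index: int = 0,
    unit: str = "state",
) -> CorrelationResult:
    """Correlate a PC with a geographic coordinate.

    ``unit='state'`` (default) correlates per-state mean PC scores with the
    state coordinate; ``unit='sample'`` correlates per-sample scores.
    ``axis`` is 'latitude' or 'longitude'; all units must have the
    coordinate available.
    """
    if axis not in ("latitude", "longitude"):
        raise ValueError("axis must be 'latitude' or 'longitude'")
    meta = {m.sample_id: m for m in metadata}
    missing = [s for s in result.samples if s not in meta]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing[:5]}")

    def coord(m: SampleMetadata) -> float:
        v = getattr(m, axis)
        if v is None or not np.isfinite(v):
            raise ValueError(f"{m.sample_id}: missing {axis}")
        return float(v)

    if unit == "sample":
        x = np.array([coord(meta[s]) for s in result.samples])
        y = result.pc_scores[:, pc_index]
        return pearson_correlation(x, y)
    if unit != "state":
        raise ValueError("unit must be 'state' or 'sample'")
    means = average_pc_by_group(result, metadata, pc_index=pc_index, by="state")
    state_coord: dict[str, float] = {}
    for m in meta.values():
        state_coord[m.state] = coord(m)
    x = np.array([state_coord[g] for g in means["group"]])
    return pearson_correlation(x, means["mean"].to_numpy())


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on a spherical Earth (radius 6371 km)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def fst_vs_distance(
    fst_matrix: pd.DataFrame,
    coordinates: Mapping[str, tuple[float, float]],
    mantel_permutations: int = 0,
    seed: int | None = None,
) -> CorrelationResult:
    """Correlate pairwise F_ST with pairwise great-circle distance.

    ``fst_matrix`` is a symmetric group-by-group DataFrame (as produced by
    ``fst.point_matrix``); ``coordinates`` maps group -> (lat, lon).
    Reports the simple Pearson correlation over the n(n-1)/2 unordered
    pairs; with ``mantel_permutations`` > 0 a Mantel permutation p-value is
    attached.
    """
    names = [g for g in fst_matrix.index if g in coordinates]
    if len(names) < 3:
        raise ValueError("need >= 3 groups with coordinates")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    f = np.array([fst_matrix.loc[a, b] for a, b in pairs], dtype=float)
    d = np.array(
        [haversine_km(*coordinates[a], *coordinates[b]) for a, b in pairs]
    )
    base = pearson_correlation(d, f)
    if mantel_permutations <= 0:
        return base
    # Mantel: permute group labels of one matrix, recompute pair correlation
    rng = np.random.default_rng(seed)
    k = len(names)
    fmat = fst_matrix.loc[names, names].to_numpy(dtype=float)
    iu = np.triu_indices(k, 1)
    dmat = np.zeros((k, k))
    for i, a in enumerate(names):
        for j in range(i + 1, k):
            dmat[i, j] = dmat[j, i] = haversine_km(
                *coordinates[a], *coordinates[names[j]]
            )
    obs = base.r
    hits = 0
    for _ in range(mantel_permutations):
        perm = rng.permutation(k)
        fp = fmat[np.ix_(perm, perm)][iu]
        r = np.corrcoef(dmat[iu], fp)[0, 1]
        if abs(r) >= abs(obs) - 1e-12:
            hits += 1
    mantel_p = (hits + 1) / (mantel_permutations + 1)
    return CorrelationResult(
        r=base.r, r_squared=base.r_squared, p_value=base.p_value,
        n=base.n, mantel_p=float(mantel_p),
    )
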