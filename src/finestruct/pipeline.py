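"""End-to-end pipeline orchestration: simulate/ingest -> QC -> PCA ->
admixture -> F_ST -> geographic correlation -> report, with per-stage
manifests recording inputs, parameters and seeds for reproducibility."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fst as fst_mod
from .admixture import fit_admixture
from .genodata import (
    GenotypeDataset,
    metadata_frame,
    read_metadata,
    read_ped_map,
    write_ped_map,
)
from .geo import pc_vs_latitude
from .pca import average_pc_by_group, compute_pca
from .qc import QCParams, run_qc
from .synthetic import ClineConfig, simulate_cline

logger = logging.getLogger("finestruct")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records completed stages."""


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Either ``ped``/``map``/``metadata`` paths or a ``simulate`` ClineConfig
    must be given.  The global seed is fanned out to every stochastic stage
    and recorded in each stage manifest.
    """

    out_dir: str
    seed: int = 0
    ped: str | None = None
    map: str | None = None
    metadata: str | None = None
    simulate: ClineConfig | None = None
    qc_params: QCParams = field(default_factory=QCParams)
    pca_k: int = 10
    admixture_K: tuple[int, ...] = (2,)
    admixture_max_iter: int = 2000
    admixture_restarts: int = 3
    fst_group_by: str = "region"
    fst_n_boot: int = 1000
    geo_axis: str = "latitude"

    def validate(self) -> None:
        problems = []
        has_files = self.ped or self.map or self.metadata
        if has_files and self.simulate is not None:
            problems.append("give either input files or a simulation config, not both")
        if not has_files and self.simulate is None:
            problems.append("one of (ped, map, metadata) or simulate is required")
        if has_files:
            for name in ("ped", "map", "metadata"):
                p = getattr(self, name)
                if p is None:
                    problems.append(f"missing path: {name}")
                elif not Path(p).exists():
                    problems.append(f"{name} file not found: {p}")
        if self.pca_k < 1:
            problems.append("pca_k must be >= 1")
        if any(k < 1 for k in self.admixture_K):
            problems.append("admixture K values must be >= 1")
        if problems:
            raise ValueError("invalid pipeline config: " + "; ".join(problems))


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages, writing outputs and a manifest under ``cfg.out_dir``.

    Returns the manifest dict.  A stage failure raises
    :class:`PipelineError` after writing the partial manifest.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": []}
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    stage_seed = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in seeds]

    def stage(name: str, fn):
        t0 = time.time()
        try:
            info = fn() or {}
        except Exception as e:
            _write_json(out / "manifest.json", manifest)
            raise PipelineError(f"stage {name!r} failed: {e}") from e
        entry = {"stage": name, "seconds": round(time.time() - t0, 3), **info}
        manifest["stages"].append(entry)
        logger.info("stage %s done in %.2fs", name, entry["seconds"])
        return entry

    state: dict = {}

    def do_input():
        if cfg.simulate is not None:
            sim_cfg = cfg.simulate
            sim_cfg.seed = stage_seed[0]
            ds, meta, truth = simulate_cline(sim_cfg)
            write_ped_map(ds, out / "input.ped", out / "input.map")
            metadata_frame(meta).to_csv(out / "metadata.tsv", sep="\t", index=False)
            state["ds"], state["meta"] = ds, meta
            return {"source": "simulation", "seed": sim_cfg.seed,
                    "n_samples": ds.n_samples, "n_snps": ds.n_snps}
        ds = read_ped_map(cfg.ped, cfg.map)
        meta = read_metadata(cfg.metadata)
        state["ds"], state["meta"] = ds, meta
        return {"source": "files", "ped": cfg.ped, "map": cfg.map,
                "n_samples": ds.n_samples, "n_snps": ds.n_snps}

    def do_qc():
        ds, report = run_qc(state["ds"], cfg.qc_params)
        state["ds"] = ds
        write_ped_map(ds, out / "qc.ped", out / "qc.map")
        _write_json(out / "qc_report.json", report.as_dict())
        return {"final_samples": ds.n_samples, "final_snps": ds.n_snps,
                "report": "qc_report.json"}

    def do_pca():
        res = compute_pca(state["ds"], k=min(cfg.pca_k,
                                             state["ds"].n_samples - 1,
                                             state["ds"].n_snps))
        state["pca"] = res
        res.scores_frame().to_csv(out / "pca_scores.tsv", sep="\t", index=False)
        pd.DataFrame({"eigenvalue": res.eigenvalues}).to_csv(
            out / "pca_eigenvalues.tsv", sep="\t", index=False
        )
        return {"k": res.k}

    def do_admixture():
        fits = {}
        for K in cfg.admixture_K:
            r = fit_admixture(state["ds"], K, seed=stage_seed[1],
                              max_iter=cfg.admixture_max_iter,
                              restarts=cfg.admixture_restarts)
            r.q_frame().to_csv(out / f"admixture_Q_K{K}.tsv", sep="\t", index=False)
            fits[K] = r
        state["admixture"] = fits
        return {"K": list(cfg.admixture_K),
                "loglik": {str(K): fits[K].loglik for K in fits}}

    def do_fst():
        grouping = {m.sample_id: getattr(m, cfg.fst_group_by)
                    for m in state["meta"]}
        grouping = {s: grouping[s] for s in state["ds"].samples}
        pairs = fst_mod.pairwise_fst_matrix(
            state["ds"], grouping, n_boot=cfg.fst_n_boot, seed=stage_seed[2]
        )
        state["fst_pairs"] = pairs
        pairs.to_csv(out / "fst_pairs.tsv", sep="\t", index=False)
        return {"n_pairs": len(pairs), "n_boot": cfg.fst_n_boot,
                "seed": stage_seed[2]}

    def do_geo():
        corr = pc_vs_latitude(state["pca"], state["meta"], axis=cfg.geo_axis)
        state["geo"] = corr
        _write_json(out / "geo_correlation.json", {
            "axis": cfg.geo_axis, "r": corr.r, "r_squared": corr.r_squared,
            "p_value": corr.p_value, "n": corr.n,
        })
        return {"axis": cfg.geo_axis, "r_squared": corr.r_squared,
                "p_value": corr.p_value}

    stage("input", do_input)
    stage("qc", do_qc)
    stage("pca", do_pca)
    stage("admixture", do_admixture)
    stage("fst", do_fst)
    stage("geo", do_geo)

    report_text = make_report(state, manifest)
    (out / "report.md").write_text(report_text)
    manifest["stages"].append({"stage": "report", "path": "report.md"})
    _write_json(out / "manifest.json", manifest)
    return manifest


def make_report(state: dict, manifest: dict | None = None) -> str:
    """Human-readable summary of the stage outputs."""
    lines = ["# Population-structure analysis report", ""]
    ds = state.get("ds")
    if ds is not None:
        lines += [f"Final dataset: {ds.n_samples} samples x {ds.n_snps} SNPs", ""]
    pairs = state.get("fst_pairs")
    lines.append("## Pairwise F_ST")
    if pairs is None or len(pairs) == 0:
        lines.append("_absent_")
    else:
        m = fst_mod.point_matrix(pairs)
        lines.append(m.to_string(float_format=lambda v: f"{v:.6f}"))
    lines.append("")
    lines.append("## PC1 vs geography")
    corr = state.get("geo")
    if corr is None:
        lines.append("_absent_")
    else:
        lines.append(corr.summary())
    lines.append("")
    lines.append("## Admixture")
    fits = state.get("admixture")
    if not fits:
        lines.append("_absent_")
    else:
        meta = state.get("meta")
        for K, r in fits.items():
            lines.append(f"K={K}: loglik {r.loglik:.1f}, "
                         f"{'converged' if r.converged else 'not converged'}")
            if meta is not None:
                region_of = {m.sample_id: m.region for m in meta}
                labels = [region_of.get(s, "?") for s in r.samples]
                df = pd.DataFrame(r.Q, index=labels)
                lines.append(
                    df.groupby(level=0).mean().to_string(
                        float_format=lambda v: f"{v:.3f}"
                    )
                )
    lines.append("")
    return "\n".join(lines)
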