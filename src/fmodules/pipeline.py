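"""End-to-end orchestration: read -> filter -> decompose -> members -> stats.

A :class:`PipelineConfig` captures every tunable of the workflow; the
serialized config plus the master seed is written into a provenance block
alongside every output so any bundle can be regenerated exactly.  Stage
seeds derive deterministically from the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .compare import overlap, sankey_links
from .dimensions import scan_dimensions, select_optimal
from .ica import decompose, default_min_size
from .matrix import FitnessMatrix, ModuleSet
from .membership import DEFAULT_K2_CUTOFF, ModuleMembership, call_all
from .stats import explained_variance, multiplicity

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "export_module_db"]

log = logging.getLogger("fmodules")


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: str | None = None
    dialect: str = "plain_matrix"
    dimension: int | None = None  # None -> scan
    scan_dims: list[int] = field(default_factory=list)
    n_runs: int = 100
    tol: float = 1e-7
    eps: float = 0.1
    min_cluster: int | None = None  # None -> 50-of-100 scaling
    sign_mode: str = "absolute"
    k2_cutoff: float | str = DEFAULT_K2_CUTOFF  # "auto" -> calibrated
    r_threshold: float = 0.7
    scan_runs: int | None = None  # reduced ensemble during the scan
    seed: int = 0
    output_dir: str = "results"
    compare_modules_path: str | None = None

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.tol <= 0 or self.eps <= 0:
            raise ValueError("tol and eps must be positive")
        if isinstance(self.k2_cutoff, str):
            if self.k2_cutoff != "auto":
                raise ValueError(f"unknown k2_cutoff mode {self.k2_cutoff!r}")
        elif self.k2_cutoff <= 0:
            raise ValueError("k2_cutoff must be positive")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if self.dimension is None and not self.scan_dims:
            raise ValueError("set a dimension or a scan grid")
        if self.seed is None:
            raise ValueError("stochastic stages require an explicit seed")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        offsets = {"scan": 101, "decompose": 211, "simulate": 307}
        return (int(self.seed) * 1009 + offsets.get(stage, 0)) % (2**31 - 1)


@dataclass
class PipelineResult:
    F: FitnessMatrix
    decomposition: object
    modules: ModuleSet
    memberships: list[ModuleMembership]
    variance: object
    multiplicity: object
    chosen_dimension: int
    scan: object | None
    overlap_table: object | None
    config: PipelineConfig


def run_pipeline(
    config: PipelineConfig, F: FitnessMatrix | None = None
) -> PipelineResult:
    """Execute the full workflow and write the output bundle.

    ``F`` may be passed directly (already in memory); otherwise it is read
    from ``config.input_path``.  Outputs: M.tsv, A.tsv, members.tsv,
    k2_trace.tsv, table1.tsv, multiplicity.tsv, provenance.json and, when a
    scan ran, scan.tsv; when a comparison set is given, overlap.tsv and
    sankey.tsv.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    if F is None:
        if config.input_path is None:
            raise ValueError("no fitness matrix given")
        F = fio.read_fitness_table(config.input_path, dialect=config.dialect)
    log.info("input matrix: %d genes x %d samples", *F.shape)
    F = fio.filter_complete_genes(F)
    log.info("complete-case genes: %d", F.n_genes)

    scan = None
    if config.dimension is not None:
        k = config.dimension
        if k > F.n_samples:
            raise ValueError(
                f"dimension {k} exceeds sample count {F.n_samples}"
            )
    else:
        scan = scan_dimensions(
            F,
            config.scan_dims,
            n_runs=config.scan_runs or config.n_runs,
            tol=config.tol,
            base_seed=config.stage_seed("scan"),
            eps=config.eps,
            min_size=config.min_cluster,
            sign_mode=config.sign_mode,
            k2_cutoff=config.k2_cutoff,
            r_threshold=config.r_threshold,
        )
        k = select_optimal(scan)
        scan.to_frame().to_csv(outdir / "scan.tsv", sep="\t", index=False)
        log.info("dimension scan chose k=%d", k)

    dec = decompose(
        F,
        k,
        n_runs=config.n_runs,
        tol=config.tol,
        base_seed=config.stage_seed("decompose"),
        eps=config.eps,
        min_size=config.min_cluster,
        sign_mode=config.sign_mode,
    )
    log.info(
        "robust decomposition: %d components at k=%d (%.1fs)",
        dec.n_components,
        k,
        time.perf_counter() - t0,
    )

    modules, memberships = call_all(
        dec.M, dec.gene_ids, cutoff=config.k2_cutoff
    )
    var = explained_variance(F, dec.M, module_ids=modules.module_ids)
    mult = multiplicity(modules)

    overlap_table = None
    if config.compare_modules_path:
        other = fio.read_module_set(config.compare_modules_path)
        overlap_table = overlap(modules, other)

    _write_bundle(
        outdir, F, dec, modules, memberships, var, mult, k, config,
        overlap_table,
    )
    return PipelineResult(
        F=F,
        decomposition=dec,
        modules=modules,
        memberships=memberships,
        variance=var,
        multiplicity=mult,
        chosen_dimension=k,
        scan=scan,
        overlap_table=overlap_table,
        config=config,
    )


def _provenance(config: PipelineConfig, extra: dict) -> dict:
    prov = {"config": asdict(config), "seed": config.seed}
    prov.update(extra)
    return prov


def _write_bundle(
    outdir, F, dec, modules, memberships, var, mult, k, config, overlap_table
):
    module_ids = modules.module_ids
    pd.DataFrame(dec.M, index=F.gene_ids, columns=module_ids).rename_axis(
        "gene_id"
    ).to_csv(outdir / "M.tsv", sep="\t", float_format="%.17g")
    pd.DataFrame(dec.A, index=module_ids, columns=F.sample_ids).rename_axis(
        "module_id"
    ).to_csv(outdir / "A.tsv", sep="\t", float_format="%.17g")

    member_rows, trace_rows = [], []
    for mm in memberships:
        for g, w, s in mm.members:
            member_rows.append(
                {
                    "module_id": mm.module_id,
                    "gene_id": g,
                    "weight": w,
                    "sign": "+" if s > 0 else "-",
                }
            )
        for g, stat in mm.k2_trace:
            trace_rows.append(
                {
                    "module_id": mm.module_id,
                    "removed_gene": g,
                    "k2_after_removal": stat,
                }
            )
    pd.DataFrame(
        member_rows, columns=["module_id", "gene_id", "weight", "sign"]
    ).to_csv(outdir / "members.tsv", sep="\t", index=False)
    pd.DataFrame(
        trace_rows, columns=["module_id", "removed_gene", "k2_after_removal"]
    ).to_csv(outdir / "k2_trace.tsv", sep="\t", index=False)

    table1 = pd.DataFrame(
        {
            "module_id": module_ids,
            "annotation": ["" for _ in module_ids],
            "n_genes": [len(modules.modules[m]) for m in module_ids],
            "explained_variance_pct": [
                100 * var.per_module.get(m, float("nan")) for m in module_ids
            ],
        }
    )
    table1.to_csv(outdir / "table1.tsv", sep="\t", index=False)

    mult_df = mult.to_frame()
    mult_df.to_csv(outdir / "multiplicity.tsv", sep="\t", index=False)

    if overlap_table is not None:
        overlap_table.to_frame().to_csv(
            outdir / "overlap.tsv", sep="\t", index=False
        )
        sankey_links(overlap_table).to_csv(
            outdir / "sankey.tsv", sep="\t", index=False
        )

    prov = _provenance(
        config,
        {
            "chosen_dimension": int(k),
            "n_components": int(dec.n_components),
            "n_genes": int(F.n_genes),
            "n_samples": int(F.n_samples),
            "total_explained_variance": float(var.total),
            "variance_formula": var.formula,
            "n_empty_modules": int(mult.n_empty_modules),
            "min_cluster_effective": (
                config.min_cluster
                if config.min_cluster is not None
                else default_min_size(config.n_runs)
            ),
            "decomposition": dec.provenance,
        },
    )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)


def export_module_db(result: PipelineResult) -> list[dict]:
    """Static per-module JSON records (id, members, activities, variance)."""
    dec = result.decomposition
    records = []
    for i, mm in enumerate(result.memberships):
        records.append(
            {
                "id": mm.module_id,
                "members": [
                    {"gene_id": g, "weight": w, "sign": s}
                    for g, w, s in mm.members
                ],
                "is_empty": mm.is_empty,
                "activity": {
                    s: float(dec.A[i, j])
                    for j, s in enumerate(dec.sample_ids)
                },
                "explained_variance": float(
                    result.variance.per_module.get(mm.module_id, float("nan"))
                ),
                "annotation": "",
            }
        )
    return records
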