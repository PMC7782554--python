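"""Pipeline configuration and end-to-end stage orchestration.

Ties the modules into the full processing chain: simulated (or
provided) reads -> ORBITA contact annotation -> binned maps -> TAD
calling (modularity and NBT) -> null models -> aggregate statistics ->
optional polymer reconstruction.  Each stage writes text outputs into
the artifact directory plus a machine-readable run log; per-stage
seeds are derived from the global seed via a counter, so stages are
individually reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import aggregates, maps, null_models, orbita, polymer, synthetic, tad_modularity, tad_nbt

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline tunables, defaulting to the production settings."""

    seed: int = 0
    # synthetic stage
    n_bins: int = 300
    n_cells: int = 4
    n_contacts_per_cell: int = 6_000
    decay_exponent: float = 1.5
    enrichment: float = 8.0
    binsize: int = 10_000
    # orbita stage
    tolerance: int = 10
    max_valency: int = 4
    switch_rate: float = 0.1
    dup_rate: float = 0.2
    # maps stage
    drop_diagonals: int = 0
    # TAD stage
    gamma_max_value: float = 375.0
    gamma_step: float = 1.0
    min_tad_bins: int = 4
    # NBT stage
    nbt_max_distance_bins: int = 100
    # null-model stage
    null_n_maps: int = 20
    window_sizes: tuple = (10, 40)
    # polymer stage (off by default: minutes of runtime)
    run_polymer: bool = False
    polymer_steps: int = 20_000
    polymer_box: float = 10.0
    # stage toggles
    stages: tuple = ("simulate", "orbita", "maps", "tads", "nbt", "null", "aggregates")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("window_sizes", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage_seed(config: PipelineConfig, counter: int) -> int:
    return (config.seed * 10_007 + counter) % (2**31 - 1)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the configured stages; return the run log (also written as JSON).

    Deterministic under a fixed global seed.  Each stage appends its
    outputs and timing to the log; a stage failure raises after the
    partial log is flushed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": asdict(config), "stages": {}}
    state: dict = {}

    def finish(stage: str, t0: float, **info) -> None:
        log["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)

    try:
        if "simulate" in config.stages:
            t0 = time.time()
            arch = synthetic.make_architecture(
                config.n_bins,
                seed=_stage_seed(config, 1),
                decay_exponent=config.decay_exponent,
                enrichment=config.enrichment,
                binsize=config.binsize,
            )
            cells = [
                synthetic.sample_cell_contacts(
                    arch, config.n_contacts_per_cell, seed=_stage_seed(config, 2 + k)
                )
                for k in range(config.n_cells)
            ]
            state["arch"], state["cells"] = arch, cells
            for k, cell in enumerate(cells):
                cell.write_tsv(out / f"cell_{k}.contacts.tsv")
            finish("simulate", t0, n_cells=len(cells),
                   contacts=[c.n_contacts() for c in cells])

        if "orbita" in config.stages and "arch" in state:
            t0 = time.time()
            genome, seqs = synthetic.random_genome(
                chromosomes=(("chrS", 60_000),), seed=_stage_seed(config, 50)
            )
            rmap = synthetic.make_restriction_map(seqs, "GATC")
            n_frag = rmap.n_fragments("chrS")
            rng = np.random.default_rng(_stage_seed(config, 51))
            pairs = set()
            while len(pairs) < 400:
                a, b = sorted(rng.choice(n_frag, size=2, replace=False))
                pairs.add((int(a), int(b)))
            contacts = [("chrS", a, "chrS", b) for a, b in sorted(pairs)]
            reads = synthetic.simulate_chimeric_reads(
                contacts, rmap, switch_rate=config.switch_rate,
                dup_rate=config.dup_rate, seed=_stage_seed(config, 52),
                tolerance=config.tolerance,
            )
            annotated, rejected = orbita.classify_reads(
                (orbita.AlignmentRecord(r.read_id, tuple(map(tuple, r.parts))) for r in reads.reads),
                rmap, tolerance=config.tolerance,
            )
            unique = orbita.dedupe_contacts(annotated)
            kept, removed = orbita.filter_fragment_valency(unique, config.max_valency)
            orbita.write_pairs(kept, out / "contacts.pairs", {"chrS": 60_000})
            finish("orbita", t0, reads=len(reads), accepted=len(annotated),
                   unique=len(unique), after_valency=len(kept),
                   removed_fragments=len(removed))

        if "maps" in config.stages and "cells" in state:
            t0 = time.time()
            merged = maps.merge_maps(state["cells"])
            state["merged"] = merged
            merged.write_tsv(out / "merged.tsv")
            pc = maps.pc_curve(state["cells"], mode="single_cell")
            np.savetxt(out / "pc_curve.tsv",
                       np.column_stack([pc.s, pc.pc]), delimiter="\t",
                       header="s_bp\tpc", comments="")
            cov = [maps.coverage_stats(c) for c in state["cells"]]
            finish("maps", t0, merged_contacts=merged.n_contacts(),
                   mean_pct_covered=float(np.mean([c["pct_covered"] for c in cov])))

        if "tads" in config.stages and "cells" in state:
            t0 = time.time()
            grid = np.arange(0.0, config.gamma_max_value + 1e-9, config.gamma_step)
            sweeps = [
                tad_modularity.gamma_sweep(c, grid, config.min_tad_bins)
                for c in state["cells"]
            ]
            state["sweeps"] = sweeps
            for k, sw in enumerate(sweeps):
                sw.segmentation_half.to_bed(out / f"cell_{k}.tads.bed")
            shared = [
                tad_modularity.compare_segmentations(
                    sweeps[a].segmentation_half, sweeps[b].segmentation_half
                )["shared_boundary_pct"]
                for a in range(len(sweeps))
                for b in range(len(sweeps))
                if a != b
            ]
            finish("tads", t0,
                   n_tads=[sw.segmentation_half.n_tads for sw in sweeps],
                   mean_shared_boundary_pct=float(np.mean(shared)) if shared else None)

        if "nbt" in config.stages and "cells" in state:
            t0 = time.time()
            segs = [
                tad_nbt.call_tads_nbt(
                    c, config.nbt_max_distance_bins, seed=_stage_seed(config, 100 + k)
                )
                for k, c in enumerate(state["cells"])
            ]
            state["nbt_segs"] = segs
            for k, seg in enumerate(segs):
                seg.to_bed(out / f"cell_{k}.tads_nbt.bed")
            finish("nbt", t0, n_tads=[s.n_tads for s in segs])

        if "null" in config.stages and "merged" in state:
            t0 = time.time()
            merged = state["merged"]
            pc = maps.pc_curve(merged, mode="single_cell")
            pcb = pc.at_bins(merged.binsize)
            fit = null_models.fit_stickiness(merged, pcb)
            rows = []
            for cell_idx, cell in enumerate(state["cells"]):
                for w in config.window_sizes:
                    counts = null_models.window_counts(cell, w)
                    if len(counts) >= 20:
                        gof = null_models.poisson_gof(counts)
                        rows.append((cell_idx, w, gof["lambda"], gof["p_value"]))
            with open(out / "window_gof.tsv", "w") as fh:
                fh.write("cell\tW\tlambda\tp_value\n")
                for r in rows:
                    fh.write("\t".join(str(x) for x in r) + "\n")
            finish("null", t0, stickiness_iters=fit.iterations,
                   residual=fit.residual, gof_rows=len(rows))

        if "aggregates" in config.stages and "merged" in state:
            t0 = time.time()
            arch = state["arch"]
            e1_proxy = np.where(arch.compartment == "A", 1.0, -1.0)
            saddle = aggregates.saddle_profile(state["merged"], e1_proxy)
            np.savetxt(out / "saddle.tsv", saddle, delimiter="\t")
            finish("aggregates", t0,
                   saddle_corner_gap=float(saddle[0, 0] + saddle[-1, -1] - 2 * saddle.mean()))

        if config.run_polymer and "cells" in state:
            t0 = time.time()
            params = polymer.DPDParams(box=config.polymer_box)
            cell = state["cells"][0]
            n = min(cell.chrom_bins[cell.chromosomes[0]], 200)
            dense = cell.to_dense(cell.chromosomes[0])[:n, :n]
            st = polymer.build_system(dense, params=params, seed=_stage_seed(config, 200))
            traj = polymer.run_dpd(st, config.polymer_steps,
                                   seed=_stage_seed(config, 201),
                                   sample_every=max(1, config.polymer_steps // 20))
            np.savetxt(out / "polymer_final.xyz.tsv", traj.frames[-1], delimiter="\t")
            finish("polymer", t0, temperature=float(traj.temperature[-1]))
    except Exception as err:  # flush partial log, then re-raise
        log["error"] = repr(err)
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        raise
    return log
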