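"""End-to-end pipeline: simulate -> extract -> solve -> evaluate.

One :class:`PipelineConfig` (a plain mapping, usually loaded from YAML)
drives every stage; a single global seed governs simulation and rendering.
Each stage writes its outputs under the run directory together with the
resolved configuration, and stages are skipped when their outputs already
exist, so an interrupted run resumes deterministically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

from . import io
from .blockwise import SolutionStore, plan_blocks, run_blockwise
from .candidates import CandidateParams, extract_graph
from .evaluate import evaluate, greedy_track
from .sim import SimConfig, render_predictions, simulate_lineages
from .tracking import SolverParams, selection_to_forest, solve
from .verify import selection_objective

log = logging.getLogger("ilptrack")

__all__ = ["resolve_config", "run_pipeline"]

_DEFAULTS: dict = {
    "seed": 0,
    "sim": {},  # SimConfig fields
    "candidates": {},  # CandidateParams fields
    "solver": {},  # SolverParams fields
    "blockwise": None,  # {"block_shape": [...], "context": [...], "workers": N}
    "evaluate": {"radius": 3.0, "lengths": [5, 10, 20]},
}


def resolve_config(config: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULTS.items()}
    for k, v in (config or {}).items():
        if k not in out:
            raise KeyError(f"unknown pipeline config section {k!r}")
        if isinstance(out.get(k), dict) and isinstance(v, dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None, out_dir, dry_run: bool = False) -> dict:
    """Run every stage under ``out_dir``; returns the evaluation report dict.

    Stage outputs: ``gt.csv`` (simulated ground truth), ``indicator.zarr`` /
    ``movement.zarr`` / ``foreground.zarr``, ``graph/`` (nodes + edges CSV),
    ``rec.csv`` and ``greedy.csv`` (reconstructions), ``report.json``.  The
    resolved config is written first; ``dry_run`` stops after validating it.
    """
    cfg = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimConfig(**{"seed": cfg["seed"], **cfg["sim"]})
    cand_params = CandidateParams(**cfg["candidates"])
    solver_params = SolverParams(**cfg["solver"])
    io.dump_config(
        out / "config.yaml",
        {
            **cfg,
            "sim": dataclasses.asdict(sim_cfg),
            "candidates": dataclasses.asdict(cand_params),
            "solver": dataclasses.asdict(solver_params),
        },
    )
    if dry_run:
        return {"dry_run": True}

    t0 = time.time()
    gt_path = out / "gt.csv"
    if gt_path.exists():
        forest = io.read_forest(gt_path)
    else:
        forest = simulate_lineages(sim_cfg)
        io.write_forest(gt_path, forest)
    log.info("simulate: %d nodes, %d edges (%.1fs)", len(forest),
             forest.n_edges, time.time() - t0)

    t0 = time.time()
    ind_path = out / "indicator.zarr"
    if ind_path.exists():
        indicator, _ = io.read_volume(ind_path)
        movement, _ = io.read_volume(out / "movement.zarr")
        foreground, _ = io.read_volume(out / "foreground.zarr")
    else:
        indicator, movement, foreground = render_predictions(forest, sim_cfg)
        io.write_volume(ind_path, indicator)
        io.write_volume(out / "movement.zarr", movement)
        io.write_volume(out / "foreground.zarr", foreground)
    log.info("render: %s (%.1fs)", indicator.shape, time.time() - t0)

    t0 = time.time()
    graph_dir = out / "graph"
    if (graph_dir / "nodes.csv").exists():
        graph = io.read_graph(graph_dir)
    else:
        graph = extract_graph(indicator, movement, cand_params)
        io.write_graph(graph_dir, graph)
    log.info("extract: %d nodes, %d edges (%.1fs)", graph.n_nodes,
             graph.n_edges, time.time() - t0)

    t0 = time.time()
    rec_path = out / "rec.csv"
    if rec_path.exists():
        rec = io.read_forest(rec_path)
    elif cfg["blockwise"]:
        bw = cfg["blockwise"]
        plan = plan_blocks(
            sim_cfg.shape, tuple(bw["block_shape"]), tuple(bw["context"])
        )
        store = SolutionStore(out / "solution_store")
        rec, selection = run_blockwise(
            graph, solver_params, plan, store=store,
            workers=int(bw.get("workers", 1)),
        )
        log.info("blockwise objective: %.6f",
                 selection_objective(graph, selection, solver_params))
        io.write_forest(rec_path, rec)
    else:
        selection = solve(graph, solver_params)
        rec = selection_to_forest(graph, selection)
        log.info("global objective: %.6f", selection.objective)
        io.write_forest(rec_path, rec)
    log.info("solve: %d nodes, %d edges (%.1fs)", len(rec), rec.n_edges,
             time.time() - t0)

    greedy_path = out / "greedy.csv"
    if greedy_path.exists():
        greedy = io.read_forest(greedy_path)
    else:
        greedy = greedy_track(graph, cand_params.edge_radius,
                              cand_params.axis_weights)
        io.write_forest(greedy_path, greedy)

    ev = cfg["evaluate"]
    report = {
        "ilp": evaluate(forest, rec, ev["radius"], ev.get("lengths")).to_dict(),
        "greedy": evaluate(forest, greedy, ev["radius"], ev.get("lengths")).to_dict(),
        "n_candidates": graph.n_nodes,
        "n_candidate_edges": graph.n_edges,
    }
    io.write_report(out / "report.json", report)
    log.info("ilp errors: %s | greedy errors: %s",
             report["ilp"]["counts"], report["greedy"]["counts"])
    return report
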