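"""End-to-end pipeline: phantom (or supplied mask) -> topology -> preliminary
classification -> topology optimizer -> voxel reconstruction -> evaluation.

Each stage writes its artifacts into the output directory together with the
effective configuration and a structured log line; reruns with the same
config and seed reproduce the outputs byte-for-byte for deterministic stages
(the metrics JSON is written with sorted keys for this reason).
"""
from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._util import log, stage_seed
from .config import PipelineConfig
from .io import read_volume, write_graph, write_particles_csv, write_phantom, write_volume
from .optimizer import optimize
from .phantom import make_phantom
from .reconstruct import confusion, dsc, fuse_hilum, metrics, paint_labels
from .topology import extract_topology
from .twinpipe import OracleClassifier


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    mask_path: str | Path | None = None,
    image_path: str | Path | None = None,
    hilum_path: str | Path | None = None,
) -> dict:
    """Execute the configured stages; returns the metrics dictionary.

    Without a ``mask_path`` a synthetic phantom provides the input volumes and
    the ground truth used for evaluation.  Partial outputs are kept on stage
    failure, with the failing stage recorded in ``FAILED_STAGE``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.save(outdir / "config.yaml")
    results: dict = {}
    stage = "init"
    t_start = time.time()
    try:
        # ---- input --------------------------------------------------------
        stage = "phantom"
        truth_vol = None
        if mask_path is None:
            vol, art, vein = make_phantom(config.phantom, seed=stage_seed(config.seed, "phantom"))
            write_phantom(vol, outdir / "phantom", trees=[art, vein])
            mask, spacing, intensity = vol.mask, vol.spacing, vol.intensity
            truth_vol = vol
        else:
            mask, spacing = read_volume(mask_path)
            mask = mask > 0
            intensity = None
            if image_path is not None:
                intensity, _ = read_volume(image_path)
        log.info("stage=phantom n_mask=%d t=%.1fs", int(mask.sum()), time.time() - t_start)

        # ---- topology -----------------------------------------------------
        stage = "topology"
        t0 = time.time()
        graph, dmap = extract_topology(mask, spacing, intensity, config.topology)
        write_graph(graph, outdir / "graph.json")
        write_particles_csv(graph, outdir / "particles.csv")
        log.info("stage=topology n_particles=%d t=%.1fs", graph.n_nodes, time.time() - t0)

        # ---- classify -----------------------------------------------------
        stage = "classify"
        truth = None
        if truth_vol is not None:
            ta = cKDTree(truth_vol.centerline_points_vox("artery"))
            tv = cKDTree(truth_vol.centerline_points_vox("vein"))
            P = graph.positions()
            truth = np.where(ta.query(P)[0] < tv.query(P)[0], 1, 2).astype(np.uint8)
        if config.classifier == "oracle":
            if truth is None:
                raise ValueError("oracle classifier requires phantom ground truth")
            oracle = OracleClassifier(
                flip_noise=config.oracle_flip_noise,
                seed=stage_seed(config.seed, "classify"),
            )
            probs = oracle.predict(truth)
        else:
            raise ValueError(
                "pipeline classifier must be 'oracle'; trained models are run "
                "through the 'classify' command"
            )
        np.savetxt(outdir / "probabilities.csv", probs.p, fmt="%.6f", header="p_artery")

        # ---- optimize -----------------------------------------------------
        stage = "optimize"
        labeled = optimize(graph, probs.p, mode=config.optimizer.mode, config=config.optimizer)
        write_graph(graph, outdir / "labeled.swc", fmt="swc", labels=labeled.labels)
        with open(outdir / "audit.jsonl", "w") as f:
            for entry in labeled.audit:
                f.write(json.dumps(entry, sort_keys=True) + "\n")

        # ---- reconstruct --------------------------------------------------
        stage = "reconstruct"
        scales = np.array([p.scale for p in graph.particles])
        av = paint_labels(
            graph.positions(), scales, labeled.labels, mask,
            config.reconstruct.dilation_factor,
        )
        if hilum_path is not None:
            hilum, hsp = read_volume(hilum_path)
            av = fuse_hilum(av, hilum.astype(av.dtype), spacing, hsp)
        write_volume(av, spacing, outdir / "av_labels.nii.gz")

        # ---- evaluate -----------------------------------------------------
        stage = "evaluate"
        if truth is not None:
            c = confusion(labeled.labels, truth)
            acc, sens, spec = metrics(c)
            results = {
                "accuracy": acc, "sensitivity": sens, "specificity": spec,
                "tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn,
                "dsc_artery": dsc(av == 1, truth_vol.truth_labels == 1),
                "dsc_vein": dsc(av == 2, truth_vol.truth_labels == 2),
                "n_particles": int(graph.n_nodes),
                "n_corrections": len(labeled.audit),
            }
        else:
            results = {
                "n_particles": int(graph.n_nodes),
                "n_artery_particles": int((labeled.labels == 1).sum()),
                "n_vein_particles": int((labeled.labels == 2).sum()),
                "n_corrections": len(labeled.audit),
            }
        (outdir / "metrics.json").write_text(
            json.dumps(results, sort_keys=True, indent=1) + "\n"
        )
    except Exception as e:
        (outdir / "FAILED_STAGE").write_text(stage + "\n")
        raise StageError(stage, e) from e
    return results
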