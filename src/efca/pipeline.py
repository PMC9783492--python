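"""Report assembly: run the sequence and trajectory stages from a RunConfig.

Outputs are plain files in the configured output directory — CSV tables for
contacts, distances, RMSD, RMSF, identity/similarity, site scores, a Newick
tree, and a JSON manifest recording every parameter plus the time
arithmetic (total analyzed time = n_replicates * last_ns; per-replica
duration = equilibration + production).  Logging goes to stderr; stdout
stays clean.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .electrostatics import site_electronegativity, site_scores_to_csv
from .errors import EfcaError, PipelineError
from .ions import AnalysisWindow, com_distance_distribution, contact_frequency, stability_check
from .pdbio import read_multimodel_pdb
from .sequence import (
    cluster_upgma,
    pairwise_identity_similarity,
    read_alignment,
    read_fasta,
    scan_ef_loops,
)
from .synthetic import HarmonicIonConfig, gen_fixture_set, gen_harmonic_ion
from .trajectory import Frame, rmsd_series, rmsf_profile

logger = logging.getLogger("efca")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).  Any
    stage failure removes the partial output directory and re-raises as
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": config.model_dump(),
        "per_replica_total_ns": config.per_replica_total_ns,
        "outputs": [],
    }
    try:
        if config.fasta or config.alignment:
            _stage(manifest, out, "sequence", _sequence_stage, config)
        if config.demo or config.replicates:
            _stage(manifest, out, "trajectory", _trajectory_stage, config)
    except EfcaError as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=_jsonable))
    manifest["outputs"].append("manifest.json")
    return manifest


def _stage(manifest: dict, out: Path, name: str, fn, config: RunConfig) -> None:
    t0 = time.perf_counter()
    logger.info("stage %s: starting", name)
    try:
        fn(manifest, out, config)
    except FileNotFoundError as exc:
        raise PipelineError(f"stage {name}: missing input file {exc.filename!r}") from exc
    except PipelineError:
        raise
    except EfcaError as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)


def _sequence_stage(manifest: dict, out: Path, config: RunConfig) -> None:
    produced = []
    if config.fasta:
        path = Path(config.fasta)
        if not path.exists():
            raise PipelineError(f"stage sequence: missing input file {str(path)!r}")
        records = read_fasta(path)
        import pandas as pd

        hits = [
            {"parent_id": h.parent_id, "loop_start": h.loop_start, "loop_sequence": h.loop_sequence}
            for rec in records
            for h in scan_ef_loops(rec)
        ]
        pd.DataFrame(hits, columns=["parent_id", "loop_start", "loop_sequence"]).to_csv(
            out / "motifs.csv", index=False
        )
        produced.append("motifs.csv")
        manifest["n_sequences"] = len(records)
        manifest["n_motif_hits"] = len(hits)
    if config.alignment:
        path = Path(config.alignment)
        if not path.exists():
            raise PipelineError(f"stage sequence: missing input file {str(path)!r}")
        aln = read_alignment(path, config.alignment_format)
        mat = pairwise_identity_similarity(aln)
        mat.to_csv(out / "identity.csv", "identity")
        mat.to_csv(out / "similarity.csv", "similarity")
        tree = cluster_upgma(mat)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        produced += ["identity.csv", "similarity.csv", "tree.nwk"]
    manifest["outputs"] += produced


def _trajectory_stage(manifest: dict, out: Path, config: RunConfig) -> None:
    window = AnalysisWindow(last_ns=config.last_ns, stride_ns=config.stride_ns)
    if config.demo:
        trajs = _demo_replicates(config)
    else:
        trajs = []
        for p in config.replicates:
            path = Path(p)
            if not path.exists():
                raise PipelineError(f"stage trajectory: missing input file {str(path)!r}")
            trajs.append(read_multimodel_pdb(path, stride_ns=config.stride_ns))

    stability = []
    for i, traj in enumerate(trajs, start=1):
        series = rmsd_series(traj, selection=config.selection)
        series.to_csv(out / f"rmsd_rep{i}.csv")
        fluct, stable = stability_check(
            series, last_ns=min(config.last_ns, traj.span_ns), threshold_A=config.rmsd_threshold_A
        )
        stability.append({"replicate": i, "max_fluctuation_A": fluct, "stable": stable})
        prof = rmsf_profile(traj, selection=config.selection)
        prof.to_csv(out / f"rmsf_rep{i}.csv")
        manifest["outputs"] += [f"rmsd_rep{i}.csv", f"rmsf_rep{i}.csv"]

    contacts = contact_frequency(trajs, window, cutoff_A=config.cutoff_A)
    contacts.to_csv(out / "contacts.csv")
    dists = com_distance_distribution(trajs, window, com_atoms=config.com_atoms)
    dists.to_csv(out / "distances.csv")
    manifest["outputs"] += ["contacts.csv", "distances.csv"]
    manifest["stability"] = stability
    manifest["n_replicates"] = len(trajs)
    manifest["total_time_ns"] = contacts.total_time_ns
    manifest["frames_counted"] = contacts.frames_counted
    manifest["contacts"] = contacts.metadata()

    if config.demo:
        fixtures = gen_fixture_set(config.seed)
        scores = {}
        for name, structure in fixtures.structures.items():
            frame = Frame(time=0.0, coordinates=structure.coordinates)
            for site, center in structure.site_centers.items():
                scores[f"{name}:{site}"] = site_electronegativity(
                    frame, structure.topology, center, radius_A=6.0,
                    dielectric=config.dielectric,
                )
        site_scores_to_csv(scores, out / "site_scores.csv")
        manifest["outputs"].append("site_scores.csv")


def _demo_replicates(config: RunConfig):
    """Synthetic demo: the TPC1-like pseudo-structure with the first ion in a
    harmonic well at the EF1 site, three independent replicates."""
    fixtures = gen_fixture_set(config.seed)
    structure = fixtures.structures["TPC1_like"]
    n_frames = int(round(config.last_ns / config.stride_ns))
    trajs = []
    for r in range(config.demo_replicates):
        cfg = HarmonicIonConfig.from_sigma(
            2.5, n_frames=n_frames, frame_stride_ns=config.stride_ns,
            site_center=tuple(structure.site_centers["EF1"]),
            seed=config.seed * 1000 + r,
        )
        trajs.append(gen_harmonic_ion(cfg, structure.topology, structure.coordinates))
    return trajs


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
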