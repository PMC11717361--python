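"""HDF5 experiment containers, YAML configuration, and pipeline orchestration.

The container layout is /cells/<id>/{chirp,bar,noise}/{rec1,rec2} arrays
plus per-cell metadata attributes (type label, classifier-confidence
stand-in, ground-truth JSON) and a /stimuli group; a schema version is
checked on read and round-trips are bit-exact. ``run_pipeline`` ties the
stages together: simulate -> preprocess -> quality -> metrics ->
disentangle -> cluster, with per-stage outputs written once and reused on
resume, and every CSV/JSON output carrying the config hash and package
version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import extract_sparse_features, fit_mixture_select_k
from .metrics import (
    disentangle_effects,
    feature_delta_table,
    records_from_experiment,
    suppression_index,
)
from .preprocess import ResponseMatrix
from .quality import apply_inclusion_criteria, quality_index
from .stimulus import load_stimulus_h5, save_stimulus_h5
from .synth import (
    SimulatedCell,
    SimulatedExperiment,
    default_feature_windows,
    make_effect_spec,
    simulate_paired_experiment,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "save_experiment",
    "load_experiment",
    "config_hash",
    "run_pipeline",
]


def save_experiment(path, exp: SimulatedExperiment) -> None:
    """Write a SimulatedExperiment to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["preset"] = exp.preset
        f.attrs["protocol"] = exp.protocol
        f.attrs["seed"] = exp.seed
        stim = f.create_group("stimuli")
        save_stimulus_h5(stim.create_group("chirp"), exp.chirp_stim)
        save_stimulus_h5(stim.create_group("bar"), exp.bar_stim)
        if exp.noise_stim is not None:
            save_stimulus_h5(stim.create_group("noise"), exp.noise_stim)
        f.attrs["cell_order"] = json.dumps([c.cell_id for c in exp.cells])
        cells = f.create_group("cells")
        for cell in exp.cells:
            g = cells.create_group(cell.cell_id)
            g.attrs["type_label"] = cell.type_label
            g.attrs["confidence"] = cell.confidence
            if cell.archetype is not None:
                g.attrs["ground_truth"] = json.dumps({
                    "type_label": cell.archetype.type_label,
                    "w_sup": cell.archetype.w_sup,
                    "tau_k": cell.archetype.tau_k,
                    "baseline": cell.archetype.baseline,
                    "gain": cell.archetype.gain,
                    "polarity": cell.archetype.polarity,
                    "category": exp.effect_spec.category(cell.type_label),
                })
            for name in ("chirp", "noise"):
                pair = getattr(cell, name)
                if pair is None:
                    continue
                sg = g.create_group(name)
                for rec, mat in zip(("rec1", "rec2"), pair):
                    d = sg.create_dataset(rec, data=mat.values)
                    d.attrs["fs"] = mat.fs
            if cell.bar is not None:
                bg = g.create_group("bar")
                for rec, dirmats in zip(("rec1", "rec2"), cell.bar):
                    rg = bg.create_group(rec)
                    for d_deg, mat in dirmats.items():
                        ds = rg.create_dataset(f"{d_deg:g}", data=mat.values)
                        ds.attrs["fs"] = mat.fs
            if cell.spikes is not None:
                sg = g.create_group("spikes")
                sg.create_dataset("rec1", data=cell.spikes[0])
                sg.create_dataset("rec2", data=cell.spikes[1])


def load_experiment(path) -> SimulatedExperiment:
    """Read an experiment container written by :func:`save_experiment`."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported container schema {version}, "
                             f"expected {SCHEMA_VERSION}")
        preset = str(f.attrs["preset"])
        protocol = str(f.attrs["protocol"])
        seed = int(f.attrs["seed"])
        chirp_stim = load_stimulus_h5(f["stimuli/chirp"])
        bar_stim = load_stimulus_h5(f["stimuli/bar"])
        noise_stim = (load_stimulus_h5(f["stimuli/noise"])
                      if "noise" in f["stimuli"] else None)
        cells = []
        order = (json.loads(f.attrs["cell_order"])
                 if "cell_order" in f.attrs else list(f["cells"]))
        for cid in order:
            g = f["cells"][cid]
            cell = SimulatedCell(cell_id=cid,
                                 type_label=str(g.attrs["type_label"]),
                                 confidence=float(g.attrs["confidence"]))
            for name in ("chirp", "noise"):
                if name in g:
                    cell_pair = tuple(
                        ResponseMatrix(values=g[name][rec][:],
                                       fs=float(g[name][rec].attrs["fs"]))
                        for rec in ("rec1", "rec2"))
                    setattr(cell, name, cell_pair)
            if "bar" in g:
                pair = []
                for rec in ("rec1", "rec2"):
                    rg = g["bar"][rec]
                    pair.append({float(k): ResponseMatrix(
                        values=rg[k][:], fs=float(rg[k].attrs["fs"]))
                        for k in rg})
                cell.bar = tuple(pair)
            if "spikes" in g:
                cell.spikes = (g["spikes/rec1"][:], g["spikes/rec2"][:])
            cells.append(cell)
    windows = default_feature_windows(chirp_stim, bar_stim)
    return SimulatedExperiment(preset=preset, protocol=protocol, seed=seed,
                               cells=cells,
                               effect_spec=make_effect_spec(preset),
                               chirp_stim=chirp_stim, bar_stim=bar_stim,
                               windows=windows, noise_stim=noise_stim)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _stamp(config: dict) -> dict:
    return {"config_hash": config_hash(config), "version": __version__}


def run_pipeline(config: dict) -> dict:
    """Execute the configured analysis stages; outputs land in ``outdir``.

    ``config`` keys: ``outdir``, ``seed``, ``preset``, ``stages`` (subset of
    simulate/preprocess/quality/metrics/disentangle/cluster, in order),
    plus optional ``n_cells_per_type``, ``n_reps``. Stage outputs that
    already exist are reused (resume semantics); re-running with the same
    config reproduces all numeric outputs because every stage derives its
    randomness from the master seed. Returns a dict of result paths.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["simulate", "preprocess", "quality",
                                   "metrics", "disentangle", "cluster"])
    seed = int(config.get("seed", 0))
    preset = config.get("preset", "g32-default")
    n_cells = int(config.get("n_cells_per_type", 30))
    n_reps = int(config.get("n_reps", 5))
    stamp = _stamp(config)
    results: dict = {}

    def write_json(name, payload):
        path = outdir / name
        with open(path, "w") as fh:
            json.dump({**stamp, **payload}, fh, indent=2, default=str)
        results[name] = str(path)

    exps = {}

    def get_exp(protocol):
        path = outdir / f"exp_{protocol}.h5"
        if protocol not in exps:
            if path.exists():
                exps[protocol] = load_experiment(path)
            else:
                exps[protocol] = simulate_paired_experiment(
                    preset, protocol, seed=seed,
                    n_cells_per_type=n_cells, n_reps=n_reps)
                save_experiment(path, exps[protocol])
        results[f"exp_{protocol}.h5"] = str(path)
        return exps[protocol]

    if "simulate" in stages:
        get_exp("ctrl-ctrl")
        get_exp("ctrl-drug")

    if "preprocess" in stages or "metrics" in stages or "cluster" in stages:
        exp = get_exp("ctrl-drug")
        records = records_from_experiment(exp)
    if "preprocess" in stages:
        rows = []
        for rec in records:
            for cond, avg in zip(("rec1", "rec2"), rec.chirp):
                rows.append({"cell_id": rec.cell_id, "type": rec.type_label,
                             "condition": cond, "stimulus": "chirp",
                             **{f"s{i}": v for i, v in enumerate(avg.values)}})
        df = pd.DataFrame(rows)
        df.attrs.update(stamp)
        path = outdir / "response_averages.csv"
        df.to_csv(path, index=False)
        results["response_averages.csv"] = str(path)

    if "quality" in stages:
        exp = get_exp("ctrl-drug")
        cells = []
        for i, cell in enumerate(exp.cells):
            cells.append({
                "cell_id": cell.cell_id,
                "qi_chirp": tuple(quality_index(m) for m in cell.chirp),
                "qi_bar": (None, None),
                "confidence": cell.confidence,
                "type_index": 32,
            })
        kept, reports = apply_inclusion_criteria(cells)
        write_json("quality.json", {
            "n_cells": len(cells), "n_included": len(kept),
            "reports": [{"cell_id": r.cell_id, "included": r.included,
                         "reasons": list(r.reasons)} for r in reports]})

    if "metrics" in stages:
        rows = []
        for rec in records:
            for cond, avg in zip(("rec1", "rec2"), rec.chirp):
                si = suppression_index(avg)
                rows.append({"cell_id": rec.cell_id, "type": rec.type_label,
                             "condition": cond, "si": si.si,
                             "auc_neg": si.auc_neg, "auc_pos": si.auc_pos})
        path = outdir / "suppression.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        results["suppression.csv"] = str(path)

    if "disentangle" in stages:
        ctrl = feature_delta_table(get_exp("ctrl-ctrl"))
        drug = feature_delta_table(get_exp("ctrl-drug"))
        effects = disentangle_effects(ctrl, drug)
        path = outdir / "effects.csv"
        effects.table.to_csv(path, index=False)
        results["effects.csv"] = str(path)
        write_json("effects_summary.json", {
            "alpha_per_test": effects.alpha_per_test,
            "n_types_tested": effects.n_types_tested,
            "categories": effects.categories})

    if "cluster" in stages:
        exp = get_exp("ctrl-drug")
        chirp = np.vstack([r.chirp[0].values for r in records])
        bar = np.vstack([r.bar[0].values for r in records])
        feats = extract_sparse_features(chirp, bar, seed=seed)
        model = fit_mixture_select_k(feats, seed=seed)
        write_json("clusters.json", {
            "chosen_k": model.chosen_k,
            "sizes": model.sizes.tolist(),
            "bic": {str(k): v for k, v in model.bic.items()},
        })
        path = outdir / "labels.csv"
        pd.DataFrame({"cell_id": [r.cell_id for r in records],
                      "label": model.labels}).to_csv(path, index=False)
        results["labels.csv"] = str(path)

    return results
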