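"""Study orchestration: phantom → segmentation → morphometry → cross → QTL.

A study is described by one YAML/JSON configuration; :func:`run_study`
executes the configured stages, writes every table as CSV plus a manifest
(config hash, master seed, package versions) and returns the output
directory.  All randomness derives from the single master seed, so
re-running an identical configuration reproduces every number.

Configuration keys (all optional except ``seed``)::

    seed: 1                      # master seed, mandatory
    out_dir: results/study       # output directory
    imaging:                     # phantom → phenotype stage
      n_specimens: 3
      phantom: {...}             # PhantomSpec overrides
      qtl_link: {parameter: n_lacunae, base: 50, gain: 10}   # optional
      segmentation: {bone_threshold: otsu, ...}
      morphometry: {n_theta_bins: 360, k_neighbors: 6}
    genetics:                    # cross → QTL stage
      cross: {n_f2: 755, n_f1: 12, env_sd: 1.0, sex_effect: 0.0,
              qtl: [{chromosome: '3', position_cM: 40, additive: 0.8}]}
      # or: cross: {csv: path/to/cross.csv, f1_csv: path/to/f1.csv}
      step_cm: 2.0
      n_perm: 100
      alpha: 0.05
      max_qtl: 10
      heritability_criterion: 40.0
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crosssim import CrossData, PlantedQTL, default_map, read_cross_csv, simulate_cross, write_cross_csv
from .morphometry import assemble_phenotypes
from .phantom import PhantomSpec, generate_phantom
from .qtl import (derive_penalties, genotype_probabilities, permutation_threshold,
                  refine_positions, scan_one_ehk, select_phenotypes,
                  stepwise_model_search, variance_explained)
from .segmentation import label_components, segment_phases

log = logging.getLogger("boneqtl.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_study(config: dict, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the result directory.

    A stage failure aborts the run with the failing stage named; partial
    outputs are retained next to a ``FAILED`` marker file.
    """
    if "seed" not in config:
        raise ValueError("config must set a seed")
    out = Path(out_dir or config.get("out_dir", "results/study"))
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": int(config["seed"]),
        "boneqtl_version": __version__,
        "numpy_version": np.__version__,
        "stages": {},
    }
    try:
        if "imaging" in config:
            t0 = time.time()
            _run_imaging(config, out)
            manifest["stages"]["imaging"] = round(time.time() - t0, 2)
            log.info("imaging stage done in %.1fs", time.time() - t0)
        if "genetics" in config:
            t0 = time.time()
            _run_genetics(config, out)
            manifest["stages"]["genetics"] = round(time.time() - t0, 2)
            log.info("genetics stage done in %.1fs", time.time() - t0)
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        log.removeHandler(handler)
        raise StageError(f"stage failed: {exc}") from exc
    manifest["runtime_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    log.removeHandler(handler)
    return out


def _phantom_spec(overrides: dict, seed: int) -> PhantomSpec:
    fields = {f.name for f in dataclasses.fields(PhantomSpec)}
    bad = set(overrides) - fields
    if bad:
        raise ValueError(f"unknown phantom parameters: {sorted(bad)}")
    kw = dict(overrides)
    for key in ("lacuna_semi_axes", "shell_center_offset", "lacuna_orientation",
                "lacuna_placement"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    kw.setdefault("seed", seed)
    return PhantomSpec(**kw)


def _run_imaging(config: dict, out: Path) -> None:
    cfg = config["imaging"]
    master = np.random.default_rng(int(config["seed"]))
    n_spec = int(cfg.get("n_specimens", 1))
    seg_kw = dict(cfg.get("segmentation", {}))
    thr = seg_kw.pop("bone_threshold", "otsu")
    morpho_kw = cfg.get("morphometry", {})
    link = cfg.get("qtl_link")
    rows = []
    for i in range(n_spec):
        seed_i = int(master.integers(2**31))
        overrides = dict(cfg.get("phantom", {}))
        if link:
            x = float(master.normal())  # stand-in genetic value for demo links
            overrides[link["parameter"]] = int(round(link["base"] + link["gain"] * x))
        spec = _phantom_spec({**overrides, "seed": seed_i}, seed_i)
        vol = generate_phantom(spec)
        seg = label_components(segment_phases(vol, thr), **seg_kw)
        row = assemble_phenotypes(seg, specimen=f"specimen_{i:03d}", **morpho_kw)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.index.name = "specimen"
    table.to_csv(out / "phenotypes.csv", float_format="%.10g")


def _load_cross(cfg: dict, seed: int, out: Path) -> CrossData:
    ccfg = cfg["cross"]
    if "csv" in ccfg:
        cross = read_cross_csv(ccfg["csv"])
        if "f1_csv" in ccfg:
            cross.phenotypes_f1 = pd.read_csv(ccfg["f1_csv"])
        return cross
    qtl = [PlantedQTL(str(q["chromosome"]), float(q["position_cM"]),
                      float(q.get("additive", 0.0)), float(q.get("dominance", 0.0)))
           for q in ccfg.get("qtl", [])]
    cross = simulate_cross(
        gmap=default_map(),
        n_f2=int(ccfg.get("n_f2", 755)),
        n_f1=int(ccfg.get("n_f1", 12)),
        qtl=qtl,
        env_sd=float(ccfg.get("env_sd", 1.0)),
        sex_effect=float(ccfg.get("sex_effect", 0.0)),
        missing_rate=float(ccfg.get("missing_rate", 0.0)),
        seed=seed,
    )
    write_cross_csv(out / "cross.csv", cross)
    return cross


def _run_genetics(config: dict, out: Path) -> None:
    cfg = config["genetics"]
    seed = int(config["seed"])
    cross = _load_cross(cfg, seed, out)
    step = float(cfg.get("step_cm", 2.0))
    n_perm = int(cfg.get("n_perm", 100))
    alpha = float(cfg.get("alpha", 0.05))
    max_qtl = int(cfg.get("max_qtl", 10))
    criterion = float(cfg.get("heritability_criterion", 40.0))

    pheno_cols = list(cross.phenotypes_f2.columns)
    if len(cross.phenotypes_f1):
        selection = select_phenotypes(cross.phenotypes_f1, cross.phenotypes_f2,
                                      criterion_percent=criterion)
        selection.to_csv(out / "heritability.csv", index=False,
                         float_format="%.10g")
        selected = list(selection.query("selected").phenotype)
        log.info("heritability screen: %d/%d phenotypes selected",
                 len(selected), len(pheno_cols))
    else:
        selected = pheno_cols

    probs = genotype_probabilities(cross, step_cM=step)
    scan_frames = []
    model_rows = []
    for name in selected:
        y = cross.phenotypes_f2[name].to_numpy()
        scan = scan_one_ehk(probs, y, cross.sex)
        frame = scan.to_frame()
        frame.insert(0, "phenotype", name)
        thr = permutation_threshold(probs, y, cross.sex, n_perm=n_perm,
                                    alpha=alpha, seed=seed + 1)
        frame["threshold"] = thr
        scan_frames.append(frame)
        pen = derive_penalties(probs, y, cross.sex, n_perm=n_perm, alpha=alpha,
                               seed=seed + 2)
        model = stepwise_model_search(probs, y, cross.sex, pen, max_qtl=max_qtl)
        if model.n_loci:
            model = refine_positions(model, cross, y, cross.sex, probs=probs)
            terms = variance_explained(model, probs, y, cross.sex)
            summary = model.summary()
            summary["pct_var"] = terms.iloc[: len(summary)]["pct_var"].to_numpy()
            summary["dropped_lod"] = terms.iloc[: len(summary)]["dropped_lod"].to_numpy()
            summary.insert(0, "phenotype", name)
            model_rows.append(summary)
            _plot_model(out, name, scan, model, thr)
        (out / f"penalties_{name}.json").write_text(json.dumps(
            dict(T_main=pen.T_main, T_heavy=pen.T_heavy, T_light=pen.T_light,
                 alpha=pen.alpha, n_perm=pen.n_perm, scaled_down=pen.scaled_down),
            indent=2))
    pd.concat(scan_frames).to_csv(out / "scans.csv", index=False,
                                  float_format="%.10g")
    if model_rows:
        pd.concat(model_rows).to_csv(out / "models.csv", index=False,
                                     float_format="%.10g")
    else:
        (out / "models.csv").write_text(
            "phenotype,chromosome,position_cM,additive,dominance,ci_lo,ci_hi,"
            "pct_var,dropped_lod\n")


def _plot_model(out: Path, name: str, scan, model, threshold: float) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = scan.to_frame()
    fig, ax = plt.subplots(figsize=(10, 3))
    offset = 0.0
    ticks, labels = [], []
    for chrom, sub in frame.groupby("chromosome", sort=False):
        ax.plot(sub.position_cM + offset, sub.lod, lw=0.8)
        ticks.append(offset + sub.position_cM.max() / 2)
        labels.append(chrom)
        offset += sub.position_cM.max() + 5
    ax.axhline(threshold, color="gray", ls="--", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("LOD")
    ax.set_title(f"{name}: genome scan ({model.n_loci} QTL in model)")
    fig.tight_layout()
    fig.savefig(out / f"scan_{name}.png", dpi=120)
    plt.close(fig)
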