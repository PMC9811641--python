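"""End-to-end orchestration: synthesize-or-load, segment, measure, classify, report.

The run configuration is a plain YAML mapping with every physical constant
surfaced (traversal threshold, bubble detection floor, train frequency,
frame interval, pixel scale, gray-level thresholds); :func:`default_config`
documents the schema.  A run is fully deterministic given (config, seed).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import imaging, seal_classifier, synthetic_data, traversal
from .imaging import DETECTION_FLOOR, FrameStack
from .materials import BridgeGeometry, JetSpec, load_materials, ohnesorge, weber
from .synthetic_data import GeneratorConfig

log = logging.getLogger("cavibridge")


def default_config() -> dict:
    """Schema and defaults of a run configuration."""
    return {
        "mode": "synthetic",            # synthetic | stacks
        "n_experiments": 20,
        "seed": 0,
        "materials": None,              # None = all bundled materials
        "stack_dirs": [],               # used in stacks mode
        "noise_sigma": 0.0,
        "jet": {"rho_0": 1000.0},
        "geometry": {"D_cb": 6e-3, "H_wall": 1e-3},
        "thresholds": {
            "traversal": 0.7,           # We/We* boundary
            "detection_floor": DETECTION_FLOOR,
            "train_frequency": 0.5,
            "binarize": 128,            # gray level separating liquid from air
            "bubble_binarize": 50,      # separates injected liquid from bridge
        },
    }


def load_config(path: str | Path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(user, dict):
        raise ValueError("config must be a YAML mapping")
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _analyze_one(
    stack: FrameStack, cfg: dict
) -> dict:
    """Measure one stack: kinematics, seal classification inputs, bubbles."""
    thr = cfg["thresholds"]
    m = imaging.analyze_stack(
        stack,
        strategy="fixed",
        threshold=thr["binarize"],
        bridge_diameter=cfg["geometry"]["D_cb"],
    )
    row: dict = {
        "A_max": m.A_max,
        "L_max": m.L_max,
        "t_col": m.t_col,
        "open_ended": m.open_ended,
    }
    try:
        u_c, u_c_err = imaging.fit_front_velocity(stack, m)
    except imaging.InsufficientDataError:
        u_c, u_c_err = np.nan, np.nan
        row["missing"] = "front-velocity fit: too few expansion frames"
    row["U_c_fit"] = u_c
    row["U_c_fit_err"] = u_c_err
    try:
        outcome = seal_classifier.classify_seal_observed(
            m.L_max, m.pinch_positions, m.dome_closed_during_expansion, m.t_col
        )
        row["observed_regime"] = outcome.regime
        row["pinch_count"] = outcome.pinch_count
    except ValueError as exc:
        row["observed_regime"] = "unclassified"
        row["missing"] = f"seal classification: {exc}"
    final_dark = imaging.binarize(
        stack.frames[-1], strategy="fixed", threshold=thr["bubble_binarize"]
    )
    bubbles = imaging.measure_bubbles(
        final_dark, stack.pixel_size, thr["detection_floor"]
    )
    row["bubble_count"] = bubbles.count
    row["A_bubbles_over_A_total"] = bubbles.ratio
    return row


def run(config: dict | str | Path, seed: Optional[int] = None) -> pd.DataFrame:
    """Execute a full run and return the per-experiment report."""
    cfg = load_config(config) if not isinstance(config, dict) else {**default_config(), **config}
    if seed is not None:
        cfg["seed"] = seed
    materials = load_materials()
    thr = cfg["thresholds"]
    rows = []
    if cfg["mode"] == "synthetic":
        gen = GeneratorConfig(
            materials=tuple(cfg["materials"]) if cfg.get("materials") else None,
            rho_jet=cfg["jet"]["rho_0"],
            D_cb=cfg["geometry"]["D_cb"],
            H_wall=cfg["geometry"]["H_wall"],
            noise_sigma=cfg.get("noise_sigma", 0.0),
        )
        base = int(cfg["seed"])
        for k in range(int(cfg["n_experiments"])):
            exp = synthetic_data.sample_experiment(base + k, gen, materials)
            stack, truth = synthetic_data.render_stack(exp)
            row = {
                "experiment": k,
                "material": exp.material.name,
                "U_0": exp.jet.U_0,
                "D_0": exp.jet.D_0,
                "true_regime": exp.regime,
            }
            row.update(_describe_pairing(exp.jet, exp.material, exp.geometry, thr))
            row.update(_analyze_one(stack, cfg))
            rows.append(row)
            log.info("experiment %d (%s): %s", k, exp.material.name, row.get("observed_regime"))
    elif cfg["mode"] == "stacks":
        for k, d in enumerate(cfg["stack_dirs"]):
            row = {"experiment": k, "stack_dir": str(d)}
            try:
                stack, _ = synthetic_data.read_stack(d)
                row.update(_analyze_one(stack, cfg))
            except Exception as exc:  # per-item failure, run continues
                row["missing"] = f"unreadable stack: {exc}"
                log.error("stack %s failed: %s", d, exc)
            rows.append(row)
    else:
        raise ValueError(f"unknown mode {cfg['mode']!r}")
    return pd.DataFrame(rows)


def _describe_pairing(jet: JetSpec, material, geom: BridgeGeometry, thr: dict) -> dict:
    a = traversal.assess(jet, material, geom, threshold=thr["traversal"], warn=False)
    return {
        "We": a.We,
        "Oh": ohnesorge(material, geom.D_cb),
        "We_star": a.We_star,
        "We_over_We_star": a.ratio,
        "decision": a.decision,
        "predicted_regime": seal_classifier.predict_seal(
            a.We, ohnesorge(material, geom.D_cb), material.material_class, material.name
        ).regime,
        "caveat": a.caveat or "",
    }


def regime_map(
    config: dict | str | Path | None = None,
    we_grid: Optional[np.ndarray] = None,
    materials: Optional[dict] = None,
) -> pd.DataFrame:
    """Predicted seal regime over a (We, Oh, material) grid, for phase diagrams."""
    cfg = default_config() if config is None else (
        load_config(config) if not isinstance(config, dict) else {**default_config(), **config}
    )
    table = materials if materials is not None else load_materials()
    if cfg.get("materials"):
        table = {k: table[k] for k in cfg["materials"]}
    we_grid = np.geomspace(50, 2000, 25) if we_grid is None else np.asarray(we_grid)
    d_cb = cfg["geometry"]["D_cb"]
    rows = []
    for name, mat in table.items():
        oh = ohnesorge(mat, d_cb)
        for we in we_grid:
            pred = seal_classifier.predict_seal(float(we), oh, mat.material_class, name)
            rows.append(
                {"material": name, "class": mat.material_class,
                 "We": float(we), "Oh": oh, "regime": pred.regime}
            )
    return pd.DataFrame(rows)
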