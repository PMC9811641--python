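"""Seeded generator of ground-truthed synthetic shadowgraph experiments.

The generator emulates the study conditions: a dark capillary bridge
(default 6 mm diameter, 1 mm wall separation) imaged at 50k frames per
second on a 768 x 328 px sensor at 10 um per pixel, impacted by a jet with
``U_0 ~ U[8, 69.5] m/s`` and ``D_0 ~ U[50, 120] um``.  The target material
is drawn from the bundled property table; for gels, the impact speed is
redrawn until the elastic Froude number ``rho U_0^2 / G`` clears a
cavity-formation floor, since below a critical inertia a gel admits no
cavity at all.

Truth kinematics follow the package's own models: the front speed comes
from the cavity-velocity model, the expansion profile from the inertial
crater law (for low-Oh targets) or from the viscous droplet-train
superposition, the seal regime from the predictive rule set, and bubble
counts/areas are drawn from the regime's expected band.  All truth
quantities that the imaging pipeline is asked to recover (front positions,
areas, bubble census) are reported from the generator's *rendered* clean
geometry — pixel-quantised, exactly what a perfect segmentation would see —
so closed-loop tests measure metrology error, not model mismatch.

Rendering is deterministic given (seed, config); optional Gaussian pixel
noise is seeded separately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import cavity_models, seal_classifier
from .imaging import DEFAULT_DT, DEFAULT_PIXEL_SIZE, FrameStack
from .materials import BridgeGeometry, JetSpec, Material, load_materials, ohnesorge, weber

GRAY_BACKGROUND = 230
GRAY_BRIDGE = 70
GRAY_INJECTED = 30
GRAY_CAVITY = 230
FRAME_SHAPE = (328, 768)   # (rows, cols)
N_PRE_FRAMES = 5
FR_E_MIN = 100.0           # cavity-formation floor for gels
L_MAX_FLOOR = 3.0e-4       # m, minimum renderable cavity depth
L_MAX_CAP_FRACTION = 0.45  # of D_cb; confinement limits the depth
OH_INERTIAL_MAX = 0.01     # below this the inertial profile is the truth model

#: per-regime draw bands: (count_lo, count_hi_inclusive, local hole/area ratio lo-hi)
_REGIME_DRAWS = {
    "no_seal": (0, 0, 0.0, 0.0),
    "deep_seal": (2, 6, 0.45, 0.60),
    "shallow_seal": (4, 8, 0.50, 0.62),
    "surface_seal": (1, 1, 0.86, 0.93),
}


class RenderError(RuntimeError):
    """Requested render is geometrically inconsistent with the bridge."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic-experiment draw."""

    materials: Optional[tuple[str, ...]] = None     # None = all of Table fixture
    u0_range: tuple[float, float] = (8.0, 69.5)     # m/s
    d0_range: tuple[float, float] = (50e-6, 120e-6)  # m
    rho_jet: float = 1000.0                          # kg/m^3 (dyed water)
    D_cb: float = 6e-3
    H_wall: float = 1e-3
    n_frames: int = 250
    noise_sigma: float = 0.0
    fr_e_min: float = FR_E_MIN


@dataclass
class BubbleTruth:
    """Planned bubble chain of the post-collapse frame (pixel units)."""

    count: int
    radius_px: int
    outer_px: int
    centers_px: list[tuple[int, int]]  # (row, col) absolute


@dataclass
class SyntheticExperiment:
    """One ground-truthed draw: material, jet, geometry and truth plan."""

    seed: int
    material: Material
    jet: JetSpec
    geometry: BridgeGeometry
    regime: str
    rule: str
    U_c: float
    L_max: float
    t_grow: float
    t_ret: float
    pinch_fracs: tuple[float, ...]     # pinch positions as fractions of L_max
    dome_frac: Optional[float]         # dome-closure time as fraction of t_grow
    bubble_plan: BubbleTruth
    config: GeneratorConfig


def _draw_material(rng: np.random.Generator, config: GeneratorConfig,
                   table: dict[str, Material]) -> Material:
    names = tuple(config.materials) if config.materials else tuple(table)
    if not names:
        raise ValueError("empty material fixture")
    return table[names[rng.integers(len(names))]]


def sample_experiment(
    seed: int,
    config: GeneratorConfig = GeneratorConfig(),
    materials: Optional[dict[str, Material]] = None,
) -> SyntheticExperiment:
    """Reproducible draw of one synthetic experiment."""
    rng = np.random.default_rng(seed)
    table = materials if materials is not None else load_materials()
    material = _draw_material(rng, config, table)
    d0 = rng.uniform(*config.d0_range)
    u0 = rng.uniform(*config.u0_range)
    if material.G_storage:
        # gels need enough inertia to open a cavity at all
        u_min = math.sqrt(config.fr_e_min * material.G_storage / material.rho_cb)
        lo = max(config.u0_range[0], min(u_min, config.u0_range[1]))
        u0 = rng.uniform(lo, config.u0_range[1])
    jet = JetSpec(rho_0=config.rho_jet, D_0=d0, U_0=u0)
    geometry = BridgeGeometry(D_cb=config.D_cb, H_wall=config.H_wall)

    we = weber(jet, material)
    oh = ohnesorge(material, geometry.D_cb)
    pred = seal_classifier.predict_seal(we, oh, material.material_class, material.name)

    u_c = cavity_models.cavity_velocity_model(jet, material)
    from .traversal import max_depth

    h_max = max_depth(jet, material)
    l_max = min(max(h_max, L_MAX_FLOOR), L_MAX_CAP_FRACTION * geometry.D_cb)
    # guarantee a handful of resolvable expansion frames at 50 kfps
    l_max = max(l_max, 4.5 * u_c * DEFAULT_DT)
    t_grow = l_max / u_c

    # retraction rate: surface-tension-driven, linear in the peak area
    a_coeff = cavity_models.crater_growth_coefficient(jet)
    r_entry = math.sqrt(a_coeff * t_grow)
    a_max_est = (4.0 / 3.0) * r_entry * l_max
    v_cap = math.sqrt(material.gamma_cb / (material.rho_cb * geometry.D_cb))
    # collapse is resolved by several frames at 50 kfps in practice
    t_ret = max(a_max_est / (3.0 * v_cap * geometry.D_cb), 6.0 * DEFAULT_DT)

    regime = pred.regime
    lo, hi, r_lo, r_hi = _REGIME_DRAWS[regime]
    count = int(rng.integers(lo, hi + 1)) if hi else 0
    local_ratio = rng.uniform(r_lo, r_hi) if hi else 0.0
    if regime == "surface_seal":
        radius_px = int(rng.integers(40, 61))
    elif count:
        radius_px = int(rng.integers(7, 12))
    else:
        radius_px = 0
    outer_px = int(math.ceil(radius_px / math.sqrt(local_ratio))) if count else 0
    if count and outer_px - radius_px < 3:
        outer_px = radius_px + 3

    px = DEFAULT_PIXEL_SIZE
    pinch_fracs: tuple[float, ...] = ()
    dome_frac = None
    if regime == "deep_seal":
        pinch_fracs = (float(rng.uniform(0.45, 0.75)),)
    elif regime == "shallow_seal":
        # keep the pinch at least a few pixels off the mouth but within L/3
        frac = float(rng.uniform(0.12, 0.30))
        frac = min(max(frac, 9.0 * px / l_max), 0.30)
        pinch_fracs = (frac,)
    elif regime == "surface_seal":
        dome_frac = float(rng.uniform(0.5, 0.7))
    origin_col = 60
    axis_row = FRAME_SHAPE[0] // 2
    centers = []
    if count:
        spacing = max(2 * outer_px + 4, 2 * radius_px + 14)
        # keep every outer disk fully inside the bridge circle
        start = origin_col + max(outer_px + 4, 40, int(0.15 * l_max / px))
        for k in range(count):
            centers.append((axis_row, start + k * spacing))
    plan = BubbleTruth(count=count, radius_px=radius_px, outer_px=outer_px,
                       centers_px=centers)

    return SyntheticExperiment(
        seed=seed, material=material, jet=jet, geometry=geometry,
        regime=regime, rule=pred.rule, U_c=u_c, L_max=l_max,
        t_grow=t_grow, t_ret=t_ret, pinch_fracs=pinch_fracs,
        dome_frac=dome_frac, bubble_plan=plan, config=config,
    )


def _truth_profile(exp: SyntheticExperiment):
    """Callable R(x_m, tau_s) of the expansion-phase truth profile."""
    oh = ohnesorge(exp.material, exp.geometry.D_cb)
    if oh < OH_INERTIAL_MAX:
        a = cavity_models.crater_growth_coefficient(exp.jet)

        def profile(x, tau):
            tau_loc = tau - x / exp.U_c
            return np.sqrt(a * np.clip(tau_loc, 0.0, None))

        return profile

    train = cavity_models.train_from_jet(exp.jet)
    tau_grid = np.linspace(0.0, max(exp.t_grow, train.period) * 1.05, 256)
    # expansion-phase profile: capillary retraction is prescribed separately
    # by the retraction schedule, so the slice model runs dissipative-only
    r_drop = cavity_models.viscous_drop_cavity(
        train, exp.material, tau_grid, rho_jet=exp.jet.rho_0,
        include_surface_tension=False,
    )
    dh = 2.0 * train.r_d
    period = train.period

    def profile(x, tau):
        k = np.floor(np.asarray(x) / dh)
        t_k = k * period
        r = np.interp(np.clip(tau - t_k, 0.0, tau_grid[-1]), tau_grid, r_drop)
        return np.where(tau - t_k > 0, r, 0.0)

    return profile


def render_stack(
    exp: SyntheticExperiment,
    n_frames: Optional[int] = None,
    noise_sigma: Optional[float] = None,
    noise_seed: Optional[int] = None,
) -> tuple[FrameStack, dict]:
    """Render the experiment to a shadowgraph stack plus truth labels.

    Truth labels report the *rendered* (pixel-quantised) front positions,
    areas and bubble census, so a perfect metrology would recover them
    exactly.  Raises :class:`RenderError` for a cavity deeper than the
    bridge unless the jet genuinely traverses.
    """
    cfg = exp.config
    n_frames = cfg.n_frames if n_frames is None else n_frames
    sigma = cfg.noise_sigma if noise_sigma is None else noise_sigma
    h, w = FRAME_SHAPE
    px = DEFAULT_PIXEL_SIZE
    dt = DEFAULT_DT
    if n_frames == 0:
        stack = FrameStack(np.zeros((0, h, w), dtype=np.uint8), dt, px,
                           (h // 2, 60), (0, 1))
        return stack, {"n_frames": 0}

    if exp.L_max > exp.geometry.D_cb:
        from .traversal import assess

        if assess(exp.jet, exp.material, exp.geometry, warn=False).decision != "traverse":
            raise RenderError("cavity deeper than the bridge for an embedding jet")

    axis_row = h // 2
    origin_col = 60
    r_cb_px = exp.geometry.D_cb / 2.0 / px
    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)
    bridge = (rows - axis_row) ** 2 + (cols - (origin_col + r_cb_px)) ** 2 <= r_cb_px**2
    xi_px = cols - origin_col  # axial offset in px

    profile = _truth_profile(exp)
    jet_half_px = max(int(round(exp.jet.D_0 / 2.0 / px)), 2)

    t_close = exp.t_grow + exp.t_ret
    t_settle = t_close + 3 * dt  # liquid relaxes before bubbles are countable
    i_impact = N_PRE_FRAMES
    frames = np.empty((n_frames, h, w), dtype=np.uint8)

    truth_front = np.full(n_frames, np.nan)
    truth_area = np.zeros(n_frames)

    plan = exp.bubble_plan

    # final-frame masks (built once)
    blob = np.zeros((h, w), dtype=bool)
    holes = np.zeros((h, w), dtype=bool)
    if plan.count:
        prev = None
        for (r0, c0) in plan.centers_px:
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
            blob |= d2 <= plan.outer_px**2
            holes |= d2 <= plan.radius_px**2
            if prev is not None:
                lo_c, hi_c = sorted((prev[1], c0))
                corridor_half = max(3, plan.radius_px // 3)
                blob |= (
                    (np.abs(rows - r0) <= corridor_half)
                    & (cols >= lo_c) & (cols <= hi_c)
                )
            prev = (r0, c0)
        blob &= bridge
        holes &= blob
    elif exp.regime == "no_seal":
        # injected liquid only: a small dark ellipse near the entry
        c_blob = origin_col + max(30, int(0.2 * exp.L_max / px))
        blob = (
            ((cols - c_blob) / max(20, int(0.25 * exp.L_max / px))) ** 2
            + ((rows - axis_row) / 12.0) ** 2
        ) <= 1.0
        blob &= bridge

    base = np.full((h, w), GRAY_BACKGROUND, dtype=np.uint8)
    base[bridge] = GRAY_BRIDGE
    final = base.copy()
    final[blob] = GRAY_INJECTED
    final[holes] = GRAY_CAVITY
    jet_mask = np.zeros((h, w), dtype=bool)
    jet_mask[
        axis_row - jet_half_px : axis_row + jet_half_px + 1, :origin_col
    ] = True

    # cavity rasterisation runs on a cropped window around the axis
    r_cap_px = int(math.ceil(math.sqrt(
        cavity_models.crater_growth_coefficient(exp.jet) * exp.t_grow
    ) / px)) + 4
    row_lo = max(axis_row - r_cap_px, 0)
    row_hi = min(axis_row + r_cap_px + 1, h)
    col_lo = origin_col
    col_hi = min(origin_col + int(exp.L_max / px) + 4, w)
    sub_rows = np.abs(np.arange(row_lo, row_hi) - axis_row)[:, None]
    sub_xi = (np.arange(col_lo, col_hi) - origin_col).astype(float)[None, :]
    sub_bridge = bridge[row_lo:row_hi, col_lo:col_hi]
    sub_x_m = np.clip(sub_xi, 0.0, None) * px

    for i in range(n_frames):
        tau = (i - i_impact) * dt
        if 0.0 < tau <= t_close:
            frame = base.copy()
            if tau <= exp.t_grow:
                front_m = exp.U_c * tau
                scale = 1.0
            else:
                front_m = exp.L_max
                scale = max(0.0, 1.0 - (tau - exp.t_grow) / exp.t_ret)
            r_px = profile(sub_x_m, min(tau, exp.t_grow)) * scale / px
            front_px = front_m / px
            cavity = (
                sub_bridge
                & (sub_xi <= front_px)
                & (r_px >= 0.5)
                & (sub_rows <= r_px)
            )
            # pinch gaps: break the cavity into components during retraction
            if exp.pinch_fracs and tau > exp.t_grow + 0.5 * exp.t_ret:
                for frac in exp.pinch_fracs:
                    gc = frac * exp.L_max / px
                    cavity &= ~((sub_xi >= gc - 2) & (sub_xi <= gc + 2))
            # dome closure: seal the mouth while still expanding
            if exp.dome_frac is not None and tau >= exp.dome_frac * exp.t_grow:
                cavity &= ~(sub_xi <= 4)
            frame[row_lo:row_hi, col_lo:col_hi][cavity] = GRAY_CAVITY
            if tau <= exp.t_grow:
                frame[jet_mask] = GRAY_INJECTED
            occupied = np.nonzero(cavity.any(axis=0))[0]
            if occupied.size:
                truth_front[i] = occupied.max() * px
            truth_area[i] = cavity.sum() * px**2
            frames[i] = frame
        elif tau > t_settle:
            frames[i] = final
        else:
            frames[i] = base

    if sigma:
        rng = np.random.default_rng(
            noise_seed if noise_seed is not None else exp.seed + 1
        )
        noise = rng.standard_normal(frames.shape, dtype=np.float32)
        np.multiply(noise, sigma, out=noise)
        np.add(noise, frames, out=noise)
        np.clip(noise, 0, 255, out=noise)
        frames = noise.astype(np.uint8)

    stack = FrameStack(frames, dt=dt, pixel_size=px,
                       origin=(axis_row, origin_col), axis=(0, 1))
    i_peak = int(np.argmax(truth_area)) if truth_area.any() else 0
    a_blob = float(blob.sum()) * px**2
    a_holes = float(holes.sum()) * px**2
    truth = {
        "seed": exp.seed,
        "material": exp.material.name,
        "regime": exp.regime,
        "U_0": exp.jet.U_0,
        "D_0": exp.jet.D_0,
        "U_c": exp.U_c,
        "L_max": float(np.nanmax(truth_front)) if np.isfinite(truth_front).any() else 0.0,
        "A_max": float(truth_area[i_peak]),
        "i_A_max": i_peak,
        "t_col": exp.t_ret,
        "bubble_count": plan.count,
        "A_total": a_blob,
        "A_bubbles": a_holes,
        "ratio": a_holes / a_blob if a_blob else 0.0,
        "pinch_positions": [f * exp.L_max for f in exp.pinch_fracs],
        "dome_closed_during_expansion": exp.dome_frac is not None,
        "front_m": truth_front.tolist(),
        "n_frames": n_frames,
        "i_impact": i_impact,
    }
    return stack, truth


def inject_noise(stack: FrameStack, sigma: float, seed: int) -> FrameStack:
    """Additive clipped Gaussian pixel noise; sigma = 0 returns an identical copy."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    frames = stack.frames.copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noisy = frames.astype(float) + rng.normal(0.0, sigma, frames.shape)
        frames = np.clip(noisy, 0, 255).astype(np.uint8)
    return FrameStack(frames, stack.dt, stack.pixel_size, stack.origin, stack.axis)


def write_stack(stack: FrameStack, truth: dict, directory: str | Path) -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata/truth sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(directory / "stack.tif", stack.frames)
    sidecar = {
        "dt": stack.dt,
        "pixel_size": stack.pixel_size,
        "origin": list(stack.origin),
        "axis": list(stack.axis),
        "truth": truth,
    }
    (directory / "stack.json").write_text(json.dumps(sidecar, indent=1))


def read_stack(directory: str | Path) -> tuple[FrameStack, dict]:
    """Read a stack written by :func:`write_stack`."""
    import tifffile

    directory = Path(directory)
    frames = tifffile.imread(directory / "stack.tif")
    meta = json.loads((directory / "stack.json").read_text())
    stack = FrameStack(
        frames, meta["dt"], meta["pixel_size"],
        tuple(meta["origin"]), tuple(meta["axis"]),
    )
    return stack, meta.get("truth", {})
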