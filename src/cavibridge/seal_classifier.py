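"""Four-way seal-regime logic for the collapsing cavity.

Observed regimes (from cavity kinematics):

* ``no_seal``      — the cavity retracts without pinching; no bubbles.
* ``shallow_seal`` — pinch-off close to the jet entry point, operationalised
  as pinch position ``x_p <= L_max/3`` (the complement of the deep-seal
  rule, so the partition is exhaustive and exclusive).
* ``deep_seal``    — pinch-off deeper than one third of the maximum depth.
* ``surface_seal`` — an overarching dome closes over the cavity mouth (at
  ``x < x_0``, the entry side of the impact point) while the cavity front is
  still advancing.

Predicted regimes (from (We, Oh, material class)) mirror the experimental
regime map: agarose gels always shallow-seal; viscoelastic PEO solutions
deep-seal inside material-specific Weber windows; low-viscosity Newtonian
liquids (Oh <~ 0.004 on the bridge scale) surface-seal for We <~ 700;
everything else does not seal.  Note the surface-seal bound is implemented
as the upper We bound it was reported as, although surface seal classically
appears at *high* We — a flagged oddity of the source data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

REGIMES = ("no_seal", "deep_seal", "shallow_seal", "surface_seal")

#: Deep-seal Weber windows (closed intervals) per viscoelastic material.
DEEP_SEAL_WINDOWS: dict[str, tuple[float, float]] = {
    "peo_600k_01wt": (500.0, 600.0),
    "peo_600k_10wt": (400.0, 700.0),
    "peo_1m_10wt": (500.0, 900.0),
}
#: Class-level fallback window: union of the per-material windows.
DEEP_SEAL_FALLBACK = (400.0, 900.0)

SURFACE_SEAL_OH_MAX = 0.004
SURFACE_SEAL_WE_MAX = 700.0

#: Expected bubble outcome per regime: (ratio_lo, ratio_hi, count_lo, count_hi).
BUBBLE_BANDS: dict[str, tuple[float, float, int, int]] = {
    "no_seal": (0.0, 0.0, 0, 0),
    "deep_seal": (0.0, 0.6, 2, 10),
    "shallow_seal": (0.35, 0.65, 4, 10),
    "surface_seal": (0.8, 1.0, 1, 2),
}


@dataclass(frozen=True)
class SealOutcome:
    """Result of observational seal classification."""

    regime: str
    pinch_position: Optional[float] = None  # m
    pinch_count: int = 0
    dome_closed_during_expansion: bool = False
    t_col: Optional[float] = None  # s

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.pinch_count < 0:
            raise ValueError("pinch count must be non-negative")


@dataclass(frozen=True)
class SealPrediction:
    regime: str
    rule: str


@dataclass(frozen=True)
class BubbleExpectation:
    """Qualitative expectation for A_bubbles/A_total and bubble count."""

    regime: str
    ratio_low: float
    ratio_high: float
    count_low: int
    count_high: int


def classify_seal_observed(
    L_max: float,
    pinch_positions: Sequence[float] = (),
    dome_closed_during_expansion: bool = False,
    t_col: Optional[float] = None,
) -> SealOutcome:
    """Deterministic observational classification.

    Precedence: surface seal (dome closure during expansion), then deep seal
    (any pinch deeper than L_max/3), then shallow seal (any pinch), else no
    seal.  A pinch reported beyond L_max is inconsistent with the trajectory
    and rejected.
    """
    if L_max < 0:
        raise ValueError("L_max must be non-negative")
    pinch_positions = list(pinch_positions)
    for x_p in pinch_positions:
        if x_p < 0 or x_p > L_max * (1 + 1e-9):
            raise ValueError(f"pinch position {x_p} outside cavity [0, {L_max}]")
    if dome_closed_during_expansion:
        regime = "surface_seal"
    elif any(x_p > L_max / 3.0 for x_p in pinch_positions):
        regime = "deep_seal"
    elif pinch_positions:
        regime = "shallow_seal"
    else:
        regime = "no_seal"
    deepest = max(pinch_positions) if pinch_positions else None
    return SealOutcome(
        regime=regime,
        pinch_position=deepest,
        pinch_count=len(pinch_positions),
        dome_closed_during_expansion=dome_closed_during_expansion,
        t_col=t_col,
    )


def predict_seal(
    We: float,
    Oh: float,
    material_class: str,
    material_name: Optional[str] = None,
) -> SealPrediction:
    """Rule-based regime prediction from (We, Oh, material class).

    Rule precedence: material class first (gels always shallow-seal), then
    the viscoelastic deep-seal Weber windows, then the Newtonian
    (Oh, We) surface-seal rule; otherwise no seal.
    """
    if We < 0 or Oh < 0:
        raise ValueError("We and Oh must be non-negative")
    if material_class == "gel":
        return SealPrediction(
            "shallow_seal", "gel targets shallow-seal at all explored conditions"
        )
    if material_class == "viscoelastic":
        lo, hi = DEEP_SEAL_WINDOWS.get(material_name, DEEP_SEAL_FALLBACK)
        if lo <= We <= hi:
            return SealPrediction(
                "deep_seal", f"viscoelastic deep-seal window We in [{lo}, {hi}]"
            )
        return SealPrediction("no_seal", "viscoelastic outside deep-seal window")
    if material_class == "newtonian":
        if Oh <= SURFACE_SEAL_OH_MAX and We <= SURFACE_SEAL_WE_MAX:
            return SealPrediction(
                "surface_seal",
                f"Newtonian with Oh <= {SURFACE_SEAL_OH_MAX} and We <= {SURFACE_SEAL_WE_MAX}",
            )
        return SealPrediction("no_seal", "Newtonian outside surface-seal window")
    raise ValueError(f"unknown material class {material_class!r}")


def fit_collapse_scaling(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """Least-squares line t_col = slope * A_max + intercept.

    Returns (slope, intercept, residual standard error of the slope).
    Collapse of the cavity is surface-tension driven, so the collapse time
    grows linearly with the maximum cavity area across liquids of similar
    surface tension.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (A_max, t_col) pairs")
    a, t = pairs[:, 0], pairs[:, 1]
    if np.ptp(a) == 0:
        raise np.linalg.LinAlgError("degenerate fit: A_max is constant")
    res = stats.linregress(a, t)
    return float(res.slope), float(res.intercept), float(res.stderr)


def expected_bubble_outcome(regime: str) -> BubbleExpectation:
    """Qualitative bubble-entrainment band implied by a seal regime.

    no seal traps nothing; deep seal traps several pinch-off bubbles with
    A_bubbles/A_total <= 0.6; shallow seal traps several small bubbles at a
    ratio near 0.5; surface seal traps most of the cavity as one large
    bubble (ratio near 1).
    """
    if regime not in BUBBLE_BANDS:
        raise ValueError(f"unknown regime {regime!r}")
    lo, hi, c_lo, c_hi = BUBBLE_BANDS[regime]
    return BubbleExpectation(regime, lo, hi, c_lo, c_hi)
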