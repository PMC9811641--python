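"""Traverse/embed prediction: collapse time, critical Weber number, classifier.

A jet traverses the bridge when the cavity's maximum depth
``H_max = (U_0/2) t_c`` exceeds the bridge diameter ``D_cb`` before the
capillary collapse at ``t_c`` cuts the cavity off.  Surface tension dominates
the collapse: each axial slice carries a radial momentum ``a/2`` per unit
density (``a = beta D_0 U_0`` the crater-growth coefficient) which the
capillary pressure at the jet-scale curvature, ``2 gamma_cb / D_0``, cancels
after

    t_c = beta rho_cb U_0 D_0^2 / (4 gamma_cb).

Eliminating ``U_0`` in favour of the Weber number turns ``H_max = D_cb`` into
a critical Weber number

    We* = 8 (rho_0 / rho_cb) D_cb / (beta D_0),

and the measured boundary is expressed as a threshold on ``We/We*``
(default 0.7, the value found for unconfined pendant droplets; wall
confinement raises the true boundary, which is why the prediction carries
material-dependent caveats below).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .materials import BridgeGeometry, JetSpec, Material, weber

DEFAULT_THRESHOLD = 0.7

#: Reported model-experiment deviations of the traversal boundary per
#: material (fractional misfit of We*; the stiffest gel is off by an order
#: of magnitude, attributed to the property relations extrapolating badly).
KNOWN_MISFITS: dict[str, str] = {
    "viscoelastic": "traversal boundary deviates by ~50% for PEO solutions "
    "(relaxation-time effects not modelled)",
    "agarose_025wt": "traversal boundary deviates by ~30% for agarose 0.25 wt%",
    "agarose_050wt": "traversal boundary off by an order of magnitude for "
    "agarose 0.50 wt% (effective surface tension likely overestimated)",
}


@dataclass(frozen=True)
class TraversalAssessment:
    """Outcome of the traverse/embed prediction for one jet/bridge pairing."""

    t_c: float
    H_max: float
    We: float
    We_star: float
    ratio: float
    decision: str
    threshold: float = DEFAULT_THRESHOLD
    caveat: Optional[str] = None

    def __post_init__(self) -> None:
        if self.t_c < 0:
            raise ValueError("collapse time must be non-negative")
        if not math.isclose(self.ratio, self.We / self.We_star, rel_tol=1e-9):
            raise ValueError("ratio must equal We/We*")


def collapse_time(jet: JetSpec, target: Material, beta: float = 1.0) -> float:
    """Surface-tension-limited cavity collapse time (s)."""
    return beta * target.rho_cb * jet.U_0 * jet.D_0**2 / (4.0 * target.gamma_cb)


def max_depth(jet: JetSpec, target: Material, beta: float = 1.0) -> float:
    """Predicted maximum cavity depth H_max = (U_0/2) t_c (m)."""
    return 0.5 * jet.U_0 * collapse_time(jet, target, beta)


def critical_weber(
    D_cb: float, jet: JetSpec, target: Material, beta: float = 1.0
) -> float:
    """Critical Weber number We* at which H_max equals the bridge diameter."""
    if D_cb <= 0:
        raise ValueError("bridge diameter must be positive")
    return 8.0 * (jet.rho_0 / target.rho_cb) * D_cb / (beta * jet.D_0)


def classify_traversal(
    We: float, We_star: float, threshold: float = DEFAULT_THRESHOLD
) -> str:
    """``"traverse"`` iff We/We* >= threshold (closed boundary), else ``"embed"``."""
    if We < 0 or We_star <= 0:
        raise ValueError("We must be non-negative and We* positive")
    return "traverse" if We / We_star >= threshold else "embed"


def _caveat_for(target: Material) -> Optional[str]:
    if target.name in KNOWN_MISFITS:
        return KNOWN_MISFITS[target.name]
    if target.material_class == "viscoelastic":
        return KNOWN_MISFITS["viscoelastic"]
    return None


def assess(
    jet: JetSpec,
    target: Material,
    geom: BridgeGeometry,
    threshold: float = DEFAULT_THRESHOLD,
    beta: float = 1.0,
    warn: bool = True,
) -> TraversalAssessment:
    """Full traverse/embed assessment, with known-misfit caveats attached."""
    t_c = collapse_time(jet, target, beta)
    We = weber(jet, target)
    We_star = critical_weber(geom.D_cb, jet, target, beta)
    caveat = _caveat_for(target)
    if caveat and warn:
        warnings.warn(caveat, stacklevel=2)
    return TraversalAssessment(
        t_c=t_c,
        H_max=0.5 * jet.U_0 * t_c,
        We=We,
        We_star=We_star,
        ratio=We / We_star,
        decision=classify_traversal(We, We_star, threshold),
        threshold=threshold,
        caveat=caveat,
    )


def classify_batch(
    frame: pd.DataFrame,
    materials: dict[str, Material],
    rho_jet: float = 1000.0,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Batch classification of rows (material, U_0, D_0, D_cb).

    Returns a copy with We, We_star, ratio, decision and caveat columns
    appended; speeds in m/s, lengths in m.
    """
    rows = []
    for rec in frame.itertuples(index=False):
        target = materials[rec.material]
        jet = JetSpec(rho_0=rho_jet, D_0=rec.D_0, U_0=rec.U_0)
        a = assess(jet, target, BridgeGeometry(D_cb=rec.D_cb), threshold, warn=False)
        rows.append(
            {
                "material": rec.material,
                "U_0": rec.U_0,
                "D_0": rec.D_0,
                "D_cb": rec.D_cb,
                "We": a.We,
                "We_star": a.We_star,
                "ratio": a.ratio,
                "decision": a.decision,
                "caveat": a.caveat or "",
            }
        )
    return pd.DataFrame(rows)
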