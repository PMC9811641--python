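"""Capillary-bridge energetics on the confining walls.

A bridge of height ``H`` meeting both walls at the equilibrium contact angle
``theta_E`` has an axial interface curvature ``-2 cos(theta_E)/H``, hence a
Laplace pressure

    dP = -2 gamma_cb cos(theta_E) / H,

negative (suction) for a concave bridge on hydrophilic walls and positive
for a convex bridge on hydrophobic walls.  The vertical adhesive force on a
wall combines the line tension along the contact perimeter with the pressure
acting over the contact disk,

    F_a = 2 pi gamma_cb R_c sin(theta_E) - pi R_c^2 dP,

positive meaning attraction to the walls.  Contact-angle hysteresis
(theta_a > theta_r) pins the contact line and dissipates energy at a rate
set per unit travel by

    Phi_cl = 2 pi R_c gamma_cb |cos(theta_a) - cos(theta_r)|,

a force; converting it to an energy requires the contact-line travel
distance, which is an explicit user input here (it is not determined by the
wetting parameters alone).  A Worthington jet after cavity collapse is
energetically favourable only when the walls neither grip the bridge
(F_a <= 0) nor eat the jet's kinetic energy through contact-line
dissipation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .materials import JetSpec

__all__ = [
    "WettabilityResult",
    "laplace_pressure",
    "adhesion_force",
    "contact_line_dissipation",
    "dissipation_energy",
    "jet_kinetic_energy",
    "worthington_favourable",
    "split_hysteresis",
    "assess_walls",
]


@dataclass(frozen=True)
class WettabilityResult:
    """Energetics of one wall configuration."""

    delta_P: float          # Pa
    F_a: float              # N
    Phi_cl: float           # N (magnitude of the contact-line force term)
    E_kjet: float           # J
    worthington_favourable: bool
    note: str = ""


def laplace_pressure(
    gamma_cb: float, theta_E: float, H_wall: float, in_plane_radius: Optional[float] = None
) -> float:
    """Laplace pressure of the bridge, axial-curvature form by default.

    dP = -2 gamma cos(theta_E)/H; passing ``in_plane_radius`` adds the
    in-plane curvature term ``+gamma/R_c`` (variant form; the axial-only
    default is the one validated against the worked adhesion forces).
    """
    if not 0.0 < theta_E < math.pi:
        raise ValueError("theta_E must lie strictly in (0, pi)")
    if H_wall <= 0 or gamma_cb <= 0:
        raise ValueError("gamma and H must be positive")
    dp = -2.0 * gamma_cb * math.cos(theta_E) / H_wall
    if in_plane_radius is not None:
        if in_plane_radius <= 0:
            raise ValueError("in-plane radius must be positive")
        dp += gamma_cb / in_plane_radius
    return dp


def adhesion_force(
    gamma_cb: float, R_c: float, theta_E: float, delta_P: float
) -> float:
    """Vertical adhesive force F_a = 2 pi gamma R_c sin(theta_E) - pi R_c^2 dP."""
    if R_c <= 0:
        raise ValueError("contact radius must be positive")
    return 2.0 * math.pi * gamma_cb * R_c * math.sin(theta_E) - math.pi * R_c**2 * delta_P


def contact_line_dissipation(
    R_c: float, gamma_cb: float, theta_a: float, theta_r: float
) -> float:
    """Magnitude of the hysteresis force 2 pi R_c gamma (cos theta_a - cos theta_r).

    Zero exactly at zero hysteresis (theta_a == theta_r).
    """
    if theta_a < theta_r:
        raise ValueError("advancing angle must be >= receding angle")
    if R_c <= 0 or gamma_cb <= 0:
        raise ValueError("R_c and gamma must be positive")
    return abs(2.0 * math.pi * R_c * gamma_cb * (math.cos(theta_a) - math.cos(theta_r)))


def dissipation_energy(phi_cl: float, travel_length: float) -> float:
    """Energy dissipated by the contact line over a given travel distance (J)."""
    if travel_length < 0:
        raise ValueError("travel length must be non-negative")
    return phi_cl * travel_length


def jet_kinetic_energy(jet: JetSpec) -> float:
    """Kinetic energy of the jet, E_kjet = (pi/8) rho_0 U_0^2 D_0^2 L_0 (J)."""
    if jet.L_0 is None:
        raise ValueError("jet length L_0 is required for the kinetic energy")
    return math.pi / 8.0 * jet.rho_0 * jet.U_0**2 * jet.D_0**2 * jet.L_0


def worthington_favourable(
    E_kjet: float,
    dissipation: float,
    F_a: float,
    energy_fraction: float = 0.5,
) -> bool:
    """Whether a Worthington jet is energetically favourable.

    Favourable iff the contact-line dissipation energy stays below
    ``energy_fraction`` of the jet kinetic energy *and* the walls do not
    attract the bridge (F_a <= 0).  A jet with no kinetic energy is never
    favourable.
    """
    if E_kjet < 0 or dissipation < 0:
        raise ValueError("energies must be non-negative")
    if E_kjet == 0:
        return False
    return dissipation <= energy_fraction * E_kjet and F_a <= 0


def split_hysteresis(theta_E: float, hysteresis: float) -> tuple[float, float]:
    """(theta_a, theta_r) from a hysteresis width split symmetrically about theta_E."""
    if hysteresis < 0:
        raise ValueError("hysteresis must be non-negative")
    return theta_E + hysteresis / 2.0, theta_E - hysteresis / 2.0


def assess_walls(
    gamma_cb: float,
    theta_E: float,
    R_c: float,
    H_wall: float,
    jet: JetSpec,
    theta_a: Optional[float] = None,
    theta_r: Optional[float] = None,
    hysteresis: float = 0.0,
    travel_length: Optional[float] = None,
    mixed: bool = False,
    energy_fraction: float = 0.5,
) -> WettabilityResult:
    """Full wettability assessment of one wall pair.

    ``mixed=True`` marks a hydrophilic-hydrophobic pairing, which collapses
    asymmetrically and is categorically unfavourable for a Worthington jet
    regardless of the energy budget.
    """
    if theta_a is None or theta_r is None:
        theta_a, theta_r = split_hysteresis(theta_E, hysteresis)
    dp = laplace_pressure(gamma_cb, theta_E, H_wall)
    fa = adhesion_force(gamma_cb, R_c, theta_E, dp)
    phi = contact_line_dissipation(R_c, gamma_cb, theta_a, theta_r)
    e_k = jet_kinetic_energy(jet)
    travel = travel_length if travel_length is not None else 2.0 * R_c
    e_diss = dissipation_energy(phi, travel)
    if mixed:
        fav = False
        note = "mixed hydrophilic-hydrophobic walls: asymmetric collapse, never favourable"
    else:
        fav = worthington_favourable(e_k, e_diss, fa, energy_fraction)
        note = (
            "hydrophobic-like: free contact line, Worthington jet favourable"
            if fav
            else "contact line pinned or dissipation-dominated: jet suppressed"
        )
    return WettabilityResult(
        delta_P=dp, F_a=fa, Phi_cl=phi, E_kjet=e_k,
        worthington_favourable=fav, note=note,
    )


def assess_scenario_file(path: str | Path) -> dict[str, WettabilityResult]:
    """Evaluate a plain-text scenario of wall configurations.

    The file is ``key = value`` lines; ``[section]`` headers open one wall
    configuration each.  Global keys: ``gamma_mN_m``, ``H_mm``, jet
    parameters ``rho_0``, ``D_0_um``, ``U_0``, ``L_0_mm``.  Per-section
    keys: ``theta_E_deg``, ``R_c_mm``, ``hysteresis_deg`` (default 0) and
    ``mixed`` (true/false).  Returns a result per section.
    """
    globals_: dict[str, float] = {}
    sections: dict[str, dict] = {}
    current: Optional[str] = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            sections[current] = {}
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        parsed = (
            value.lower() == "true"
            if value.lower() in ("true", "false")
            else float(value)
        )
        (sections[current] if current else globals_)[key] = parsed
    jet = JetSpec(
        rho_0=globals_.get("rho_0", 1000.0),
        D_0=globals_.get("D_0_um", 100.0) * 1e-6,
        U_0=globals_.get("U_0", 40.0),
        L_0=globals_.get("L_0_mm", 19.0) * 1e-3,
    )
    gamma = globals_.get("gamma_mN_m", 72.1) * 1e-3
    h_wall = globals_.get("H_mm", 1.0) * 1e-3
    out: dict[str, WettabilityResult] = {}
    for name, sec in sections.items():
        out[name] = assess_walls(
            gamma_cb=gamma,
            theta_E=math.radians(sec["theta_E_deg"]),
            R_c=sec["R_c_mm"] * 1e-3,
            H_wall=h_wall,
            jet=jet,
            hysteresis=math.radians(sec.get("hysteresis_deg", 0.0)),
            mixed=bool(sec.get("mixed", False)),
        )
    return out
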