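"""Material records, agarose property relations and dimensionless groups.

The capillary-bridge targets span three material classes: Newtonian liquids
(water, aqueous glycerol), viscoelastic PEO solutions characterised by a
relaxation time ``lambda``, and agarose gels characterised by a storage
modulus ``G``.  For the gels, surface tension and shear viscosity are not
measured directly but assigned through empirical linear relations in ``G``
(:func:`agarose_properties`).

All quantities are SI internally (kg, m, s); the bundled property table is
stored in the mixed units it is conventionally printed in (mPa s, mN/m, ms)
and converted on load.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pandas as pd

G_GRAVITY = 9.81  # m s^-2

# Empirical linear relations assigning effective surface tension (N/m) and
# shear viscosity (Pa s) to an agarose gel of storage modulus G (Pa).
AGAROSE_GAMMA_SLOPE = 0.001022
AGAROSE_GAMMA_INTERCEPT = 0.072292
AGAROSE_MU_SLOPE = 6.005e-5
AGAROSE_MU_INTERCEPT = 0.00834

# Experimental validity windows for the jet parameters (warn outside).
U0_VALID = (8.0, 69.5)        # m/s
D0_VALID = (50e-6, 120e-6)    # m


class InvalidMaterialError(ValueError):
    """Raised for physically inadmissible material parameters."""


class NotViscoelasticError(TypeError):
    """Raised when a relaxation-time quantity is requested of a material without one."""


class NotGelError(TypeError):
    """Raised when a storage-modulus quantity is requested of a non-gel."""


@dataclass(frozen=True)
class Material:
    """Bulk properties of a capillary-bridge substance.

    Parameters
    ----------
    name : str
        Label, e.g. ``"water"`` or ``"agarose_015wt"``.
    rho_cb : float
        Density (kg/m^3).
    mu_cb : float
        Shear viscosity (Pa s).
    gamma_cb : float
        Surface tension (N/m).
    lambda_relax : float, optional
        Viscoelastic relaxation time (s).  Present iff viscoelastic.
    G_storage : float, optional
        Storage modulus (Pa).  Present iff gel.
    """

    name: str
    rho_cb: float
    mu_cb: float
    gamma_cb: float
    lambda_relax: Optional[float] = None
    G_storage: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rho_cb <= 0 or self.mu_cb <= 0 or self.gamma_cb <= 0:
            raise InvalidMaterialError(
                f"{self.name}: rho, mu, gamma must all be positive"
            )
        if self.lambda_relax is not None and self.lambda_relax < 0:
            raise InvalidMaterialError(f"{self.name}: negative relaxation time")
        if self.G_storage is not None and self.G_storage < 0:
            raise InvalidMaterialError(f"{self.name}: negative storage modulus")
        if self.lambda_relax is not None and self.G_storage is not None:
            raise InvalidMaterialError(
                f"{self.name}: a material cannot be both viscoelastic and a gel"
            )

    @property
    def material_class(self) -> str:
        """``"viscoelastic"`` iff a relaxation time is present, ``"gel"`` iff a
        storage modulus is present, else ``"newtonian"``."""
        if self.lambda_relax is not None:
            return "viscoelastic"
        if self.G_storage is not None:
            return "gel"
        return "newtonian"


@dataclass(frozen=True)
class JetSpec:
    """Impacting microfluidic jet: liquid density, diameter, speed and length.

    ``U_0`` and ``D_0`` outside the experimentally explored windows
    ([8, 69.5] m/s and [50, 120] um by default) trigger a warning but are
    accepted.
    """

    rho_0: float                      # kg/m^3
    D_0: float                        # m
    U_0: float                        # m/s
    L_0: Optional[float] = None       # m
    gamma_0: Optional[float] = None   # N/m (carried, unused by We)
    u0_window: tuple = U0_VALID
    d0_window: tuple = D0_VALID

    def __post_init__(self) -> None:
        if self.rho_0 <= 0 or self.D_0 <= 0 or self.U_0 < 0:
            raise ValueError("jet density/diameter must be positive, U_0 >= 0")
        for val in (self.L_0, self.gamma_0):
            if val is not None and val <= 0:
                raise ValueError("optional jet parameters must be positive if given")
        lo, hi = self.u0_window
        if self.U_0 and not lo <= self.U_0 <= hi:
            warnings.warn(
                f"U_0={self.U_0} m/s outside validated window [{lo}, {hi}] m/s",
                stacklevel=2,
            )
        lo, hi = self.d0_window
        if not lo <= self.D_0 <= hi:
            warnings.warn(
                f"D_0={self.D_0} m outside validated window [{lo}, {hi}] m",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BridgeGeometry:
    """Confinement geometry: bridge diameter, wall separation and wetting angles."""

    D_cb: float = 6e-3            # bridge diameter in the impact plane (m)
    H_wall: float = 1e-3          # wall separation (m)
    R_c: float = 2.5e-3           # wall contact radius (m)
    theta_E_top: float = math.radians(23.0)
    theta_E_bottom: float = math.radians(23.0)
    theta_a: float = math.radians(32.0)
    theta_r: float = math.radians(14.0)

    def __post_init__(self) -> None:
        if self.D_cb <= 0 or self.H_wall <= 0 or self.R_c <= 0:
            raise ValueError("geometric lengths must be positive")
        for th in (self.theta_E_top, self.theta_E_bottom, self.theta_a, self.theta_r):
            if not 0.0 < th < math.pi:
                raise ValueError("contact angles must lie strictly in (0, pi)")
        if self.theta_a < self.theta_r:
            raise ValueError("advancing angle must be >= receding angle")


@dataclass(frozen=True)
class DimensionlessSet:
    """All dimensionless groups of a jet/target pairing plus the capillary time."""

    We: float
    Fr: float
    Oh: float
    Re: float
    De: float = 0.0
    Fr_e: float = 0.0
    tau_c: float = 0.0
    g: float = G_GRAVITY


def weber(jet: JetSpec, target: Material) -> float:
    """Weber number We = rho_0 D_0 U_0^2 / gamma_cb.

    Jet density and diameter against the *target's* surface tension: the
    cavity has to be opened against the target interface, so We measures jet
    inertia relative to target capillarity.
    """
    if target.gamma_cb <= 0:
        raise InvalidMaterialError("target surface tension must be positive")
    return jet.rho_0 * jet.D_0 * jet.U_0**2 / target.gamma_cb


def froude(jet: JetSpec) -> float:
    """Froude number Fr = U_0^2 / (g D_0); gravity is irrelevant when Fr >> 1."""
    return jet.U_0**2 / (G_GRAVITY * jet.D_0)


def ohnesorge(target: Material, length: float) -> float:
    """Ohnesorge number Oh = mu / sqrt(rho gamma L) of the target.

    ``length`` is the scale the viscous-capillary balance is evaluated at:
    the jet diameter for impact-scale arguments, the bridge diameter for the
    seal-regime map (the bridge sets the collapse scale).
    """
    if length <= 0:
        raise ValueError("length scale must be positive")
    return target.mu_cb / math.sqrt(target.rho_cb * target.gamma_cb * length)


def reynolds(target: Material, U_0: float, D_0: float) -> float:
    """Impact-scale Reynolds number of the target, Re = rho_cb U_0 D_0 / mu_cb."""
    return target.rho_cb * U_0 * D_0 / target.mu_cb


def agarose_properties(G: float) -> tuple[float, float]:
    """Effective (gamma_cb, mu_cb) of an agarose gel from its storage modulus.

    gamma = 0.001022 G + 0.072292   [N/m]
    mu    = 6.005e-5 G + 0.00834    [Pa s]

    Calibrated on dilute gels (G <~ 200 Pa); extrapolation to stiff gels
    overestimates the surface tension, which is why the bundled table stores
    measured/printed values rather than recomputing them from these relations.
    """
    if G < 0:
        raise ValueError("storage modulus must be non-negative")
    gamma = AGAROSE_GAMMA_SLOPE * G + AGAROSE_GAMMA_INTERCEPT
    mu = AGAROSE_MU_SLOPE * G + AGAROSE_MU_INTERCEPT
    return gamma, mu


def capillary_time(target: Material, geom: BridgeGeometry, convention: str = "standard") -> float:
    """Capillary time of the bridge.

    ``"standard"``: tau_c = sqrt(rho_cb D_cb^3 / gamma_cb), the inertio-capillary
    time (dimensionally a time; the default).  ``"printed"``: the literal form
    rho_cb D_cb / gamma_cb sometimes quoted, which is not dimensionally a time
    and is provided for comparison only.
    """
    if convention == "standard":
        return math.sqrt(target.rho_cb * geom.D_cb**3 / target.gamma_cb)
    if convention == "printed":
        return target.rho_cb * geom.D_cb / target.gamma_cb
    raise ValueError(f"unknown capillary-time convention {convention!r}")


def deborah(target: Material, geom: BridgeGeometry, convention: str = "standard") -> float:
    """Deborah number De = lambda / tau_c of a viscoelastic target."""
    if target.lambda_relax is None:
        raise NotViscoelasticError(f"{target.name} has no relaxation time")
    return target.lambda_relax / capillary_time(target, geom, convention)


def elastic_froude(target: Material, U_0: float) -> float:
    """Elastic Froude number Fr_e = rho_cb U_0^2 / G (gel targets only)."""
    if target.G_storage is None:
        raise NotGelError(f"{target.name} has no storage modulus")
    if target.G_storage <= 0:
        raise NotGelError("storage modulus must be positive for Fr_e")
    return target.rho_cb * U_0**2 / target.G_storage


def impact_shear_rate(jet: JetSpec) -> float:
    """Characteristic shear rate during impact, U_0/D_0 (~1e5 1/s here)."""
    return jet.U_0 / jet.D_0


def dimensionless_set(
    jet: JetSpec, target: Material, geom: BridgeGeometry
) -> DimensionlessSet:
    """Assemble every dimensionless group the downstream models use."""
    tau = capillary_time(target, geom)
    return DimensionlessSet(
        We=weber(jet, target),
        Fr=froude(jet),
        Oh=ohnesorge(target, geom.D_cb),
        Re=reynolds(target, jet.U_0, jet.D_0),
        De=(target.lambda_relax / tau if target.lambda_relax is not None else 0.0),
        Fr_e=(
            elastic_froude(target, jet.U_0)
            if target.G_storage is not None and target.G_storage > 0
            else 0.0
        ),
        tau_c=tau,
    )


def load_material_table() -> pd.DataFrame:
    """Bundled property table (printed units) as a DataFrame keyed by name."""
    with resources.files("cavibridge.data").joinpath("material_properties.csv").open() as fh:
        return pd.read_csv(fh)


def load_materials() -> dict[str, Material]:
    """Bundled property table converted to SI :class:`Material` records."""
    table = load_material_table()
    out: dict[str, Material] = {}
    for row in table.itertuples(index=False):
        out[row.name] = Material(
            name=row.name,
            rho_cb=float(row.rho_kg_m3),
            mu_cb=float(row.mu_mPa_s) * 1e-3,
            gamma_cb=float(row.gamma_mN_m) * 1e-3,
            lambda_relax=(
                None if pd.isna(row.lambda_ms) else float(row.lambda_ms) * 1e-3
            ),
            G_storage=(None if pd.isna(row.G_Pa) else float(row.G_Pa)),
        )
    return out
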