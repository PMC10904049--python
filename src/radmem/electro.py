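"""Membrane surface electrostatics for peripheral protein partitioning.

The cytoplasmic leaflet of the plasma membrane carries a negative surface
potential (of order -35 mV) generated by anionic phospholipids.  A protein
of net charge ``z`` equilibrating between the bulk cytoplasm and that
surface is enriched (or depleted) by the Boltzmann factor
``exp(-z F V / (R T))``; protons partition the same way, so the pH at the
surface is lower than in the bulk.  Away from the surface the potential
decays exponentially with the Debye screening length of the cytoplasmic
electrolyte.  This module implements those closed forms in the linearized
(Debye-Hueckel) regime; nonlinear Gouy-Chapman theory is out of scope.

Units: potentials in mV at the interface of every public function
(converted to volts internally), lengths in nm, ionic strength in mol/L,
temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import constants

#: CODATA physical constants (SI).
FARADAY = constants.value("Faraday constant")          # C/mol
GAS_CONSTANT = constants.R                              # J/(K mol)
BOLTZMANN = constants.k                                 # J/K
AVOGADRO = constants.N_A                                # 1/mol
ELEMENTARY_CHARGE = constants.e                         # C
VACUUM_PERMITTIVITY = constants.epsilon_0               # F/m

#: Exponent magnitude beyond which exp() is reported as +/-inf with a flag.
_OVERFLOW_EXPONENT = 700.0


@dataclass(frozen=True)
class MembraneModel:
    """Parameters of the charged-surface / electrolyte system.

    Attributes
    ----------
    v0 : float
        Electrostatic potential at the membrane surface, mV (signed;
        the cytoplasmic leaflet is negative).
    ionic_strength : float
        1:1 electrolyte concentration, mol/L.
    temperature : float
        Absolute temperature, K.
    relative_permittivity : float
        Dielectric constant of the aqueous phase.
    """

    v0: float = -35.0
    ionic_strength: float = 0.150
    temperature: float = 298.15
    relative_permittivity: float = 78.5

    def __post_init__(self) -> None:
        if self.ionic_strength <= 0:
            raise ValueError("ionic_strength must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.relative_permittivity <= 1:
            raise ValueError("relative_permittivity must be > 1")


@dataclass(frozen=True)
class PartitionResult:
    """Boltzmann partition of a charged species across a potential.

    ``ratio`` is [X]_membrane / [X]_cytoplasm.  When the exponent exceeds
    the floating-point range the ratio is +inf (or 0) and ``overflowed``
    is set instead of raising.
    """

    z: float
    ratio: float
    v_mV: float
    temperature: float
    overflowed: bool = field(default=False)


def debye_length(model: MembraneModel) -> float:
    """Debye screening length of the electrolyte, in nm.

    ``lambda_D = sqrt(eps_r eps_0 k_B T / (2 N_A e^2 I*1000))`` with I in
    mol/L (the factor 1000 converts to mol/m^3).  For 150 mM 1:1 salt at
    298.15 K this is 0.785 nm.
    """
    i_si = model.ionic_strength * 1000.0  # mol/m^3
    lam_m = math.sqrt(
        model.relative_permittivity * VACUUM_PERMITTIVITY * BOLTZMANN
        * model.temperature
        / (2.0 * AVOGADRO * ELEMENTARY_CHARGE**2 * i_si)
    )
    return lam_m * 1e9


def screened_potential(model: MembraneModel, x_nm: float) -> float:
    """Potential ``V(x) = V0 exp(-x / lambda_D)`` at distance x (nm), in mV.

    Linearized Debye-Hueckel decay; the sign of V0 is preserved and the
    magnitude decreases monotonically toward zero.
    """
    if x_nm < 0:
        raise ValueError("distance x must be >= 0")
    return model.v0 * math.exp(-x_nm / debye_length(model))


def boltzmann_partition(z: float, model: MembraneModel,
                        v_mV: float | None = None) -> PartitionResult:
    """Equilibrium concentration ratio of a charge-z species at the surface.

    ``ratio = exp(-z F V / (R T))`` with V in volts.  A positive species at
    a negative surface is enriched (ratio > 1).  ``v_mV`` overrides the
    model's surface potential (e.g. to partition at a screened distance).
    """
    if not math.isfinite(z):
        raise ValueError("charge z must be finite")
    v = (model.v0 if v_mV is None else v_mV) * 1e-3
    exponent = -z * FARADAY * v / (GAS_CONSTANT * model.temperature)
    if abs(exponent) > _OVERFLOW_EXPONENT:
        ratio = math.inf if exponent > 0 else 0.0
        return PartitionResult(z=z, ratio=ratio, v_mV=v * 1e3,
                               temperature=model.temperature, overflowed=True)
    return PartitionResult(z=z, ratio=math.exp(exponent), v_mV=v * 1e3,
                           temperature=model.temperature)


def surface_pH(bulk_pH: float, model: MembraneModel) -> float:
    """pH at the charged surface from Boltzmann partition of protons.

    Protons (z = +1) accumulate at a negative surface, lowering the pH:
    ``pH_surface = pH_bulk + F V / (ln(10) R T)`` with V in volts.
    For bulk pH 7.2 and V = -35 mV at 298.15 K this gives 6.6.
    """
    if not 0 < bulk_pH < 14:
        raise ValueError("bulk_pH must be in (0, 14)")
    v = model.v0 * 1e-3
    return bulk_pH + FARADAY * v / (math.log(10.0) * GAS_CONSTANT
                                    * model.temperature)


def enrichment_fold_change(z_before: float, z_after: float,
                           model: MembraneModel) -> float:
    """Fold change in the partition ratio when the net charge changes.

    ``partition(z_before) / partition(z_after)
    = exp(-(z_before - z_after) F V / (R T))``.  Phosphorylation that drops
    z by 4 at V = -35 mV lowers membrane enrichment ~230-fold.
    """
    dz = z_before - z_after
    res = boltzmann_partition(dz, model)
    return res.ratio
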