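"""Flory–Rehner equilibrium-swelling mesh-size calculator.

The nanoscale mesh of a crosslinked polymer network is estimated from an
equilibrium swelling assay: a gel is weighed immediately after crosslinking
(relaxed), after 24 h of swelling (swollen), and after lyophilization (dry).
The chain of relations is

    Q_m = (m_wet − m_dry) / m_dry                    mass swelling ratio
    Q_v = 1 + (ρ_p/ρ_s)·(Q_m − 1)                    volumetric swelling ratio
    υ   = 1 / Q_v                                    polymer volume fraction
    1/M_c = 2/M_n − (ῡ/V₁)·[ln(1−υ_2s) + υ_2s + χ₁·υ_2s²]
            / ( υ_2r·[ (υ_2s/υ_2r)^{1/3} − ½·(υ_2s/υ_2r) ] )
    ξ   = υ_2s^{−1/3} · l · √(2·C_n·M_c/M_r)         mesh size (nm)

with ῡ = 1/ρ_p the polymer specific volume (cm³/g, dimensionally consistent
with V₁ in mL/mol), υ_2r and υ_2s the relaxed and equilibrium (swollen)
polymer volume fractions, M_n the polymer molecular weight before
crosslinking, M_c the molecular weight between crosslinks, M_r the repeat
unit, l the backbone bond length, and C_n the Flory characteristic ratio.
Defaults are the PEG/PBS constants: ρ_p = 1.125 g/cm³, ρ_s = 1.011 g/cm³,
V₁ = 18 mL/mol, χ₁ = 0.426, M_r = 44 g/mol, l = 0.15 nm, C_n = 4.

Only mass *ratios* enter, so results are invariant under rescaling all
masses.  The natural logarithm is evaluated exactly (no series truncation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SwellingInfeasibleError

__all__ = [
    "SwellingInput",
    "SwellingResult",
    "mass_swelling_ratio",
    "volumetric_swelling_ratio",
    "polymer_volume_fraction",
    "flory_rehner_Mc",
    "mesh_size",
    "mesh_size_pipeline",
]


@dataclass(frozen=True)
class SwellingInput:
    """Swelling-assay masses (g) and polymer constants."""

    m_wet_relaxed: float
    m_wet_swollen: float
    m_dry: float
    M_n: float  # g/mol, polymer molecular weight before crosslinking
    rho_polymer: float = 1.125  # g/cm³
    rho_solvent: float = 1.011  # g/cm³
    M_r: float = 44.0  # g/mol, repeat unit
    V_1: float = 18.0  # mL/mol, solvent molar volume
    chi_1: float = 0.426  # polymer-solvent interaction
    bond_length_l: float = 0.15  # nm
    C_n: float = 4.0  # Flory characteristic ratio

    def __post_init__(self) -> None:
        for name in (
            "m_wet_relaxed", "m_wet_swollen", "m_dry", "M_n",
            "rho_polymer", "rho_solvent", "M_r", "V_1", "bond_length_l", "C_n",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if self.m_wet_relaxed < self.m_dry or self.m_wet_swollen < self.m_dry:
            raise DomainError("wet masses must be >= the dry mass")


@dataclass
class SwellingResult:
    """All intermediates of the mesh-size chain."""

    Q_m_relaxed: float
    Q_m_swollen: float
    Q_v_relaxed: float
    Q_v_swollen: float
    v_2r: float
    v_2s: float
    M_c: float  # g/mol
    mesh_size_xi: float  # nm


def mass_swelling_ratio(m_wet: float, m_dry: float) -> float:
    """Q_m = (m_wet − m_dry)/m_dry."""
    if m_dry <= 0:
        raise DomainError("dry mass must be > 0")
    return (m_wet - m_dry) / m_dry


def volumetric_swelling_ratio(Q_m: float, rho_p: float, rho_s: float) -> float:
    """Q_v = 1 + (ρ_p/ρ_s)·(Q_m − 1)."""
    if rho_p <= 0 or rho_s <= 0:
        raise DomainError("densities must be > 0")
    if Q_m < 0:
        raise DomainError("mass swelling ratio must be >= 0")
    return 1.0 + (rho_p / rho_s) * (Q_m - 1.0)


def polymer_volume_fraction(Q_v: float) -> float:
    """υ = 1/Q_v, validated to lie in (0, 1)."""
    if Q_v <= 1.0:
        raise SwellingInfeasibleError(
            f"volumetric swelling ratio {Q_v:.4g} <= 1: swelling inconsistent "
            "with a solvated network"
        )
    return 1.0 / Q_v


def flory_rehner_Mc(
    v_2r: float,
    v_2s: float,
    M_n: float,
    rho_p: float,
    V_1: float = 18.0,
    chi_1: float = 0.426,
) -> float:
    """Molecular weight between crosslinks from the Flory–Rehner relation."""
    for name, v in (("v_2r", v_2r), ("v_2s", v_2s)):
        if not 0.0 < v < 1.0:
            raise DomainError(f"{name} must lie in (0, 1), got {v}")
    if M_n <= 0 or rho_p <= 0 or V_1 <= 0:
        raise DomainError("M_n, rho_p and V_1 must be > 0")
    vbar = 1.0 / rho_p
    mixing = np.log(1.0 - v_2s) + v_2s + chi_1 * v_2s**2
    ratio = v_2s / v_2r
    elastic = v_2r * (ratio ** (1.0 / 3.0) - 0.5 * ratio)
    inv_Mc = 2.0 / M_n - (vbar / V_1) * mixing / elastic
    if inv_Mc <= 0:
        raise SwellingInfeasibleError(
            "nonpositive 1/M_c: swelling inconsistent with the network model"
        )
    return 1.0 / inv_Mc


def mesh_size(
    v_2s: float, M_c: float, M_r: float, l: float = 0.15, C_n: float = 4.0
) -> float:
    """ξ = υ_2s^(−1/3) · l · √(2·C_n·M_c/M_r), in nm for l in nm."""
    for name, v in (("v_2s", v_2s), ("M_c", M_c), ("M_r", M_r), ("l", l), ("C_n", C_n)):
        if not v > 0:
            raise DomainError(f"{name} must be > 0")
    return v_2s ** (-1.0 / 3.0) * l * np.sqrt(2.0 * C_n * M_c / M_r)


def mesh_size_pipeline(inp: SwellingInput) -> SwellingResult:
    """Full chain: masses → Q_m → Q_v → υ (relaxed and swollen) → M_c → ξ."""
    Qm_r = mass_swelling_ratio(inp.m_wet_relaxed, inp.m_dry)
    Qm_s = mass_swelling_ratio(inp.m_wet_swollen, inp.m_dry)
    Qv_r = volumetric_swelling_ratio(Qm_r, inp.rho_polymer, inp.rho_solvent)
    Qv_s = volumetric_swelling_ratio(Qm_s, inp.rho_polymer, inp.rho_solvent)
    v_2r = polymer_volume_fraction(Qv_r)
    v_2s = polymer_volume_fraction(Qv_s)
    M_c = flory_rehner_Mc(v_2r, v_2s, inp.M_n, inp.rho_polymer, inp.V_1, inp.chi_1)
    xi = mesh_size(v_2s, M_c, inp.M_r, inp.bond_length_l, inp.C_n)
    return SwellingResult(
        Q_m_relaxed=Qm_r,
        Q_m_swollen=Qm_s,
        Q_v_relaxed=Qv_r,
        Q_v_swollen=Qv_s,
        v_2r=v_2r,
        v_2s=v_2s,
        M_c=M_c,
        mesh_size_xi=xi,
    )
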