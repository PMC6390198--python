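"""Liquid junction potential by the generalized Henderson equation.

Whole-cell recordings with a K-gluconate internal against a NaCl-based
bath develop a stationary junction potential at the pipette tip of order
+10 to +16 mV (bath relative to pipette), dominated by the mobility
mismatch between Cl- and the large, slow gluconate anion.  The Henderson
equation gives the stationary potential for a free-diffusion junction:

    E = -(RT/F) * [sum_i z_i u_i dc_i / sum_i z_i^2 u_i dc_i]
               * ln( sum_i z_i^2 u_i c_i^bath / sum_i z_i^2 u_i c_i^pip )

with dc_i = c_i^bath - c_i^pip and u_i the (electro)diffusive mobility of
species i.  Mobilities are taken proportional to lambda_i / |z_i| where
lambda_i is the limiting equivalent conductivity, which by Nernst-Einstein
makes u_i proportional to the diffusion coefficient.  The sign convention
is bath minus pipette, so the usual K-gluconate internal gives a positive
value (the amount by which the uncorrected membrane potential reading is
too depolarized).

Organic anions (gluconate, HEPES, ATP, phosphocreatine) have no tabulated
Kohlrausch values; the table below carries the published estimates used by
standard junction-potential calculators.  Neutral species (glucose,
mannitol) carry no current and are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UndefinedJunctionError

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)

#: Limiting equivalent conductivities at 25 C, S cm^2 / equivalent,
#: from standard electrochemical tables; organic species are literature
#: estimates of the kind shipped with junction-potential calculators.
LIMITING_CONDUCTIVITY: dict[str, tuple[int, float]] = {
    # name: (charge, lambda_eq)
    "K": (1, 73.50),
    "Na": (1, 50.11),
    "Li": (1, 38.69),
    "Cs": (1, 77.30),
    "NH4": (1, 73.70),
    "Ca": (2, 59.50),
    "Mg": (2, 53.06),
    "H": (1, 349.8),
    "TEA": (1, 32.70),
    "choline": (1, 38.60),
    "Cl": (-1, 76.35),
    "Br": (-1, 78.10),
    "F": (-1, 55.40),
    "NO3": (-1, 71.46),
    "HCO3": (-1, 44.50),
    "H2PO4": (-1, 33.00),
    "SO4": (-2, 80.00),
    "OH": (-1, 198.3),
    "acetate": (-1, 40.90),
    "gluconate": (-1, 24.30),
    "glutamate": (-1, 26.00),
    "aspartate": (-1, 22.05),
    "HEPES": (-1, 22.05),
    "MeSO4": (-1, 48.50),
    "ATP": (-2, 25.00),
    "GTP": (-2, 25.00),
    "phosphocreatine": (-2, 25.00),
    "EGTA": (-2, 20.00),
    "ascorbate": (-1, 32.00),
    "pyruvate": (-1, 35.00),
}


@dataclass
class IonSpecies:
    """One charged species of a solution."""

    name: str
    concentration: float  # mM
    charge: int
    conductivity: float   # limiting equivalent conductivity, S cm^2/eq

    @property
    def mobility(self) -> float:
        """Diffusive mobility, proportional to D_i (Nernst-Einstein)."""
        return self.conductivity / abs(self.charge)


@dataclass
class SolutionComposition:
    """An electrolyte solution as a list of charged species.

    ``from_recipe`` builds one from a {species-name: mM} mapping using the
    built-in conductivity table; unknown or neutral names must be omitted
    by the caller (they do not enter the Henderson computation).
    """

    species: list[IonSpecies] = field(default_factory=list)
    temperature: float = 25.0  # Celsius

    @classmethod
    def from_recipe(
        cls, recipe: dict[str, float], temperature: float = 25.0
    ) -> "SolutionComposition":
        species = []
        for name, conc in recipe.items():
            if name not in LIMITING_CONDUCTIVITY:
                raise KeyError(
                    f"no conductivity entry for species {name!r}; add one to "
                    "LIMITING_CONDUCTIVITY or pass IonSpecies explicitly"
                )
            if conc < 0:
                raise ValueError(f"negative concentration for {name!r}")
            z, lam = LIMITING_CONDUCTIVITY[name]
            species.append(IonSpecies(name, float(conc), z, lam))
        return cls(species=species, temperature=temperature)

    def charged(self) -> list[IonSpecies]:
        return [s for s in self.species if s.charge != 0 and s.concentration > 0]


def liquid_junction_potential(
    pipette: SolutionComposition, bath: SolutionComposition
) -> float:
    """Stationary junction potential, bath minus pipette, in mV.

    Raises :class:`UndefinedJunctionError` when either solution has no
    charged species.  Identical solutions give exactly 0.
    """
    if not pipette.charged() or not bath.charged():
        raise UndefinedJunctionError("a solution has no charged species")

    temperature = 0.5 * (pipette.temperature + bath.temperature)
    rt_f = GAS_CONSTANT * (273.15 + temperature) / FARADAY * 1000.0  # mV

    names = sorted(
        {s.name for s in pipette.charged()} | {s.name for s in bath.charged()}
    )
    pip = {s.name: s for s in pipette.charged()}
    bat = {s.name: s for s in bath.charged()}

    num = den = 0.0
    s_pip = s_bath = 0.0
    for name in names:
        ref = pip.get(name) or bat.get(name)
        assert ref is not None
        other = bat.get(name) if ref is pip.get(name) else pip.get(name)
        if other is not None and (
            other.charge != ref.charge or other.conductivity != ref.conductivity
        ):
            raise ValueError(f"inconsistent definitions of species {name!r}")
        z, u = ref.charge, ref.mobility
        c_p = pip[name].concentration if name in pip else 0.0
        c_b = bat[name].concentration if name in bat else 0.0
        d = c_b - c_p
        num += z * u * d
        den += z * z * u * d
        s_pip += z * z * u * c_p
        s_bath += z * z * u * c_b

    if s_pip <= 0 or s_bath <= 0:
        raise UndefinedJunctionError("zero ionic strength on one side")
    if den == 0.0:
        # identical mobility-weighted profiles; no net junction
        return 0.0
    return float(-rt_f * (num / den) * np.log(s_bath / s_pip))


#: Pipette internal used for the whole-cell recordings: 120 K-gluconate,
#: 10 KCl, 10 HEPES, 4 MgATP, 10 Na2-phosphocreatine, 0.3 GTP (mM).
#: Salts are entered fully dissociated; GTP is carried at its nominal
#: concentration and HEPES as its anion.
PIPETTE_INTERNAL: dict[str, float] = {
    "K": 130.0,
    "gluconate": 120.0,
    "Cl": 10.0,
    "HEPES": 10.0,
    "Mg": 4.0,
    "ATP": 4.0,
    "Na": 20.0,
    "phosphocreatine": 10.0,
    "GTP": 0.3,
}

#: Recording ACSF: 126 NaCl, 3 KCl, 1.5 MgCl2, 1.6 CaCl2, 10 glucose
#: (neutral, omitted), 1.2 NaH2PO4, 26 NaHCO3 (mM).
RECORDING_ACSF: dict[str, float] = {
    "Na": 126.0 + 1.2 + 26.0,
    "K": 3.0,
    "Mg": 1.5,
    "Ca": 1.6,
    "Cl": 126.0 + 3.0 + 2 * 1.5 + 2 * 1.6,
    "H2PO4": 1.2,
    "HCO3": 26.0,
}


def recording_junction_potential(temperature: float = 25.0) -> float:
    """Junction potential of the standard K-gluconate internal against the
    recording ACSF, in mV (positive: bath relative to pipette)."""
    pip = SolutionComposition.from_recipe(PIPETTE_INTERNAL, temperature)
    bath = SolutionComposition.from_recipe(RECORDING_ACSF, temperature)
    return liquid_junction_potential(pip, bath)
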