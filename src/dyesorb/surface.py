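"""Nanoparticle surface characterization and system-composition bookkeeping.

Covers the arithmetic around a simulated dye/nanoparticle box: the pH →
silanol-ionization mapping, surface densities of silanol groups and
counterions per Å² of nominal sphere area, the ion counts required to keep
the box neutral, total atom counts, and the simple percent comparisons used
for dipole moments and for the dye's contribution to a measured
dye–particle complex size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SystemSpec",
    "ionization_fraction_for_ph",
    "surface_density",
    "snp_charge",
    "neutralizing_ion_counts",
    "validate_neutralization",
    "validate_spec",
    "total_atom_count",
    "percent_difference",
    "size_contribution",
    "characterize_table",
]

#: tabulated silanol ionization (deprotonation) fractions
IONIZATION_TABLE = {7: 0.133, 12: 0.30}


@dataclass
class SystemSpec:
    """Composition of one dye/nanoparticle simulation box."""

    name: str
    crystal: str  # quartz | cristobalite
    nominal_diameter: float  # Å
    ph: float
    n_snp: int
    atoms_per_snp: int
    n_dye: int
    atoms_per_dye: int
    dye_charge: int  # e per dye
    n_silanol: int  # surface silanol groups per particle
    ionization_fraction: float
    n_cl: int
    n_na_per_snp: int
    n_water_atoms: int

    def __post_init__(self) -> None:
        if self.crystal not in ("quartz", "cristobalite"):
            raise ValueError("crystal must be 'quartz' or 'cristobalite'")
        for f in ("n_snp", "atoms_per_snp", "n_dye", "atoms_per_dye",
                  "n_silanol", "n_cl", "n_na_per_snp", "n_water_atoms"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0.0 <= self.ionization_fraction <= 1.0:
            raise ValueError("ionization fraction must be in [0, 1]")


def ionization_fraction_for_ph(ph: float) -> float:
    """Tabulated fraction of ionized surface silanols (0.133 at pH 7, 0.30 at pH 12)."""
    key = int(ph) if float(ph).is_integer() else ph
    try:
        return IONIZATION_TABLE[key]
    except (KeyError, TypeError):
        raise ValueError(
            f"no tabulated ionization fraction for pH {ph}; known: "
            f"{sorted(IONIZATION_TABLE)}"
        ) from None


def surface_density(count: float, diameter: float) -> float:
    """Groups per Å² of nominal sphere surface, count / (π·d²)."""
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    return count / (math.pi * diameter**2)


def snp_charge(spec: SystemSpec) -> int:
    """Particle charge in e: −round(n_silanol × ionization_fraction)."""
    return -round(spec.n_silanol * spec.ionization_fraction)


def neutralizing_ion_counts(spec: SystemSpec) -> tuple[int, int]:
    """(Cl⁻ required for the dyes, Na⁺ required per particle)."""
    return spec.n_dye * spec.dye_charge, abs(snp_charge(spec))


def validate_neutralization(spec: SystemSpec) -> list[str]:
    """Check the declared ion counts against the required ones.

    Returns a list of human-readable problems (empty when consistent); a
    mismatch is surfaced, never silently accepted.
    """
    n_cl_req, n_na_req = neutralizing_ion_counts(spec)
    problems = []
    if spec.n_cl != n_cl_req:
        problems.append(
            f"{spec.name}: {spec.n_cl} Cl- declared, {n_cl_req} required for "
            f"{spec.n_dye} dyes of charge +{spec.dye_charge}e"
        )
    if spec.n_na_per_snp != n_na_req:
        problems.append(
            f"{spec.name}: {spec.n_na_per_snp} Na+ per particle declared, "
            f"{n_na_req} required for particle charge {snp_charge(spec)}e"
        )
    return problems


def validate_spec(spec: SystemSpec) -> list[str]:
    """All composition consistency checks, reported rather than rejected.

    Besides the neutralization checks this flags a water-atom count that is
    not an exact multiple of three; a couple of published composition rows
    carry such counts, and the atom count (not the molecule count) is what
    enters the total, so the mismatch is surfaced but tolerated.
    """
    problems = validate_neutralization(spec)
    if spec.n_water_atoms % 3 != 0:
        problems.append(
            f"{spec.name}: {spec.n_water_atoms} water atoms is not a "
            "multiple of 3"
        )
    return problems


def total_atom_count(spec: SystemSpec) -> int:
    """Total atoms: dyes + particles + Cl⁻ + Na⁺ + water."""
    return (
        spec.n_dye * spec.atoms_per_dye
        + spec.n_snp * spec.atoms_per_snp
        + spec.n_cl
        + spec.n_snp * spec.n_na_per_snp
        + spec.n_water_atoms
    )


def percent_difference(a: float, b: float) -> float:
    """Signed percent difference 100·(b − a)/a of two magnitudes (e.g. Debye)."""
    if a <= 0:
        raise ValueError("reference value must be > 0")
    return 100.0 * (b - a) / a


def size_contribution(layer_thickness: float, np_diameter: float) -> float:
    """Percent contribution of an adsorbed dye layer to the measured size."""
    if layer_thickness <= 0 or np_diameter <= 0:
        raise ValueError("thickness and diameter must be > 0")
    return 100.0 * layer_thickness / np_diameter


def characterize_table(specs: list[SystemSpec]) -> pd.DataFrame:
    """Composition table plus derived densities and validation status."""
    rows = []
    for s in specs:
        rows.append(
            {
                "system": s.name,
                "crystal": s.crystal,
                "diameter_A": s.nominal_diameter,
                "pH": s.ph,
                "n_dye": s.n_dye,
                "atoms_per_dye": s.atoms_per_dye,
                "n_snp": s.n_snp,
                "atoms_per_snp": s.atoms_per_snp,
                "n_cl": s.n_cl,
                "n_na_per_snp": s.n_na_per_snp,
                "n_water_atoms": s.n_water_atoms,
                "total_atoms": total_atom_count(s),
                "snp_charge_e": snp_charge(s),
                "silanol_per_A2": surface_density(s.n_silanol, s.nominal_diameter),
                "ionized_per_A2": surface_density(
                    s.n_silanol * s.ionization_fraction, s.nominal_diameter
                ),
                "na_per_A2": surface_density(s.n_na_per_snp, s.nominal_diameter),
                "neutral_ok": not validate_neutralization(s),
            }
        )
    return pd.DataFrame(rows)
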