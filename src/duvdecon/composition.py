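"""Cell composition budget: aromatic residues per cell and the mixture recipe.

An exponentially growing E. coli cell (40-min doubling time, ~1000 fg wet
mass, ~0.9 um^3) carries its deep-UV-resonant aromatic units in four pools:
protein (Phe/Trp/Tyr residues), RNA and DNA (nucleobases in nucleic acids)
and the free-metabolite pool (free nucleotides plus traces of free aromatic
amino acids).  This module turns class masses, residue mole fractions and
metabolite concentrations into absolute aromatic-unit counts per cell,
summary fractions (total resonant units, nucleotide vs amino-acid split,
fraction of nucleobases sequestered in nucleic acids), the sampling geometry
of a dried spot, the recipe of an artificial cell-mimic mixture, and exact
oligomer base compositions.

Two budget modes:

``transcribed``
    the tabulated per-unit counts are taken as given — guarantees fidelity to
    the source composition table;
``derived``
    counts are recomputed from masses, mean residue masses and mole
    fractions via n = (m / M_residue) * N_A * x (macromolecules) or
    n = C * V * N_A (metabolites) — exercises the arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.constants import Avogadro

__all__ = [
    "UnitEntry",
    "ClassBudget",
    "CellBudget",
    "MixtureRecipe",
    "SpotGeometry",
    "units_from_mass",
    "units_from_concentration",
    "budget_summary",
    "mixture_recipe",
    "cells_per_spot",
    "base_composition",
    "round_half_away",
]

#: Default cell volume in fL (1 um^3 == 1 fL).
CELL_VOLUME_FL = 0.9
#: Conversion volume (fL) implied by the tabulated metabolite counts
#: (e.g. 16.0 mM adenine -> 10.7e6 units requires ~1.11 fL, not 0.9).
METABOLITE_VOLUME_FL = 1.113
#: Mean residue masses (Da), back-calibrated so derived class totals match
#: the tabulated totals (protein: 165 fg at 7.1 mol% aromatic -> 65.2e6).
MEAN_RESIDUE_MASS_DA = {"protein": 108.2, "RNA": 340.0, "DNA": 327.0}

# Composition table for the average exponentially growing cell.
# Macromolecule classes: (percent cell mass, mass fg, {unit: (mole %, count e6)})
# Metabolites: {unit: (concentration mM, count e6)} with the tabulated subtotal.
TABLE_PROTEIN = {"mass_fg": 165.0, "pct_mass": 16.5, "subtotal_e6": 65.2,
                 "units": {"Phe": (3.46, 31.8), "Trp": (1.06, 9.74),
                           "Tyr": (2.58, 23.6)}}
TABLE_RNA = {"mass_fg": 60.0, "pct_mass": 6.0, "subtotal_e6": 106.0,
             "units": {"A": (24.8, 26.2), "C": (21.8, 23.0),
                       "G": (32.4, 34.2), "U": (21.0, 22.2)}}
TABLE_DNA = {"mass_fg": 9.0, "pct_mass": 0.9, "subtotal_e6": 16.6,
             "units": {"A": (24.5, 4.07), "C": (24.6, 4.08),
                       "G": (26.2, 4.35), "T": (24.7, 4.10)}}
TABLE_METABOLITES = {"mass_fg": 70.0, "pct_mass": 7.0, "subtotal_e6": 36.4,
                     "units": {"A": (16.0, 10.7), "C": (2.75, 1.84),
                               "G": (5.85, 3.91), "T": (4.98, 3.33),
                               "U": (22.7, 15.2), "Phe": (2.00, 0.012),
                               "Trp": (1.33, 0.0008), "Tyr": (3.22, 0.019)}}
TABLE_OTHER = {"mass_fg": 57.0, "pct_mass": 5.7}
TABLE_WATER = {"mass_fg": 639.0, "pct_mass": 63.9}

NUCLEOBASE_UNITS = ("A", "C", "G", "T", "U")
AAA_UNITS = ("Phe", "Trp", "Tyr")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (deterministic printed-figure comparison)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def units_from_mass(mass_fg: float, mean_residue_mass_da: float,
                    aromatic_mole_fraction: float) -> float:
    """Aromatic units per cell in a macromolecule class.

    count = (mass_fg * 1e-15 g / M_residue) * N_A * mole fraction.
    """
    if mass_fg <= 0 or mean_residue_mass_da <= 0:
        raise ValueError("mass and residue mass must be positive")
    if not 0.0 <= aromatic_mole_fraction <= 1.0:
        raise ValueError("aromatic_mole_fraction must lie in [0, 1]")
    residues = mass_fg * 1e-15 / mean_residue_mass_da * Avogadro
    return residues * aromatic_mole_fraction


def units_from_concentration(conc_mm: float, volume_fl: float) -> float:
    """Metabolite units per cell: n = C[mM] * V[fL] * N_A (unit-converted)."""
    if conc_mm < 0 or volume_fl < 0:
        raise ValueError("concentration and volume must be non-negative")
    return conc_mm * 1e-3 * volume_fl * 1e-15 * Avogadro


@dataclass
class UnitEntry:
    """One aromatic unit within a class: composition datum + derived count."""

    unit: str
    mole_percent: float | None = None   # macromolecule classes
    concentration_mM: float | None = None  # metabolite pool
    count_e6: float = 0.0  # aromatic units per cell, in millions


@dataclass
class ClassBudget:
    name: str
    mass_fg: float
    pct_mass: float
    units: list = field(default_factory=list)
    subtotal_e6: float = 0.0

    def unit_count(self, unit: str) -> float:
        for u in self.units:
            if u.unit == unit:
                return u.count_e6
        return 0.0

    def nucleobase_count_e6(self) -> float:
        return sum(u.count_e6 for u in self.units if u.unit in NUCLEOBASE_UNITS)

    def aaa_count_e6(self) -> float:
        return sum(u.count_e6 for u in self.units if u.unit in AAA_UNITS)


@dataclass
class CellBudget:
    """Per-class masses and aromatic-unit counts for an average cell."""

    classes: dict
    mode: str = "transcribed"
    cell_volume_fL: float = CELL_VOLUME_FL
    metabolite_volume_fL: float = METABOLITE_VOLUME_FL
    mean_residue_mass_Da: dict = field(
        default_factory=lambda: dict(MEAN_RESIDUE_MASS_DA))

    def __post_init__(self):
        total_pct = sum(c.pct_mass for c in self.classes.values())
        if abs(total_pct - 100.0) > 0.2:
            raise ValueError(f"class mass percentages sum to {total_pct}, not 100")
        for c in self.classes.values():
            if c.mass_fg < 0 or any(u.count_e6 < 0 for u in c.units):
                raise ValueError("masses and counts must be non-negative")
        for c in self.classes.values():
            derived = sum(u.count_e6 for u in c.units)
            if c.subtotal_e6 and derived:
                if abs(derived - c.subtotal_e6) / c.subtotal_e6 > 0.05:
                    c.inconsistent_subtotal = True  # tabulated metabolite quirk

    @classmethod
    def from_reference_table(cls, mode: str = "transcribed",
                             metabolite_volume_fL: float = METABOLITE_VOLUME_FL,
                             mean_residue_mass_Da: dict | None = None) -> "CellBudget":
        """Build the budget from the built-in composition table.

        ``transcribed`` keeps the tabulated per-unit counts; ``derived``
        recomputes every count from masses / mole fractions / concentrations.
        """
        if mode not in ("transcribed", "derived"):
            raise ValueError("mode must be 'transcribed' or 'derived'")
        masses = dict(mean_residue_mass_Da or MEAN_RESIDUE_MASS_DA)
        classes: dict = {}
        for name, table, key in (("protein", TABLE_PROTEIN, "protein"),
                                 ("RNA", TABLE_RNA, "RNA"),
                                 ("DNA", TABLE_DNA, "DNA")):
            units = []
            for unit, (molpct, count) in table["units"].items():
                if mode == "derived":
                    count = units_from_mass(table["mass_fg"], masses[key],
                                            molpct / 100.0) / 1e6
                units.append(UnitEntry(unit, mole_percent=molpct,
                                       count_e6=count))
            subtotal = (table["subtotal_e6"] if mode == "transcribed"
                        else sum(u.count_e6 for u in units))
            classes[name] = ClassBudget(name, table["mass_fg"],
                                        table["pct_mass"], units, subtotal)
        units = []
        for unit, (conc, count) in TABLE_METABOLITES["units"].items():
            if mode == "derived":
                count = units_from_concentration(conc, metabolite_volume_fL) / 1e6
            units.append(UnitEntry(unit, concentration_mM=conc, count_e6=count))
        subtotal = (TABLE_METABOLITES["subtotal_e6"] if mode == "transcribed"
                    else sum(u.count_e6 for u in units))
        classes["metabolites"] = ClassBudget(
            "metabolites", TABLE_METABOLITES["mass_fg"],
            TABLE_METABOLITES["pct_mass"], units, subtotal)
        classes["other"] = ClassBudget("other", TABLE_OTHER["mass_fg"],
                                       TABLE_OTHER["pct_mass"])
        classes["water"] = ClassBudget("water", TABLE_WATER["mass_fg"],
                                       TABLE_WATER["pct_mass"])
        return cls(classes=classes, mode=mode,
                   metabolite_volume_fL=metabolite_volume_fL,
                   mean_residue_mass_Da=masses)

    # -- totals -------------------------------------------------------
    def class_subtotal_e6(self, name: str) -> float:
        return self.classes[name].subtotal_e6

    def total_aromatic_e6(self) -> float:
        return sum(self.classes[n].subtotal_e6
                   for n in ("protein", "RNA", "DNA", "metabolites"))

    def metabolite_aaa_e6(self) -> float:
        return self.classes["metabolites"].aaa_count_e6()

    def metabolite_nucleobase_e6(self) -> float:
        """Nucleobase share of the metabolite subtotal.

        The tabulated subtotal exceeds the per-unit sum (36.4 vs ~35.0
        million); in transcribed mode the subtotal is honoured and the AAA
        contribution removed from it, in derived mode the per-unit sum is used.
        """
        c = self.classes["metabolites"]
        if self.mode == "transcribed":
            return c.subtotal_e6 - c.aaa_count_e6()
        return c.nucleobase_count_e6()


@dataclass
class SpotGeometry:
    """Deposition and sampling geometry of a dried cell spot."""

    deposited_volume_uL: float = 2.0
    cell_density_per_mL: float = 1.6e8
    dry_spot_diameter_mm: float = 2.0
    laser_spot_diameter_um: float = 68.0

    def __post_init__(self):
        for f in ("deposited_volume_uL", "cell_density_per_mL",
                  "dry_spot_diameter_mm", "laser_spot_diameter_um"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.laser_spot_diameter_um > self.dry_spot_diameter_mm * 1000.0:
            raise ValueError("laser spot cannot exceed the dry spot")


def cells_per_spot(geometry: SpotGeometry) -> float:
    """Cells interrogated per laser spot, assuming uniform spot coverage.

    count = deposited cells * (laser diameter / dry-spot diameter)^2.
    """
    deposited = geometry.deposited_volume_uL * 1e-3 * geometry.cell_density_per_mL
    ratio = geometry.laser_spot_diameter_um / (geometry.dry_spot_diameter_mm * 1000.0)
    return deposited * ratio**2


def budget_summary(budget: CellBudget) -> dict:
    """Summary fractions of the aromatic budget.

    Returns the total resonant units (millions), the nucleotide vs amino-acid
    percentage split, the percentage of nucleobases sequestered in nucleic
    acids (vs free metabolites), and the percentage of aromatic amino-acid
    residues held in protein — raw and rounded to printed precision.
    """
    total = budget.total_aromatic_e6()
    if total <= 0:
        raise ValueError("budget has zero aromatic units")
    nucleic = (budget.class_subtotal_e6("RNA") + budget.class_subtotal_e6("DNA"))
    met_nb = budget.metabolite_nucleobase_e6()
    met_aaa = budget.metabolite_aaa_e6()
    protein = budget.class_subtotal_e6("protein")

    nucleotide_total = nucleic + met_nb
    amino_total = protein + met_aaa
    sequestered_pct = 100.0 * nucleic / (nucleic + met_nb)
    nucleotide_pct = 100.0 * nucleotide_total / total
    amino_pct = 100.0 * amino_total / total
    protein_aaa_pct = 100.0 * protein / (protein + met_aaa)
    return {
        "total_aromatic_e6": total,
        "total_aromatic_e6_rounded": round_half_away(total),
        "nucleotide_pct": nucleotide_pct,
        "nucleotide_pct_rounded": round_half_away(nucleotide_pct),
        "amino_acid_pct": amino_pct,
        "amino_acid_pct_rounded": round_half_away(amino_pct),
        "sequestered_nucleobase_pct": sequestered_pct,
        "sequestered_nucleobase_pct_rounded": round_half_away(sequestered_pct),
        "protein_aaa_pct": protein_aaa_pct,
    }


@dataclass
class MixtureRecipe:
    """Component concentrations (mM) of the artificial cell-mimic mixture.

    Thirteen components: oligomer standards stand in for nucleobases bound in
    nucleic acids (``oligo_A`` .. ``oligo_U``), nucleotide triphosphates for
    the free-nucleotide pool (``free_A`` .. ``free_U``), and free amino acids
    for Phe/Trp/Tyr.
    """

    concentrations_mM: dict
    total_mM: float = 1.00

    def __post_init__(self):
        if any(v < -1e-12 for v in self.concentrations_mM.values()):
            raise ValueError("concentrations must be non-negative")
        s = sum(self.concentrations_mM.values())
        if abs(s - self.total_mM) > 1e-9:
            raise ValueError(f"concentrations sum to {s}, not {self.total_mM}")


def mixture_recipe(budget: CellBudget, total_mM: float = 1.00) -> MixtureRecipe:
    """Allocate ``total_mM`` across 13 standards per the budget's residue counts.

    Oligomer components get the macromolecular (RNA + DNA) counts of each
    base, free-nucleotide components the metabolite nucleobase counts, and
    amino-acid components the protein + metabolite aromatic-residue counts;
    concentrations are proportional to the counts and sum to ``total_mM``.
    """
    rna, dna = budget.classes["RNA"], budget.classes["DNA"]
    met, prot = budget.classes["metabolites"], budget.classes["protein"]
    counts: dict = {}
    for base in NUCLEOBASE_UNITS:
        counts[f"oligo_{base}"] = rna.unit_count(base) + dna.unit_count(base)
        counts[f"free_{base}"] = met.unit_count(base)
    for aa in AAA_UNITS:
        counts[aa] = prot.unit_count(aa) + met.unit_count(aa)
    total_counts = sum(counts.values())
    if total_counts <= 0:
        raise ValueError("budget has zero aromatic units")
    conc = {k: total_mM * v / total_counts for k, v in counts.items()}
    # exact conservation of the requested total despite float division
    drift = total_mM - sum(conc.values())
    biggest = max(conc, key=conc.get)
    conc[biggest] += drift
    return MixtureRecipe(concentrations_mM=conc, total_mM=total_mM)


def base_composition(sequence: str) -> dict:
    """Exact base counts and molar percentages of a DNA/RNA sequence.

    Accepts A/C/G/T/U (case-insensitive).  Returns counts, unrounded molar
    percentages and percentages rounded half-away-from-zero to integers.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    counts = {b: 0 for b in NUCLEOBASE_UNITS}
    for i, ch in enumerate(seq):
        if ch not in counts:
            raise ValueError(f"invalid character {ch!r} at position {i}")
        counts[ch] += 1
    n = len(seq)
    counts = {b: c for b, c in counts.items() if c > 0}
    pct = {b: 100.0 * c / n for b, c in counts.items()}
    return {
        "length": n,
        "counts": counts,
        "molar_percent": pct,
        "molar_percent_rounded": {b: int(round_half_away(v))
                                  for b, v in pct.items()},
    }
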