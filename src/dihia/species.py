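"""Diisocyanate species and NCO-mass unit conversion.

Air concentrations of different diisocyanates (DIs) are made comparable by
expressing mass as the reactive isocyanate (NCO) group:

    ug NCO/m3 = ug DI/m3 * (mass of NCO groups / molecular weight of DI)

Each species carries its molecular weight, number of NCO groups and the name
of the urinary diamine metabolite it hydrolyses to (MDI->MDA, TDI->TDA,
HDI->HDA, IPDI->IPDA).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

#: molar mass of one N=C=O group, g/mol
NCO_GROUP_MASS = 42.017


@dataclass(frozen=True)
class DiSpecies:
    """A diisocyanate analyte.

    Parameters
    ----------
    name : str
        Species identifier (e.g. ``"MDI"``).
    molecular_weight : float
        Molar mass of the diisocyanate, g/mol.
    n_nco_groups : int
        Number of isocyanate groups (2 for all common diisocyanates).
    metabolite_name : str
        Urinary diamine measured in biomonitoring (e.g. ``"MDA"``).
    """

    name: str
    molecular_weight: float
    n_nco_groups: int
    metabolite_name: str

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular_weight must be > 0")
        if self.n_nco_groups < 1:
            raise ValueError(f"{self.name}: n_nco_groups must be >= 1")
        if not 0.0 < self.nco_fraction < 1.0:
            raise ValueError(
                f"{self.name}: NCO mass fraction {self.nco_fraction:.3f} "
                "must lie strictly between 0 and 1"
            )

    @property
    def nco_fraction(self) -> float:
        """Mass fraction of the molecule carried by its NCO groups."""
        return self.n_nco_groups * NCO_GROUP_MASS / self.molecular_weight


def _load_registry() -> tuple[dict[str, DiSpecies], dict[str, float]]:
    text = resources.files("dihia.data").joinpath("species.yaml").read_text()
    raw = yaml.safe_load(text)
    reg = {}
    for name, rec in raw["species"].items():
        reg[name] = DiSpecies(
            name=name,
            molecular_weight=float(rec["molecular_weight"]),
            n_nco_groups=int(rec["n_nco_groups"]),
            metabolite_name=rec["metabolite"],
        )
    oel = {k: float(v) for k, v in raw["oel"].items()}
    return reg, oel


SPECIES, _OEL_RAW = _load_registry()

#: metabolite name -> parent species
METABOLITE_TO_SPECIES = {sp.metabolite_name: sp for sp in SPECIES.values()}


@dataclass(frozen=True)
class OelThresholds:
    """Occupational exposure limits for isocyanates, ug NCO/m3."""

    short_term_fi: float = _OEL_RAW["short_term_fi"]
    proposed_boel: float = _OEL_RAW["proposed_boel"]
    proposed_boel_2029: float = _OEL_RAW["proposed_boel_2029"]

    def __post_init__(self) -> None:
        for f in ("short_term_fi", "proposed_boel", "proposed_boel_2029"):
            if getattr(self, f) <= 0:
                raise ValueError(f"OEL {f} must be positive")


def get_species(name: str) -> DiSpecies:
    """Look up a species by its own name or by its metabolite's name."""
    if name in SPECIES:
        return SPECIES[name]
    if name in METABOLITE_TO_SPECIES:
        return METABOLITE_TO_SPECIES[name]
    raise KeyError(
        f"unknown diisocyanate or metabolite {name!r}; "
        f"known: {sorted(SPECIES)} / {sorted(METABOLITE_TO_SPECIES)}"
    )


def convert_di_to_nco(conc: float, species: DiSpecies | str) -> float:
    """Convert an air concentration from ug DI/m3 to ug NCO/m3.

    The conversion multiplies by the species' NCO mass fraction and is
    therefore linear in ``conc``.
    """
    if isinstance(species, str):
        species = get_species(species)
    if conc < 0:
        raise ValueError("concentration must be nonnegative")
    return conc * species.nco_fraction


def convert_nco_to_di(conc_nco: float, species: DiSpecies | str) -> float:
    """Inverse of :func:`convert_di_to_nco`."""
    if isinstance(species, str):
        species = get_species(species)
    if conc_nco < 0:
        raise ValueError("concentration must be nonnegative")
    return conc_nco / species.nco_fraction
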