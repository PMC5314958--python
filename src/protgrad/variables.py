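"""Canonical gradient variables and their motivation groups.

The analysis distinguishes three groups of drivers of land protection:

* ``representative`` — six biophysical gradients (climate, relief, soils) along
  which a representativeness-seeking network would spread protection evenly;
* ``preferential`` — five variables proxying valued conditions (tourism
  attractiveness, proximity to international frontiers, standing biomass,
  animal and vascular-plant species richness);
* ``opportunistic`` — four variables proxying low-cost / low-conflict land
  (population, isolation from cities, distance to coasts, cropland suitability).

The random forest ranks only the preferential + opportunistic nine; the
biophysical six are the gradients whose evenness is the representativeness
diagnostic, so their "importance" would measure the opposite of what is meant.
"""

from __future__ import annotations

REPRESENTATIVE = "representative"
PREFERENTIAL = "preferential"
OPPORTUNISTIC = "opportunistic"

GROUPS = (REPRESENTATIVE, PREFERENTIAL, OPPORTUNISTIC)

#: The 15 canonical gradient variables, in canonical order.
CANONICAL_VARIABLES: dict[str, str] = {
    "temperature": REPRESENTATIVE,          # mean annual, degC
    "precipitation": REPRESENTATIVE,        # annual, mm
    "ppt_pet": REPRESENTATIVE,              # precipitation : potential-ET ratio
    "elevation": REPRESENTATIVE,            # m a.s.l.
    "slope": REPRESENTATIVE,                # terrain slope, degrees
    "soil_fertility": REPRESENTATIVE,       # topsoil exchangeable bases, cmolc/kg
    "tourism": PREFERENTIAL,                # photo density per inhabitant
    "frontiers": PREFERENTIAL,              # distance to international frontiers, km
    "biomass": PREFERENTIAL,                # living biomass carbon, Mg/ha
    "animal_richness": PREFERENTIAL,        # breeding vertebrate species count
    "plant_richness": PREFERENTIAL,         # vascular plant species count
    "population": OPPORTUNISTIC,            # inhabitants per cell
    "isolation": OPPORTUNISTIC,             # travel time to large cities, minutes
    "coasts": OPPORTUNISTIC,                # distance to ocean coasts, km
    "cropland_suitability": OPPORTUNISTIC,  # rain-fed crop suitability, 0-100
}

VARIABLE_ORDER: tuple[str, ...] = tuple(CANONICAL_VARIABLES)

#: Predictors entering the random forest (preferential + opportunistic).
RF_PREDICTORS: tuple[str, ...] = tuple(
    v for v, g in CANONICAL_VARIABLES.items() if g != REPRESENTATIVE
)

#: Animal and plant richness proxy the single "biological conservation"
#: motivation and are pre-averaged before the preferential group average.
BIOLOGICAL_PAIR: tuple[str, str] = ("animal_richness", "plant_richness")

#: Items entering each motivation-group average. A tuple item is pre-averaged
#: into one value before the group mean is taken.
GROUP_ITEMS: dict[str, tuple] = {
    PREFERENTIAL: ("tourism", "frontiers", "biomass", BIOLOGICAL_PAIR),
    OPPORTUNISTIC: ("population", "isolation", "coasts", "cropland_suitability"),
}


def group_of(variable: str) -> str:
    """Return the motivation group of a canonical variable."""
    try:
        return CANONICAL_VARIABLES[variable]
    except KeyError:
        raise KeyError(f"unknown canonical variable {variable!r}") from None
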