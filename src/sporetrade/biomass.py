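"""Colonization measurements to common biomass units and reproductive allocation.

The allocation experiment measures, per fungal species x host plant x
replicate pot: root colonization as ergosterol (ug per g dry root), soil
colonization as hyphal length (m per g dry soil), and spore output R as
spore density (spores per g dry soil).  This module converts those to a
common mass currency:

* ergosterol -> root hyphal length by inverting the calibration
  ``E (ug) = 0.4 * L (m) + 0.18``;
* hyphal length -> dry mass by treating hyphae as cylinders of radius 4 um
  (mid-value of the 1-10 um range reported for AM hyphae) with dry density
  0.23 g/cm^3;
* body size W_alpha = mass of total mycelium, root plus soil compartments;
* allocation to reproduction A = R * W0, with W0 the single-spore mass.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sporetrade.trait_db import SPORE_MASS_PER_UM3

logger = logging.getLogger(__name__)

#: colonization CSV schema
COLONIZATION_COLUMNS = (
    "fungal_species", "host_species", "replicate",
    "root_ergosterol_ug_per_g", "soil_hyphal_m_per_g", "spores_per_g",
)


@dataclass(frozen=True)
class ConversionConstants:
    """Physical constants of the conversion chain (overridable, logged)."""

    spore_mass_per_volume: float = SPORE_MASS_PER_UM3  # ug / um^3
    hyphal_radius: float = 4.0                          # um
    hyphal_density: float = 0.23                        # g / cm^3 dry
    ergosterol_slope: float = 0.4                       # ug per m hyphae
    ergosterol_intercept: float = 0.18                  # ug

    def __post_init__(self) -> None:
        non_default = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value <= 0:
                raise ValueError(f"{f.name} must be positive")
            if value != f.default:
                non_default.append(f"{f.name}={value}")
        if non_default:
            logger.info("non-default conversion constants: %s", ", ".join(non_default))


DEFAULT_CONSTANTS = ConversionConstants()


def ergosterol_to_hyphal_length(ergosterol: float,
                                constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Invert the ergosterol calibration to root hyphal length in meters.

    ``L = (E - intercept) / slope``; ergosterol below the intercept would
    imply negative length and clamps to 0 with a warning.
    """
    if ergosterol < 0:
        raise ValueError(f"ergosterol must be nonnegative, got {ergosterol}")
    length = (ergosterol - constants.ergosterol_intercept) / constants.ergosterol_slope
    if length < 0:
        logger.warning(
            "ergosterol %.4g ug below calibration intercept %.2f; clamping length to 0",
            ergosterol, constants.ergosterol_intercept,
        )
        return 0.0
    return length


def hyphal_length_to_dry_mass(length: float,
                              constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Dry mass (ug) of ``length`` meters of cylindrical hyphae.

    volume = pi r^2 L; with r in um and L in m the volume in cm^3 is
    ``pi * r^2 * L * 1e-6``, and mass follows from the dry density.
    """
    if length < 0:
        raise ValueError(f"length must be nonnegative, got {length}")
    volume_cm3 = math.pi * constants.hyphal_radius**2 * length * 1e-6
    mass_g = volume_cm3 * constants.hyphal_density
    return mass_g * 1e6  # ug


def dry_mass_to_hyphal_length(mass_ug: float,
                              constants: ConversionConstants = DEFAULT_CONSTANTS) -> float:
    """Inverse of :func:`hyphal_length_to_dry_mass` (meters from ug)."""
    if mass_ug < 0:
        raise ValueError("mass must be nonnegative")
    return mass_ug / (math.pi * constants.hyphal_radius**2 * constants.hyphal_density)


def total_body_size(root_ergosterol: float, soil_hyphal_length: float,
                    constants: ConversionConstants = DEFAULT_CONSTANTS,
                    ) -> tuple[float, float]:
    """Body mass W_alpha (ug) and total hyphal length (m) of one record.

    Root length is recovered from ergosterol, added to the measured soil
    length, and the sum converted to dry mass.
    """
    root_len = ergosterol_to_hyphal_length(root_ergosterol, constants)
    total_len = root_len + soil_hyphal_length
    return hyphal_length_to_dry_mass(total_len, constants), total_len


def reproductive_allocation(spore_output: float, spore_mass: float) -> float:
    """Total mass allocated to reproduction, A = R * W0 (ug per g soil)."""
    if spore_mass <= 0:
        raise ValueError(f"spore mass W0 must be positive, got {spore_mass}")
    if spore_output < 0:
        raise ValueError(f"spore output must be nonnegative, got {spore_output}")
    return spore_output * spore_mass


def read_colonization_table(path) -> pd.DataFrame:
    """Read and validate a colonization CSV."""
    df = pd.read_csv(path)
    missing = set(COLONIZATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    meas = ["root_ergosterol_ug_per_g", "soil_hyphal_m_per_g", "spores_per_g"]
    if (df[meas] < 0).any().any():
        raise ValueError(f"{path}: negative measurement values")
    dup = df.duplicated(["fungal_species", "host_species", "replicate"])
    if dup.any():
        raise ValueError(f"{path}: duplicate replicate ids within species x host")
    return df


def build_allocation_table(colonization: pd.DataFrame,
                           spore_mass_ug: dict[str, float] | pd.Series,
                           constants: ConversionConstants = DEFAULT_CONSTANTS,
                           aggregate_replicates: bool = True) -> pd.DataFrame:
    """Per species x host allocation records from raw colonization data.

    ``spore_mass_ug`` maps fungal species to single-spore mass W0 (ug), as
    produced by the trait database.  Replicates are averaged to species x
    host means before conversion by default (each fitted point is one
    species growing with one host); per-replicate rows are kept with
    ``aggregate_replicates=False``.  Species without a W0 entry are dropped
    with a logged note.

    Returns columns: fungal_species, host_species, spore_output_R (per g
    soil), spore_mass_W0 (ug), allocation_A (ug per g soil), body_mass_Walpha
    (ug), extraradical_length (m per g soil).
    """
    spore_mass = pd.Series(spore_mass_ug, dtype=float)
    df = colonization.copy()
    known = df["fungal_species"].isin(spore_mass.index)
    if not known.all():
        dropped = sorted(df.loc[~known, "fungal_species"].unique())
        logger.info("dropping species without spore-size data: %s", dropped)
        df = df[known]
    if df.empty:
        raise ValueError("no colonization rows with matching spore sizes")

    keys = ["fungal_species", "host_species"]
    if aggregate_replicates:
        df = df.groupby(keys, as_index=False, sort=False)[
            ["root_ergosterol_ug_per_g", "soil_hyphal_m_per_g", "spores_per_g"]
        ].mean()

    walpha, ext_len = zip(*(
        total_body_size(e, s, constants)
        for e, s in zip(df["root_ergosterol_ug_per_g"], df["soil_hyphal_m_per_g"])
    ))
    out = pd.DataFrame({
        "fungal_species": df["fungal_species"].to_numpy(),
        "host_species": df["host_species"].to_numpy(),
        "spore_output_R": df["spores_per_g"].to_numpy(float),
        "spore_mass_W0": spore_mass.reindex(df["fungal_species"]).to_numpy(),
        "body_mass_Walpha": np.asarray(walpha),
        "extraradical_length": df["soil_hyphal_m_per_g"].to_numpy(float),
    })
    if not aggregate_replicates:
        out.insert(2, "replicate", df["replicate"].to_numpy())
    out["allocation_A"] = [
        reproductive_allocation(r, w)
        for r, w in zip(out["spore_output_R"], out["spore_mass_W0"])
    ]
    return out
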