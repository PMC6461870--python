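"""Spore trait database: diameter ranges to volumes and masses.

Taxonomic descriptions of arbuscular mycorrhizal (AM) fungi report spore size
as diameter ranges: an *inner* range covering most spores of a species and an
optional *outer* range with extreme values.  Spores described as "globose"
get a single diameter range and are treated as spheres; "subglobose" spores
get a long-axis and a short-axis range and are treated as prolate spheroids
(the short axis duplicated).  Volumes convert to dry mass with the empirical
constant 3.64e-7 ug per um^3 (from the only AMF species with both spore
volume and spore weight published, Funneliformis caledonium).

A few Ambisporaceae species are dimorphic, producing a smaller "glomoid" and
a larger "acaulosporoid" spore type; such species carry one record per morph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: dry mass of 1 um^3 of AMF spore, in ug
SPORE_MASS_PER_UM3 = 3.64e-7

MORPH_LABELS = ("default", "glomoid", "acaulosporoid")
SHAPE_CLASSES = ("globose", "subglobose")

#: expected columns of a trait CSV (long axis required, the rest optional)
TRAIT_COLUMNS = (
    "species", "family", "morph", "shape",
    "inner_low_long", "inner_high_long", "outer_low_long", "outer_high_long",
    "inner_low_short", "inner_high_short", "outer_low_short", "outer_high_short",
)


@dataclass(frozen=True)
class SporeRecord:
    """Raw diameter-range description of one species x morph, in um."""

    species_id: str
    family: str
    morph_label: str = "default"
    shape_class: str = "globose"
    inner_range_long: tuple[float, float] = (0.0, 0.0)
    outer_range_long: tuple[float, float] | None = None
    inner_range_short: tuple[float, float] | None = None
    outer_range_short: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.morph_label not in MORPH_LABELS:
            raise ValueError(f"unknown morph label {self.morph_label!r}")
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        for name in ("inner_range_long", "outer_range_long",
                     "inner_range_short", "outer_range_short"):
            pair = getattr(self, name)
            if pair is None:
                continue
            low, high = pair
            if not (0 < low <= high):
                raise ValueError(
                    f"{self.species_id} ({self.morph_label}): {name} must satisfy "
                    f"0 < low <= high, got {pair}"
                )
        if self.shape_class == "subglobose" and self.inner_range_short is None:
            raise ValueError(
                f"{self.species_id}: subglobose record requires a short-axis inner range"
            )


@dataclass(frozen=True)
class SporeSize:
    """Derived single-spore geometry and mass for one species x morph.

    ``diameter_long``/``diameter_short`` are range midpoints in um, ``volume``
    in um^3 and ``mass`` in ug.  For globose spores the two diameters match.
    """

    species_id: str
    morph_label: str
    range_basis: str
    diameter_long: float
    diameter_short: float
    volume: float
    mass: float

    def __post_init__(self) -> None:
        if self.diameter_short > self.diameter_long + 1e-12:
            raise ValueError("short diameter exceeds long diameter")
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@dataclass
class TaxaDistribution:
    """Offspring-size sample for one taxon, single consistent unit."""

    taxon_label: str
    values: np.ndarray
    unit: str = "um3"
    quantiles: dict = field(init=False)
    log10_span: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size < 2:
            raise ValueError(f"{self.taxon_label}: need >= 2 values")
        if np.any(v <= 0):
            raise ValueError(f"{self.taxon_label}: offspring sizes must be positive")
        self.values = v
        q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])
        self.quantiles = {"q25": float(q25), "median": float(med), "q75": float(q75)}
        self.log10_span = float(np.log10(v.max() / v.min()))


def volume_to_mass(volume: float) -> float:
    """Convert a spore volume (um^3) to dry mass (ug).

    Linear conversion at 3.64e-7 ug/um^3.
    """
    if volume < 0:
        raise ValueError(f"volume must be nonnegative, got {volume}")
    return volume * SPORE_MASS_PER_UM3


def sphere_volume(diameter: float) -> float:
    return math.pi / 6.0 * diameter**3


def prolate_spheroid_volume(d_long: float, d_short: float) -> float:
    """Volume of a prolate spheroid with the short axis duplicated."""
    return math.pi / 6.0 * d_long * d_short**2


def _midpoint(pair: tuple[float, float]) -> float:
    return 0.5 * (pair[0] + pair[1])


def compute_spore_size(rec: SporeRecord, range_basis: str = "inner") -> SporeSize:
    """Derive a single spore volume and mass from a diameter-range record.

    The diameter on each axis is the midpoint of the chosen (inner or outer)
    range.  Globose spores: sphere of that diameter.  Subglobose spores:
    prolate spheroid, V = (pi/6) * d_long * d_short^2.  Records lacking the
    requested outer range fall back to the inner range with a logged note.
    """
    if range_basis not in ("inner", "outer"):
        raise ValueError(f"range_basis must be 'inner' or 'outer', got {range_basis!r}")

    long_pair = rec.inner_range_long
    short_pair = rec.inner_range_short
    if range_basis == "outer":
        if rec.outer_range_long is not None:
            long_pair = rec.outer_range_long
        else:
            logger.info("%s: outer range missing, falling back to inner", rec.species_id)
        if rec.shape_class == "subglobose":
            short_pair = rec.outer_range_short or rec.inner_range_short

    d_long = _midpoint(long_pair)
    if rec.shape_class == "globose":
        d_short = d_long
        volume = sphere_volume(d_long)
    else:
        d_short = _midpoint(short_pair)
        if d_short > d_long:
            # axis labels occasionally swapped in descriptions
            d_long, d_short = d_short, d_long
        volume = prolate_spheroid_volume(d_long, d_short)
    if d_long <= 0 or d_short <= 0:
        raise ValueError(f"{rec.species_id}: non-positive derived diameter")

    return SporeSize(
        species_id=rec.species_id,
        morph_label=rec.morph_label,
        range_basis=range_basis,
        diameter_long=d_long,
        diameter_short=d_short,
        volume=volume,
        mass=volume_to_mass(volume),
    )


def _parse_pair(row: pd.Series, low_col: str, high_col: str,
                species: str) -> tuple[float, float] | None:
    lo, hi = row.get(low_col), row.get(high_col)
    if pd.isna(lo) and pd.isna(hi):
        return None
    try:
        lo, hi = float(lo), float(hi)
    except (TypeError, ValueError) as exc:
        raise ValueError(
            f"species {species!r}: malformed numeric cell in {low_col}/{high_col}"
        ) from exc
    return (lo, hi)


def parse_trait_table(path, range_basis: str = "inner") -> list[SporeRecord]:
    """Read a spore-trait CSV into :class:`SporeRecord` objects, in file order.

    The CSV is comma-separated UTF-8 with a mandatory header; diameters are
    in um.  Dimorphic species appear as one row per morph.  Duplicate
    species x morph rows and invalid ranges raise with the offending species
    named.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: trait table is empty")
    missing = {"species", "family", "shape"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")

    records: list[SporeRecord] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        species = str(row["species"])
        morph = str(row["morph"]) if "morph" in df.columns and pd.notna(row.get("morph")) else "default"
        key = (species, morph)
        if key in seen:
            raise ValueError(f"duplicate species x morph entry: {key}")
        seen.add(key)
        try:
            rec = SporeRecord(
                species_id=species,
                family=str(row["family"]),
                morph_label=morph,
                shape_class=str(row["shape"]).strip().lower(),
                inner_range_long=_parse_pair(row, "inner_low_long", "inner_high_long", species),
                outer_range_long=_parse_pair(row, "outer_low_long", "outer_high_long", species),
                inner_range_short=_parse_pair(row, "inner_low_short", "inner_high_short", species),
                outer_range_short=_parse_pair(row, "outer_low_short", "outer_high_short", species),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx} (species {species!r}): {exc}") from exc
        if range_basis == "outer" and rec.outer_range_long is None:
            logger.info("%s: no outer range in table, inner will be used", species)
        records.append(rec)
    return records


def size_table(records: Sequence[SporeRecord], range_basis: str = "inner") -> pd.DataFrame:
    """Tidy DataFrame of derived spore sizes for a set of records."""
    sizes = [compute_spore_size(r, range_basis) for r in records]
    return pd.DataFrame(
        {
            "species": [s.species_id for s in sizes],
            "morph": [s.morph_label for s in sizes],
            "range_basis": [s.range_basis for s in sizes],
            "diameter_long_um": [s.diameter_long for s in sizes],
            "diameter_short_um": [s.diameter_short for s in sizes],
            "volume_um3": [s.volume for s in sizes],
            "mass_ug": [s.mass for s in sizes],
        }
    )


def select_morph(records: Sequence[SporeRecord], morph: str) -> list[SporeRecord]:
    """One record per species: the requested morph where dimorphic, else default.

    ``morph`` is ``"glomoid"`` or ``"acaulosporoid"``.
    """
    if morph not in ("glomoid", "acaulosporoid"):
        raise ValueError(f"morph must be 'glomoid' or 'acaulosporoid', got {morph!r}")
    by_species: dict[str, dict[str, SporeRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.species_id not in by_species:
            order.append(r.species_id)
        by_species.setdefault(r.species_id, {})[r.morph_label] = r
    out = []
    for sp in order:
        morphs = by_species[sp]
        out.append(morphs.get(morph) or morphs.get("default") or next(iter(morphs.values())))
    return out


def compare_taxa(groups: Sequence[TaxaDistribution]) -> pd.DataFrame:
    """Summarize and pairwise-compare offspring-size distributions.

    Returns a per-group summary (quantiles, log10 span, geometric mean) with
    pairwise fold-differences attached as ``.attrs["pairwise"]``: for each
    ordered pair, the ratio of geometric means (primary, since sizes are
    analyzed on log scale) and of arithmetic means (secondary).
    """
    if len(groups) < 1:
        raise ValueError("need at least one group")
    units = {g.unit for g in groups}
    if len(units) > 1:
        raise ValueError(f"groups declare mixed units: {sorted(units)}")

    rows = []
    for g in groups:
        rows.append(
            {
                "taxon": g.taxon_label,
                "n": int(g.values.size),
                "q25": g.quantiles["q25"],
                "median": g.quantiles["median"],
                "q75": g.quantiles["q75"],
                "log10_span": g.log10_span,
                "geometric_mean": float(np.exp(np.mean(np.log(g.values)))),
                "arithmetic_mean": float(np.mean(g.values)),
            }
        )
    summary = pd.DataFrame(rows)

    pairwise = []
    for a in groups:
        for b in groups:
            gm_a = np.exp(np.mean(np.log(a.values)))
            gm_b = np.exp(np.mean(np.log(b.values)))
            pairwise.append(
                {
                    "taxon_a": a.taxon_label,
                    "taxon_b": b.taxon_label,
                    "fold_geometric": float(gm_a / gm_b),
                    "fold_arithmetic": float(np.mean(a.values) / np.mean(b.values)),
                }
            )
    summary.attrs["pairwise"] = pd.DataFrame(pairwise)
    summary.attrs["unit"] = groups[0].unit
    return summary
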