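"""Experimental design of a pot-based grass–legume diversity experiment.

The design emulated here is a mesocosm (large outdoor pot) diversity
experiment: a small species pool (by default four perennial grasses and one
legume, white clover) is grown in monocultures, all pairwise mixtures and the
full-pool mixture, under a repeated cutting regime.  The growing season is
split into consecutive biomass-production periods delimited by the cuts; the
calendar is expressed as (year index, day of year) so that a period spanning
the winter (e.g. DOY 281 of year 1 to DOY 101 of year 2) is representable.

Sward types label richness × legume presence: ``1-``/``1+`` monocultures
without/with the legume, ``2-``/``2+`` two-species mixtures, ``5+`` the
five-species mixture (always containing the legume in the default pool).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "TRAIT_NAMES",
    "Period",
    "DEFAULT_PERIODS",
    "SpeciesSpec",
    "PotSpec",
    "DesignSpec",
    "default_species_pool",
    "build_design",
    "day_number",
]

#: Species-level trait names used throughout the package (units in docstrings
#: of :class:`SpeciesSpec`).
TRAIT_NAMES = (
    "SLA",              # specific leaf area, m^2 kg^-1
    "LDMC",             # leaf dry matter content, mg g^-1
    "N",                # leaf nitrogen content, %
    "d13C",             # leaf carbon isotopic composition, per mil
    "height_growth",    # vegetative height growth rate, cm day^-1
    "root_growth",      # deep root length growth rate, mm cm^-2 day^-1
    "top_layer_share",  # share of above-ground biomass in the top canopy layer, %
)


def day_number(date: tuple[int, int]) -> int:
    """Absolute day number of a (year, DOY) date on a 365-day calendar.

    Year 1 DOY 1 maps to 1.  Leap days are ignored; the synthetic calendar
    is a bookkeeping device, not a civil calendar.
    """
    year, doy = date
    if not 1 <= doy <= 365:
        raise ValueError(f"day of year out of range: {doy}")
    return (year - 1) * 365 + doy


@dataclass(frozen=True)
class Period:
    """A biomass-production period between two consecutive cuts."""

    label: str
    start: tuple[int, int]  # (year, DOY), inclusive
    end: tuple[int, int]    # (year, DOY), inclusive

    def __post_init__(self) -> None:
        if day_number(self.end) < day_number(self.start):
            raise ValueError(f"period {self.label!r} ends before it starts")

    @property
    def start_day(self) -> int:
        return day_number(self.start)

    @property
    def end_day(self) -> int:
        return day_number(self.end)

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1

    def contains(self, date: tuple[int, int]) -> bool:
        return self.start_day <= day_number(date) <= self.end_day


#: The six default production periods: spring year 1, early summer year 1,
#: late summer year 1, autumn year 1, autumn year 1 – early spring year 2
#: (spanning the winter), and spring year 2.
DEFAULT_PERIODS: tuple[Period, ...] = (
    Period("113-143", (1, 113), (1, 143)),
    Period("144-190", (1, 144), (1, 190)),
    Period("191-224", (1, 191), (1, 224)),
    Period("225-280", (1, 225), (1, 280)),
    Period("281-101", (1, 281), (2, 101)),
    Period("102-161", (2, 102), (2, 161)),
)


@dataclass(frozen=True)
class SpeciesSpec:
    """Static description of one species in the pool.

    Parameters
    ----------
    species_id
        Short code, e.g. ``"dg"``.
    functional_group
        ``"grass"`` or ``"legume"``.
    stature
        ``"tall"`` or ``"short"``.
    rooting
        ``"deep"``, ``"shallow"`` or ``"intermediate"``.
    mono_yield_by_period
        Baseline mean monoculture above-ground biomass (g pot^-1), one value
        per production period.
    trait_means, trait_sds
        Per-trait mean and between-pot standard deviation; keys must be a
        subset of :data:`TRAIT_NAMES`.
    green_leaf_fraction
        Fraction of above-ground biomass that is green leaf, used for the
        green-leaf abundance weighting of community nitrogen.
    """

    species_id: str
    functional_group: str
    stature: str
    rooting: str
    mono_yield_by_period: tuple[float, ...]
    trait_means: dict[str, float] = field(default_factory=dict)
    trait_sds: dict[str, float] = field(default_factory=dict)
    green_leaf_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.functional_group not in ("grass", "legume"):
            raise ValueError(f"unknown functional group {self.functional_group!r}")
        if any(m < 0 for m in self.mono_yield_by_period):
            raise ValueError(f"{self.species_id}: monoculture yields must be >= 0")
        for name in list(self.trait_means) + list(self.trait_sds):
            if name not in TRAIT_NAMES:
                raise ValueError(f"{self.species_id}: unknown trait {name!r}")
        if any(s < 0 for s in self.trait_sds.values()):
            raise ValueError(f"{self.species_id}: trait SDs must be >= 0")
        if not 0 <= self.green_leaf_fraction <= 1:
            raise ValueError(f"{self.species_id}: green_leaf_fraction must be in [0, 1]")

    @property
    def is_legume(self) -> bool:
        return self.functional_group == "legume"


@dataclass(frozen=True)
class PotSpec:
    """One pot: its species composition, sown proportions and labels."""

    pot_id: str
    composition: tuple[str, ...]
    proportions: tuple[float, ...]
    replicate: int
    sward_type: str

    def __post_init__(self) -> None:
        if len(self.composition) != len(self.proportions):
            raise ValueError(f"{self.pot_id}: composition/proportion length mismatch")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError(f"{self.pot_id}: sown proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError(f"{self.pot_id}: sown proportions must be >= 0")

    @property
    def richness(self) -> int:
        return len(self.composition)


@dataclass(frozen=True)
class DesignSpec:
    """Full experimental design: pots, period calendar, measurement dates.

    ``measurement_dates`` maps an instrument name (``"leaf"``, ``"height"``,
    ``"root"``, ``"canopy_layer"``, ``"isotope"``) to the ordered (year, DOY)
    dates at which that instrument was read.
    """

    pots: tuple[PotSpec, ...]
    periods: tuple[Period, ...] = DEFAULT_PERIODS
    measurement_dates: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.pot_id for p in self.pots]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pot ids in design")

    @property
    def species_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for pot in self.pots:
            for s in pot.composition:
                seen.setdefault(s)
        return tuple(seen)

    @property
    def calendar_start(self) -> tuple[int, int]:
        return self.periods[0].start

    @property
    def calendar_end(self) -> tuple[int, int]:
        return self.periods[-1].end

    def period(self, label: str) -> Period:
        for p in self.periods:
            if p.label == label:
                return p
        raise KeyError(f"unknown period {label!r}")

    def period_of(self, date: tuple[int, int]) -> Period | None:
        """Period containing *date*, or None if the date falls between cuts."""
        for p in self.periods:
            if p.contains(date):
                return p
        return None

    def sward_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for pot in self.pots:
            counts[pot.sward_type] = counts.get(pot.sward_type, 0) + 1
        return counts

    def pots_for_composition(self, composition: tuple[str, ...]) -> list[PotSpec]:
        key = tuple(sorted(composition))
        return [p for p in self.pots if tuple(sorted(p.composition)) == key]

    def compositions(self, min_richness: int = 1) -> list[tuple[str, ...]]:
        seen: dict[tuple[str, ...], None] = {}
        for pot in self.pots:
            if pot.richness >= min_richness:
                seen.setdefault(pot.composition)
        return list(seen)


def default_species_pool() -> list[SpeciesSpec]:
    """The default five-species pool: four grasses and one legume.

    The grasses split into tall deep-rooted (cocksfoot ``dg``, tall fescue
    ``fa``) and short shallow-rooted (smooth meadow-grass ``pp``, yellow
    oat-grass ``tf``) strategies; the legume is white clover (``tr``) with an
    intermediate rooting pattern.  Baseline monoculture yields follow the
    seasonal course of a cut fertile upland sward (high spring and early
    summer production, reduced autumn and winter regrowth); the legume
    establishes slowly in its first spring and yields more later.  Trait
    means separate an acquisitive legume (high SLA and N, low LDMC, more
    negative d13C) from conservative grasses, and tall from short grasses in
    height growth and canopy-top share.
    """
    grass_base = (92.6, 149.6, 85.3, 74.1, 59.1, 54.6)
    legume_yield = (31.2, 159.7, 120.4, 134.8, 100.3, 118.3)

    def scale(factors: float) -> tuple[float, ...]:
        return tuple(round(v * factors, 2) for v in grass_base)

    pool = [
        SpeciesSpec(
            "dg", "grass", "tall", "deep", scale(1.10),
            trait_means={"SLA": 22.0, "LDMC": 250.0, "N": 2.0, "d13C": -27.8,
                         "height_growth": 0.90, "root_growth": 0.060,
                         "top_layer_share": 60.0},
            trait_sds={"SLA": 1.5, "LDMC": 15.0, "N": 0.15, "d13C": 0.2,
                       "height_growth": 0.08, "root_growth": 0.008,
                       "top_layer_share": 5.0},
            green_leaf_fraction=0.75,
        ),
        SpeciesSpec(
            "fa", "grass", "tall", "deep", scale(1.05),
            trait_means={"SLA": 18.0, "LDMC": 280.0, "N": 1.8, "d13C": -27.5,
                         "height_growth": 0.80, "root_growth": 0.055,
                         "top_layer_share": 58.0},
            trait_sds={"SLA": 1.2, "LDMC": 18.0, "N": 0.14, "d13C": 0.2,
                       "height_growth": 0.07, "root_growth": 0.007,
                       "top_layer_share": 5.0},
            green_leaf_fraction=0.75,
        ),
        SpeciesSpec(
            "pp", "grass", "short", "shallow", scale(0.92),
            trait_means={"SLA": 20.0, "LDMC": 260.0, "N": 2.1, "d13C": -28.2,
                         "height_growth": 0.45, "root_growth": 0.020,
                         "top_layer_share": 40.0},
            trait_sds={"SLA": 1.4, "LDMC": 16.0, "N": 0.16, "d13C": 0.2,
                       "height_growth": 0.05, "root_growth": 0.004,
                       "top_layer_share": 5.0},
            green_leaf_fraction=0.8,
        ),
        SpeciesSpec(
            "tf", "grass", "short", "shallow", scale(0.88),
            trait_means={"SLA": 24.0, "LDMC": 240.0, "N": 2.2, "d13C": -28.4,
                         "height_growth": 0.50, "root_growth": 0.025,
                         "top_layer_share": 42.0},
            trait_sds={"SLA": 1.6, "LDMC": 14.0, "N": 0.16, "d13C": 0.2,
                       "height_growth": 0.05, "root_growth": 0.004,
                       "top_layer_share": 5.0},
            green_leaf_fraction=0.8,
        ),
        SpeciesSpec(
            "tr", "legume", "short", "intermediate", legume_yield,
            trait_means={"SLA": 28.0, "LDMC": 180.0, "N": 3.8, "d13C": -29.5,
                         "height_growth": 0.35, "root_growth": 0.040,
                         "top_layer_share": 35.0},
            trait_sds={"SLA": 2.0, "LDMC": 12.0, "N": 0.25, "d13C": 0.2,
                       "height_growth": 0.04, "root_growth": 0.006,
                       "top_layer_share": 5.0},
            green_leaf_fraction=0.85,
        ),
    ]
    return pool


def _default_measurement_dates(periods: tuple[Period, ...]) -> dict[str, tuple[tuple[int, int], ...]]:
    """Instrument calendars mirroring the cadence of the study design."""

    def from_day(day: int) -> tuple[int, int]:
        year = (day - 1) // 365 + 1
        return (year, day - (year - 1) * 365)

    cut_dates = tuple(p.end for p in periods)
    # 18 height readings spread evenly over the growth season; 23 root-imaging
    # dates (22 growth intervals) roughly twice a month.
    h0, h1 = day_number((1, 136)), day_number((2, 156))
    height = tuple(from_day(h0 + round(i * (h1 - h0) / 17)) for i in range(18))
    r0, r1 = day_number((1, 127)), day_number((2, 147))
    root = tuple(from_day(r0 + round(i * (r1 - r0) / 22)) for i in range(23))
    return {
        "leaf": ((1, 136), (2, 157)),
        "canopy_layer": ((1, 136), (2, 157)),
        "harvest": cut_dates,
        "isotope": (periods[0].end, periods[3].end, periods[5].end),
        "height": height,
        "root": root,
    }


def build_design(
    n_reps_mono: int,
    n_reps_mix: int,
    species_pool: list[SpeciesSpec],
    periods: tuple[Period, ...] = DEFAULT_PERIODS,
) -> DesignSpec:
    """Enumerate the full design: monocultures, all pairs, full-pool mixture.

    Sward-type labels combine richness and legume presence (``"2+"`` is a
    two-species mixture containing the legume).  With the default pool and
    (4, 3) replication this yields the canonical 53-pot design:
    5 monocultures x 4 + 10 pairs x 3 + 1 five-species mixture x 3.

    Raises
    ------
    ValueError
        If the pool is empty, contains duplicate ids, or does not contain
        exactly one legume.
    """
    if not species_pool:
        raise ValueError("species pool is empty")
    ids = [s.species_id for s in species_pool]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate species ids in pool: {ids}")
    legumes = [s for s in species_pool if s.is_legume]
    if len(legumes) != 1:
        raise ValueError(f"expected exactly one legume in the pool, found {len(legumes)}")
    if n_reps_mono < 1 or n_reps_mix < 1:
        raise ValueError("replicate counts must be >= 1")
    n_periods = len(periods)
    for s in species_pool:
        if len(s.mono_yield_by_period) != n_periods:
            raise ValueError(
                f"{s.species_id}: {len(s.mono_yield_by_period)} monoculture yields "
                f"for {n_periods} periods"
            )

    legume_id = legumes[0].species_id
    compositions: list[tuple[tuple[str, ...], int]] = []
    for sid in ids:
        compositions.append(((sid,), n_reps_mono))
    for pair in itertools.combinations(ids, 2):
        compositions.append((pair, n_reps_mix))
    if len(ids) > 2:
        compositions.append((tuple(ids), n_reps_mix))

    pots: list[PotSpec] = []
    for comp, n_reps in compositions:
        richness = len(comp)
        sward = f"{richness}{'+' if legume_id in comp else '-'}"
        props = tuple(1.0 / richness for _ in comp)
        for rep in range(1, n_reps + 1):
            pot_id = f"{'-'.join(comp)}.{rep}"
            pots.append(PotSpec(pot_id, comp, props, rep, sward))

    return DesignSpec(
        pots=tuple(pots),
        periods=tuple(periods),
        measurement_dates=_default_measurement_dates(tuple(periods)),
    )
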