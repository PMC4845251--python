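"""Seeded synthetic datasets emulating a grass–legume mesocosm experiment.

The generator produces every table the analysis pipeline consumes — design,
per-period per-species biomass, trait measurements, daily pot weights with
watering additions, and soil-moisture series — together with the noise-free
ground truth (expected diversity-effect partition per composition and
period) needed for recovery tests.

Biomass model
-------------
Species *i* in a pot gets mean biomass ``M_i(period) * p_i * m`` where ``m``
combines the interaction multipliers of :class:`InteractionSpec`:

* ``complementarity_amplitude`` c: all species in all mixtures get ``1 + c``
  (a symmetric relative-yield surplus, so the ground-truth selection effect
  is exactly zero when it acts alone with equal sown proportions);
* ``facilitation_ramp[period]`` f: grasses sharing a pot with the legume get
  an extra ``1 + f`` — nondecreasing over periods by default, emulating the
  delayed onset of legume facilitation;
* ``legume_suppression_early`` s < 1: the legume's relative yield is
  multiplied by s in its establishment phase (first two periods in pairs; a
  longer, stronger schedule in the full five-species mixture, where clover
  establishes slowest).

Pot-level noise is multiplicative lognormal with coefficient of variation
``noise_cv``, mean-preserving, so ground truth computed from the noise-free
means is also the expectation of the realized tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import diversity_effects as de
from .design import (
    DEFAULT_PERIODS,
    TRAIT_NAMES,
    DesignSpec,
    SpeciesSpec,
    build_design,
    day_number,
    default_species_pool,
)

__all__ = [
    "InteractionSpec",
    "GeneratedDataset",
    "simulate_biomass",
    "simulate_water",
    "simulate_traits",
    "generate_dataset",
    "planted_response",
]

# soil-water constants (per pot): dry soil mass, pot tare, gravimetric
# moisture at the drought minimum and the well-watered maximum, and the
# watering setpoint at 80% of field capacity
DRY_SOIL_KG = 90.0
TARE_KG = 12.0
SM_MIN = 0.054
SM_MAX = 0.379
SM_SETPOINT = 0.8 * SM_MAX
ET_PER_LEAF_AREA = 0.4   # kg water per m^2 leaf per day at full canopy
REFILL_EVERY = 3         # days between watering events
SENSOR_DEPTHS = (15, 30, 50)  # cm


@dataclass(frozen=True)
class InteractionSpec:
    """Interaction multipliers and noise of the biomass generator."""

    facilitation_ramp: tuple[float, ...] = (0.0, 0.0, 0.1, 0.2, 0.3, 0.4)
    legume_suppression_early: float = 0.35
    complementarity_amplitude: float = 0.12
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.facilitation_ramp):
            raise ValueError("facilitation multipliers must be >= 0")
        if self.legume_suppression_early < 0:
            raise ValueError("legume suppression multiplier must be >= 0")
        if self.complementarity_amplitude < 0:
            raise ValueError("complementarity amplitude must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @classmethod
    def neutral(cls, n_periods: int = 6, seed: int = 0) -> "InteractionSpec":
        """No interactions, no noise: mixtures behave exactly additively."""
        return cls(
            facilitation_ramp=tuple(0.0 for _ in range(n_periods)),
            legume_suppression_early=1.0,
            complementarity_amplitude=0.0,
            noise_cv=0.0,
            seed=seed,
        )


@dataclass
class GeneratedDataset:
    """All tables of one synthetic experiment plus the generating truth."""

    design: DesignSpec
    pool: list[SpeciesSpec]
    interaction: InteractionSpec
    biomass: pd.DataFrame
    traits: pd.DataFrame
    weights: pd.DataFrame
    moisture: pd.DataFrame
    ground_truth: pd.DataFrame
    model_truth: dict | None = None


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _interaction_multiplier(
    species: SpeciesSpec,
    pot_richness: int,
    legume_present: bool,
    period_idx: int,
    ix: InteractionSpec,
) -> float:
    """Deterministic multiplier on relative yield for one species x period."""
    if pot_richness == 1:
        return 1.0
    m = 1.0 + ix.complementarity_amplitude
    if species.is_legume:
        s = ix.legume_suppression_early
        if pot_richness > 2:
            # slower establishment in the full mixture: stronger, longer
            schedule = (s * s, s * s, s, s, 1.0, 1.0)
        else:
            schedule = (s, s, 1.0, 1.0, 1.0, 1.0)
        m *= schedule[period_idx] if period_idx < len(schedule) else 1.0
    elif legume_present:
        ramp = ix.facilitation_ramp
        f = ramp[period_idx] if period_idx < len(ramp) else ramp[-1]
        m *= 1.0 + f
    return m


def simulate_biomass(
    design: DesignSpec,
    pool: list[SpeciesSpec],
    ix: InteractionSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the per-pot per-period per-species biomass table.

    Returns
    -------
    (biomass, ground_truth)
        ``biomass`` columns: ``pot_id, period, species, biomass,
        green_leaf_biomass, top_layer_biomass`` (g pot^-1).
        ``ground_truth`` holds the noise-free expected partition per mixture
        composition and period, computed with
        :func:`swardlab.diversity_effects.additive_partition` on the
        noise-free means.
    """
    species_map = {s.species_id: s for s in pool}
    period_labels = [p.label for p in design.periods]
    ss = np.random.SeedSequence(ix.seed)
    pot_seeds = ss.spawn(len(design.pots))

    rows: list[dict] = []
    for pot, child in zip(design.pots, pot_seeds):
        rng = np.random.default_rng(child)
        legume_present = any(species_map[s].is_legume for s in pot.composition)
        for pi, period in enumerate(period_labels):
            noise = _lognormal_factors(rng, ix.noise_cv, len(pot.composition))
            # per-pot per-period draw of the canopy-layer share and green
            # fraction enters downstream via the biomass splits
            for (sid, p_sown), z in zip(zip(pot.composition, pot.proportions), noise):
                sp = species_map[sid]
                mult = _interaction_multiplier(sp, pot.richness, legume_present, pi, ix)
                b = sp.mono_yield_by_period[pi] * p_sown * mult * z
                share = sp.trait_means.get("top_layer_share", 50.0) / 100.0
                rows.append({
                    "pot_id": pot.pot_id, "period": period, "species": sid,
                    "biomass": b,
                    "green_leaf_biomass": b * sp.green_leaf_fraction,
                    "top_layer_biomass": b * share,
                })
    biomass = pd.DataFrame(rows)

    # ground truth from noise-free means
    gt_rows: list[dict] = []
    for comp in design.compositions(min_richness=2):
        pots = design.pots_for_composition(comp)
        sown = dict(zip(pots[0].composition, pots[0].proportions))
        richness = len(comp)
        legume_present = any(species_map[s].is_legume for s in comp)
        for pi, period in enumerate(period_labels):
            mono = np.array([species_map[s].mono_yield_by_period[pi] for s in comp])
            prop = np.array([sown[s] for s in comp])
            mults = np.array([
                _interaction_multiplier(species_map[s], richness, legume_present, pi, ix)
                for s in comp
            ])
            expected_obs = mono * prop * mults
            res = de.additive_partition(expected_obs, mono, prop, species=comp)
            gt_rows.append({
                "composition": "-".join(comp), "period": period,
                "net_effect": res.net_effect,
                "complementarity": res.complementarity,
                "selection": res.selection,
            })
    ground_truth = pd.DataFrame(gt_rows)
    return biomass, ground_truth


def _pot_leaf_area_by_period(
    pot_biomass: pd.DataFrame, species_map: dict[str, SpeciesSpec], period_labels: list[str]
) -> dict[str, float]:
    """Full-canopy community leaf area (m^2) per period from realized biomass."""
    la = {}
    for period in period_labels:
        sub = pot_biomass[pot_biomass["period"] == period]
        la[period] = float(sum(
            r.biomass / 1000.0 * species_map[r.species].trait_means.get("SLA", 20.0)
            for r in sub.itertuples()
        ))
    return la


def simulate_water(
    design: DesignSpec,
    pool: list[SpeciesSpec],
    ix: InteractionSpec,
    biomass: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily pot weights, watering additions and soil moisture.

    A simple store-and-drawdown model: daily evapotranspiration is
    proportional to current community leaf area (which regrows within each
    period after a cut), water is drawn from the pot store (never below the
    drought-minimum moisture), and every few days the pot is refilled to the
    80%-of-field-capacity setpoint, with the addition logged.  Pot weight is
    tare + dry soil + soil water, so daily ET is exactly recoverable from
    the weight drop plus additions.  Depth-resolved sensor moisture draws
    relatively more from the deep layer in legume-containing pots.

    Returns
    -------
    (weights, moisture)
        ``weights`` columns: ``pot_id, year, doy, weight_kg, addition_kg``.
        ``moisture`` columns: ``pot_id, year, doy, moisture`` plus one
        ``swc{depth}`` column (m^3 m^-3) per sensor depth.
    """
    species_map = {s.species_id: s for s in pool}
    period_labels = [p.label for p in design.periods]
    if biomass is None:
        biomass, _ = simulate_biomass(design, pool, ix)

    start = day_number(design.calendar_start)
    end = day_number(design.calendar_end)
    days = np.arange(start, end + 1)
    # ET noise gets its own child stream per pot, independent of biomass noise
    ss = np.random.SeedSequence((ix.seed, 1))
    pot_seeds = ss.spawn(len(design.pots))

    period_of_day: dict[int, int] = {}
    for pi, p in enumerate(design.periods):
        for d in range(p.start_day, p.end_day + 1):
            period_of_day[d] = pi

    w_rows: list[dict] = []
    m_rows: list[dict] = []
    for pot, child in zip(design.pots, pot_seeds):
        rng = np.random.default_rng(child)
        legume_present = any(species_map[s].is_legume for s in pot.composition)
        la_by_period = _pot_leaf_area_by_period(
            biomass[biomass["pot_id"] == pot.pot_id], species_map, period_labels
        )
        deep_share = 0.30 if legume_present else 0.20
        layer_shares = np.array([0.5 - deep_share / 2, 0.5 - deep_share / 2, deep_share])
        layer_caps = np.array([0.25, 0.35, 0.40]) * DRY_SOIL_KG * SM_SETPOINT

        moisture = SM_SETPOINT
        layer_water = layer_caps.copy()
        et_noise = _lognormal_factors(rng, min(ix.noise_cv, 0.05), days.size)
        for di, d in enumerate(days):
            pi = period_of_day.get(int(d))
            if pi is None:
                la_max, frac = 0.0, 0.0
            else:
                p = design.periods[pi]
                frac = 0.15 + 0.85 * (d - p.start_day) / max(p.n_days - 1, 1)
                la_max = la_by_period[p.label]
            et_demand = ET_PER_LEAF_AREA * la_max * frac * et_noise[di]
            available = max((moisture - SM_MIN) * DRY_SOIL_KG, 0.0)
            et = min(et_demand, available)
            moisture -= et / DRY_SOIL_KG
            layer_water = np.maximum(layer_water - et * layer_shares, 0.0)

            addition = 0.0
            if di % REFILL_EVERY == 0:
                deficit = (SM_SETPOINT - moisture) * DRY_SOIL_KG
                if deficit > 0:
                    addition = deficit
                    moisture = SM_SETPOINT
                    layer_water = layer_caps.copy()

            year, doy = (int(d) - 1) // 365 + 1, (int(d) - 1) % 365 + 1
            w_rows.append({
                "pot_id": pot.pot_id, "year": year, "doy": doy,
                "weight_kg": TARE_KG + DRY_SOIL_KG * (1.0 + moisture),
                "addition_kg": addition,
            })
            swc = 0.40 * layer_water / layer_caps  # volumetric, setpoint ~0.40
            row = {"pot_id": pot.pot_id, "year": year, "doy": doy, "moisture": moisture}
            for depth, v in zip(SENSOR_DEPTHS, swc):
                row[f"swc{depth}"] = v
            m_rows.append(row)

    return pd.DataFrame(w_rows), pd.DataFrame(m_rows)


def simulate_traits(
    design: DesignSpec,
    pool: list[SpeciesSpec],
    ix: InteractionSpec,
    traits: tuple[str, ...] = TRAIT_NAMES,
) -> pd.DataFrame:
    """Simulate trait measurements and growth time series.

    Emits a long table ``pot_id, species, year, doy, variable, value``:

    * leaf traits (``SLA``, ``LDMC``, ``top_layer_share``) per species at the
      two leaf-sampling dates; ``N`` at every harvest; ``d13C`` at the three
      isotope harvests — all drawn around the species trait means;
    * ``height`` (cm) per species at the height-reading dates, accumulating
      at a noisy species-specific rate and reset to the 5 cm cutting height
      after each cut;
    * ``root_length`` (mm cm^-2, pot level, species empty) at the
      root-imaging dates, accumulating at a biomass-weighted community rate
      (boosted by the facilitation ramp in legume pots) with negative
      increments never generated (root length is cumulative growth).
    """
    unknown = [t for t in traits if t not in TRAIT_NAMES]
    if unknown:
        raise ValueError(f"unknown trait name(s): {unknown}")
    species_map = {s.species_id: s for s in pool}
    cal_start = day_number(design.calendar_start)
    cal_end = day_number(design.calendar_end)
    for instrument, dates in design.measurement_dates.items():
        for date in dates:
            if not cal_start <= day_number(date) <= cal_end:
                raise ValueError(
                    f"{instrument} measurement date {date} outside the design calendar"
                )

    ss = np.random.SeedSequence((ix.seed, 2))
    pot_seeds = ss.spawn(len(design.pots))
    dates = design.measurement_dates
    cut_days = [p.end_day for p in design.periods]

    rows: list[dict] = []

    def emit(pot_id, species, date, variable, value):
        rows.append({
            "pot_id": pot_id, "species": species, "year": date[0], "doy": date[1],
            "variable": variable, "value": float(value),
        })

    sampling = [
        ("SLA", "leaf"), ("LDMC", "leaf"), ("top_layer_share", "canopy_layer"),
        ("N", "harvest"), ("d13C", "isotope"),
    ]
    for pot, child in zip(design.pots, pot_seeds):
        rng = np.random.default_rng(child)
        legume_present = any(species_map[s].is_legume for s in pot.composition)
        for variable, instrument in sampling:
            if variable not in traits:
                continue
            for date in dates.get(instrument, ()):
                for sid in pot.composition:
                    sp = species_map[sid]
                    v = rng.normal(sp.trait_means[variable], sp.trait_sds[variable])
                    if variable in ("SLA", "LDMC", "N"):
                        v = max(v, 0.0)
                    elif variable == "top_layer_share":
                        v = float(np.clip(v, 0.0, 100.0))
                    emit(pot.pot_id, sid, date, variable, v)

        if "height_growth" in traits:
            hdates = dates.get("height", ())
            heights = {sid: 5.0 for sid in pot.composition}
            prev_day = None
            for date in hdates:
                d = day_number(date)
                if prev_day is not None:
                    dt = d - prev_day
                    if any(prev_day < c <= d for c in cut_days):
                        heights = {sid: 5.0 for sid in pot.composition}
                        dt = min(dt, 7)  # regrowth since the cut
                    for sid in pot.composition:
                        sp = species_map[sid]
                        rate = rng.normal(sp.trait_means["height_growth"],
                                          sp.trait_sds["height_growth"])
                        heights[sid] += max(rate, 0.0) * dt
                for sid in pot.composition:
                    emit(pot.pot_id, sid, date, "height", heights[sid])
                prev_day = d

        if "root_growth" in traits:
            rdates = dates.get("root", ())
            weights = np.asarray(pot.proportions)
            mean_rate = float(sum(
                w * species_map[sid].trait_means["root_growth"]
                for sid, w in zip(pot.composition, weights)
            ))
            sd_rate = float(sum(
                w * species_map[sid].trait_sds["root_growth"]
                for sid, w in zip(pot.composition, weights)
            ))
            ramp = ix.facilitation_ramp
            length = 0.0
            prev_day = None
            for date in rdates:
                d = day_number(date)
                if prev_day is not None:
                    pi = next((i for i, p in enumerate(design.periods) if p.contains(date)), None)
                    boost = 1.0 + (ramp[pi] if legume_present and pi is not None
                                   and pi < len(ramp) else 0.0)
                    rate = max(rng.normal(mean_rate * boost, sd_rate), 0.0)
                    length += rate * (d - prev_day)
                emit(pot.pot_id, "", date, "root_length", length)
                prev_day = d

    return pd.DataFrame(rows)


def planted_response(
    X: np.ndarray,
    active: tuple[int, ...],
    coefs: tuple[float, ...],
    target_r2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Build a response from a planted predictor subset at a target R^2.

    The signal is ``X[:, active] @ coefs``; Gaussian noise is scaled so the
    population R^2 equals ``target_r2``.  Returns the response and a truth
    record (active indices, coefficients, noise SD).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target_r2 must be in (0, 1)")
    signal = X[:, list(active)] @ np.asarray(coefs, dtype=float)
    sig_var = float(np.var(signal))
    noise_sd = np.sqrt(sig_var * (1 - target_r2) / target_r2)
    y = signal + rng.normal(0.0, noise_sd, size=X.shape[0])
    return y, {"active": tuple(active), "coefs": tuple(coefs), "noise_sd": noise_sd,
               "target_r2": target_r2}


def generate_dataset(
    ix: InteractionSpec | None = None,
    pool: list[SpeciesSpec] | None = None,
    design: DesignSpec | None = None,
    n_reps_mono: int = 4,
    n_reps_mix: int = 3,
) -> GeneratedDataset:
    """Generate a complete seeded dataset with the default 53-pot design."""
    if ix is None:
        ix = InteractionSpec()
    if pool is None:
        pool = default_species_pool()
    if design is None:
        design = build_design(n_reps_mono, n_reps_mix, pool)
    biomass, ground_truth = simulate_biomass(design, pool, ix)
    weights, moisture = simulate_water(design, pool, ix, biomass=biomass)
    traits = simulate_traits(design, pool, ix)
    return GeneratedDataset(
        design=design, pool=pool, interaction=ix,
        biomass=biomass, traits=traits, weights=weights, moisture=moisture,
        ground_truth=ground_truth,
    )
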