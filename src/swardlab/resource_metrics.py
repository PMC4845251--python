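"""Derived resource-use variables: water, nitrogen and light metrics.

Converts raw tables (daily pot weights and watering additions, gravimetric
soil moisture, biomass splits, trait measurements) into per-pot per-period
community variables:

* daily evapotranspiration (ET, kg) from the pot weight balance;
* relative extractable water (REW), soil moisture rescaled between a drought
  minimum and a well-watered maximum;
* water-use efficiency (WUE, g biomass per kg water);
* nitrogen yield (gN pot^-1) and its ratio to ET;
* community leaf area (m^2 pot^-1) from biomass and specific leaf area;
* maximum height and deep-root growth rates per period;
* the top-canopy-layer biomass percentage.

Internal units are fixed: biomass g, water kg, SLA m^2 kg^-1; conversions
(g -> kg for leaf area, % -> fraction for N) happen inside the functions and
are noted in their docstrings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, day_number

__all__ = [
    "REW_SM_MIN",
    "REW_SM_MAX",
    "EtSeries",
    "daily_et_from_weights",
    "compute_rew",
    "compute_wue",
    "compute_nyield",
    "nyield_per_et",
    "community_leaf_area",
    "growth_rate_series",
    "max_rate_per_period",
    "top_layer_fraction",
    "species_period_table",
    "build_period_metrics",
]

#: Default gravimetric-moisture bounds of the REW rescaling: the drought
#: minimum (from a companion drydown on the same soil) and the well-watered
#: maximum.
REW_SM_MIN = 0.054
REW_SM_MAX = 0.379


@dataclass
class EtSeries:
    """Daily evapotranspiration of one pot, with its clipping diagnostics."""

    pot_id: str
    days: np.ndarray          # absolute day numbers
    et: np.ndarray            # kg, after clipping negatives to 0
    et_raw: np.ndarray        # kg, before clipping
    additions: np.ndarray     # kg added on each day
    n_clipped: int = 0

    def period_sum(self, start_day: int, end_day: int) -> float:
        mask = (self.days >= start_day) & (self.days <= end_day)
        return float(self.et[mask].sum())


def daily_et_from_weights(
    weights: pd.DataFrame,
    pot_id: str | None = None,
) -> EtSeries:
    """Daily ET from the pot weight balance.

    ``ET_t = (W_{t-1} - W_t) + additions_t``: the weight drop corrected for
    water added by rain or irrigation that day.  Negative corrected values
    (condensation, scale error) are clipped to 0 and counted in
    ``n_clipped``; the raw series is kept for mass-balance checks.

    Parameters
    ----------
    weights
        Columns ``year, doy, weight_kg, addition_kg`` (one row per day,
        strictly increasing dates); an optional ``pot_id`` column must be
        single-valued.
    """
    df = weights
    if "pot_id" in df.columns:
        pots = df["pot_id"].unique()
        if pot_id is None:
            if len(pots) != 1:
                raise ValueError("weights table holds several pots; pass pot_id")
            pot_id = pots[0]
        df = df[df["pot_id"] == pot_id]
    if len(df) < 2:
        raise ValueError("need at least two weight records to compute daily ET")
    days = np.array([day_number((y, d)) for y, d in zip(df["year"], df["doy"])])
    if np.any(np.diff(days) <= 0):
        raise ValueError("weight dates must be strictly increasing")
    w = df["weight_kg"].to_numpy(dtype=float)
    add = df["addition_kg"].to_numpy(dtype=float)
    et_raw = (w[:-1] - w[1:]) + add[1:]
    n_clipped = int(np.sum(et_raw < 0))
    if n_clipped:
        warnings.warn(f"{pot_id}: {n_clipped} negative daily ET values clipped to 0",
                      stacklevel=2)
    et = np.clip(et_raw, 0.0, None)
    return EtSeries(pot_id=str(pot_id), days=days[1:], et=et, et_raw=et_raw,
                    additions=add[1:], n_clipped=n_clipped)


def compute_rew(
    moisture: np.ndarray | pd.Series,
    sm_min: float = REW_SM_MIN,
    sm_max: float = REW_SM_MAX,
) -> np.ndarray:
    """Relative extractable water: ``(SM_t - SM_min) / (SM_max - SM_min)``.

    Values are clipped into [0, 1] with a warning — the bounds come from
    companion measurements, so observed moisture may lie slightly outside
    them.
    """
    if sm_max <= sm_min:
        raise ValueError(f"sm_max ({sm_max}) must exceed sm_min ({sm_min})")
    sm = np.asarray(moisture, dtype=float)
    rew = (sm - sm_min) / (sm_max - sm_min)
    n_out = int(np.sum((rew < 0) | (rew > 1)))
    if n_out:
        warnings.warn(f"{n_out} REW values outside [0, 1] clipped", stacklevel=2)
    return np.clip(rew, 0.0, 1.0)


def compute_wue(biomass_g: float, et_kg: float) -> float:
    """Water-use efficiency (g kg^-1): biomass over evapotranspiration."""
    if et_kg <= 0:
        raise ValueError(f"ET must be > 0 to compute WUE, got {et_kg}")
    return biomass_g / et_kg


def compute_nyield(n_pct: float, biomass_g: float) -> float:
    """Nitrogen yield (gN): N content (%) x biomass, with the %->fraction conversion."""
    if n_pct < 0 or biomass_g < 0:
        raise ValueError("N content and biomass must be >= 0")
    return (n_pct / 100.0) * biomass_g


def nyield_per_et(nyield_g: float, et_kg: float) -> float:
    """Shoot N produced per kg of water transpired (gN kg^-1)."""
    if nyield_g < 0:
        raise ValueError("Nyield must be >= 0")
    if et_kg <= 0:
        raise ValueError(f"ET must be > 0, got {et_kg}")
    return nyield_g / et_kg


def community_leaf_area(
    biomass_by_species: dict[str, float],
    sla_by_species: dict[str, float],
) -> float:
    """Community leaf area (m^2 pot^-1): sum of biomass (g -> kg) x SLA."""
    if set(biomass_by_species) != set(sla_by_species):
        raise ValueError(
            f"species mismatch: biomass {sorted(biomass_by_species)} "
            f"vs SLA {sorted(sla_by_species)}"
        )
    return sum(
        (b / 1000.0) * sla_by_species[s] for s, b in biomass_by_species.items()
    )


def growth_rate_series(
    measurements: list[tuple[tuple[int, int], float]],
    floor_decrements: bool = False,
) -> list[tuple[int, int, float]]:
    """Per-interval growth rates from an ordered measurement series.

    Each consecutive pair of measurements yields
    ``(start_day, end_day, rate = dvalue / ddays)``.  With
    ``floor_decrements=True`` (root length, a cumulative growth record)
    negative increments are floored at 0 before the rate is formed; height
    decrements are kept as negative rates.
    """
    if len(measurements) < 2:
        raise ValueError("need at least two measurements to form a growth rate")
    days = [day_number(date) for date, _ in measurements]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError("measurement dates must be strictly increasing")
    rates = []
    for (d0, (_, v0)), (d1, (_, v1)) in zip(
        zip(days, measurements), zip(days[1:], measurements[1:])
    ):
        dv = v1 - v0
        if floor_decrements:
            dv = max(dv, 0.0)
        rates.append((d0, d1, dv / (d1 - d0)))
    return rates


def max_rate_per_period(
    rates: list[tuple[int, int, float]],
    start_day: int,
    end_day: int,
) -> float:
    """Maximum rate over intervals assigned to a period by their end day.

    Returns NaN when no interval ends inside the period (a missing value,
    not an error).
    """
    in_period = [r for _, d1, r in rates if start_day <= d1 <= end_day]
    return max(in_period) if in_period else float("nan")


def top_layer_fraction(biomass_top_g: float, biomass_total_g: float) -> float:
    """Percentage of biomass in the top canopy layer; NaN if the total is 0."""
    if biomass_top_g < 0 or biomass_total_g < 0:
        raise ValueError("biomass must be >= 0")
    if biomass_total_g == 0:
        warnings.warn("zero total biomass: top-layer fraction undefined", stacklevel=2)
        return float("nan")
    if biomass_top_g > biomass_total_g:
        raise ValueError("top-layer biomass exceeds total biomass")
    return 100.0 * biomass_top_g / biomass_total_g


# ---------------------------------------------------------------------------
# table assembly


def _nearest_date_value(
    df: pd.DataFrame, target_day: int
) -> float:
    """Value whose measurement date is nearest to target_day (ties: earlier)."""
    days = np.array([day_number((y, d)) for y, d in zip(df["year"], df["doy"])])
    return float(df["value"].to_numpy()[np.argmin(np.abs(days - target_day))])


def species_period_table(
    design: DesignSpec,
    biomass: pd.DataFrame,
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Species-level values per pot x period, the base for community metrics.

    Columns: biomass splits, the leaf traits assigned to each period (N from
    that period's harvest; SLA/LDMC/top-layer share and d13C from the nearest
    sampling date), species leaf area, species top-layer percentage, and the
    per-period maximum height growth rate.
    """
    leaf_traits = traits[traits["species"] != ""]
    out_rows: list[dict] = []
    for pot in design.pots:
        pot_tr = leaf_traits[leaf_traits["pot_id"] == pot.pot_id]
        pot_bm = biomass[biomass["pot_id"] == pot.pot_id]
        for sid in pot.composition:
            sp_tr = pot_tr[pot_tr["species"] == sid]
            heights = sp_tr[sp_tr["variable"] == "height"].sort_values(["year", "doy"])
            h_rates = None
            if len(heights) >= 2:
                h_rates = growth_rate_series(
                    [((int(r.year), int(r.doy)), r.value) for r in heights.itertuples()]
                )
            for period in design.periods:
                brow = pot_bm[(pot_bm["period"] == period.label)
                              & (pot_bm["species"] == sid)]
                if brow.empty:
                    raise ValueError(
                        f"missing biomass row for pot {pot.pot_id}, species {sid}, "
                        f"period {period.label}"
                    )
                b = float(brow["biomass"].iloc[0])
                rec = {
                    "pot_id": pot.pot_id, "period": period.label, "species": sid,
                    "biomass": b,
                    "green_leaf_biomass": float(brow["green_leaf_biomass"].iloc[0]),
                    "top_layer_biomass": float(brow["top_layer_biomass"].iloc[0]),
                }
                mid_day = period.end_day
                for var in ("SLA", "LDMC", "N", "d13C", "top_layer_share"):
                    vdf = sp_tr[sp_tr["variable"] == var]
                    rec[var] = _nearest_date_value(vdf, mid_day) if len(vdf) else float("nan")
                rec["leaf_area"] = (b / 1000.0) * rec["SLA"]
                rec["height_growth"] = (
                    max_rate_per_period(h_rates, period.start_day, period.end_day)
                    if h_rates else float("nan")
                )
                out_rows.append(rec)
    return pd.DataFrame(out_rows)


def build_period_metrics(
    design: DesignSpec,
    biomass: pd.DataFrame,
    traits: pd.DataFrame,
    weights: pd.DataFrame,
    moisture: pd.DataFrame,
    sm_min: float = REW_SM_MIN,
    sm_max: float = REW_SM_MAX,
    species_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-pot per-period community metrics table.

    One row per pot x period with: total biomass, ET, WUE, community leaf
    area, green-leaf-weighted N, Nyield, Nyield/ET, mean REW, maximum height
    growth (biomass-weighted over species), maximum deep-root growth, and
    top-layer biomass percentage.
    """
    if species_table is None:
        species_table = species_period_table(design, biomass, traits)
    root_tr = traits[(traits["species"] == "") & (traits["variable"] == "root_length")]

    rows: list[dict] = []
    for pot in design.pots:
        et_series = daily_et_from_weights(weights, pot_id=pot.pot_id)
        pot_mo = moisture[moisture["pot_id"] == pot.pot_id]
        mo_days = np.array([day_number((y, d))
                            for y, d in zip(pot_mo["year"], pot_mo["doy"])])
        rew = compute_rew(pot_mo["moisture"].to_numpy(), sm_min, sm_max)
        pot_roots = root_tr[root_tr["pot_id"] == pot.pot_id].sort_values(["year", "doy"])
        r_rates = None
        if len(pot_roots) >= 2:
            r_rates = growth_rate_series(
                [((int(r.year), int(r.doy)), r.value) for r in pot_roots.itertuples()],
                floor_decrements=True,
            )
        sp = species_table[species_table["pot_id"] == pot.pot_id]
        for period in design.periods:
            psp = sp[sp["period"] == period.label]
            b_total = float(psp["biomass"].sum())
            et = et_series.period_sum(period.start_day, period.end_day)
            la = community_leaf_area(
                dict(zip(psp["species"], psp["biomass"])),
                dict(zip(psp["species"], psp["SLA"])),
            )
            glb = psp["green_leaf_biomass"].to_numpy()
            n_pct = (
                float(np.average(psp["N"], weights=glb)) if glb.sum() > 0
                else float("nan")
            )
            nyield = compute_nyield(n_pct, b_total) if not np.isnan(n_pct) else float("nan")
            bw = psp["biomass"].to_numpy()
            hg = psp["height_growth"].to_numpy()
            ok = ~np.isnan(hg)
            h_growth = (
                float(np.average(hg[ok], weights=bw[ok])) if ok.any() and bw[ok].sum() > 0
                else float("nan")
            )
            mask = (mo_days >= period.start_day) & (mo_days <= period.end_day)
            rows.append({
                "pot_id": pot.pot_id, "sward_type": pot.sward_type,
                "period": period.label,
                "biomass": b_total,
                "et": et,
                "wue": compute_wue(b_total, et) if et > 0 else float("nan"),
                "leaf_area": la,
                "n_pct": n_pct,
                "nyield": nyield,
                "nyield_per_et": (nyield_per_et(nyield, et)
                                  if et > 0 and not np.isnan(nyield) else float("nan")),
                "rew": float(rew[mask].mean()) if mask.any() else float("nan"),
                "height_growth": h_growth,
                "root_growth": (max_rate_per_period(r_rates, period.start_day,
                                                    period.end_day)
                                if r_rates else float("nan")),
                "biom_st1": top_layer_fraction(float(psp["top_layer_biomass"].sum()),
                                               b_total)
                            if b_total > 0 else float("nan"),
            })
    return pd.DataFrame(rows)
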