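"""Net diversity effect, additive partition and proportional deviations.

Over-yielding in mixtures is quantified against a null expectation built from
monocultures: the expected biomass of species *i* in a mixture is
``E_i = M_i * p_i`` with ``M_i`` the mean monoculture biomass and ``p_i`` its
proportion (sown proportions by default).  The net diversity effect
``net = sum_i (O_i - E_i)`` is partitioned additively into

* complementarity effect  ``CE = N * mean(dRY) * mean(M)`` and
* selection effect        ``SE = N * cov(dRY, M)``

where ``dRY_i = O_i / M_i - p_i`` is the deviation of species *i*'s observed
relative yield from its expected proportion and ``cov`` is the population
covariance (divisor ``N``), which makes ``net = CE + SE`` an algebraic
identity.  A positive CE means species yield on average more than expected
relative to their monocultures (niche complementarity and/or facilitation); a
positive SE means high-yielding species dominate the relative-yield surplus.

Proportional deviations ``D_i = (O_i - E_i) / E_i`` express, per species or
per functional group (grasses pooled vs. the legume), the sign and relative
magnitude of the interaction outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec, SpeciesSpec

__all__ = [
    "PartitionResult",
    "expected_biomass",
    "additive_partition",
    "proportional_deviation",
    "group_deviation",
    "partition_per_period",
]


@dataclass(frozen=True)
class PartitionResult:
    """Additive partition of the net diversity effect for one community."""

    species: tuple[str, ...]
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    delta_ry: tuple[float, ...]
    net_effect: float
    complementarity: float
    selection: float
    proportion_convention: str = "sown"

    @property
    def n_species(self) -> int:
        return len(self.species)


def expected_biomass(mono_mean: float, proportion: float) -> float:
    """Expected mixture biomass of one species: monoculture mean x proportion."""
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must be in [0, 1], got {proportion}")
    if np.isnan(mono_mean):
        raise ValueError("monoculture reference is missing (NaN)")
    return mono_mean * proportion


def additive_partition(
    observed,
    mono_means,
    proportions,
    species: tuple[str, ...] | None = None,
    proportion_convention: str = "sown",
) -> PartitionResult:
    """Partition the net diversity effect into complementarity and selection.

    Parameters
    ----------
    observed
        Observed per-species biomass in the mixture (g pot^-1); zeros are
        valid (a species that failed in mixture).
    mono_means
        Per-species mean monoculture biomass (g pot^-1); must be > 0.
    proportions
        Per-species expected proportions, summing to 1.

    Returns
    -------
    PartitionResult
        With ``net_effect == complementarity + selection`` exactly (up to
        floating point).
    """
    obs = np.asarray(observed, dtype=float)
    mono = np.asarray(mono_means, dtype=float)
    prop = np.asarray(proportions, dtype=float)
    n = obs.size
    if n < 2:
        raise ValueError("partition requires at least two species")
    if mono.size != n or prop.size != n:
        raise ValueError("observed, mono_means and proportions must align")
    if np.any(mono <= 0) or np.any(np.isnan(mono)):
        bad = np.flatnonzero(~(mono > 0))
        names = [species[i] if species else str(i) for i in bad]
        raise ValueError(f"monoculture means must be > 0 (relative yield undefined) for {names}")
    if abs(prop.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1, got {prop.sum()}")

    expected = mono * prop
    delta_ry = obs / mono - prop
    net = float(np.sum(obs - expected))
    complementarity = float(n * delta_ry.mean() * mono.mean())
    # population covariance (divisor N): required for net = CE + SE exactly
    selection = float(np.sum((delta_ry - delta_ry.mean()) * (mono - mono.mean())))
    return PartitionResult(
        species=tuple(species) if species is not None else tuple(str(i) for i in range(n)),
        observed=tuple(obs),
        expected=tuple(expected),
        delta_ry=tuple(delta_ry),
        net_effect=net,
        complementarity=complementarity,
        selection=selection,
        proportion_convention=proportion_convention,
    )


def proportional_deviation(observed: float, expected: float) -> float:
    """``D = (observed - expected) / expected``; NaN (with warning) if expected <= 0."""
    if expected <= 0:
        warnings.warn("expected biomass <= 0: proportional deviation undefined", stacklevel=2)
        return float("nan")
    return (observed - expected) / expected


def group_deviation(
    observed: dict[str, float],
    expected: dict[str, float],
    group: tuple[str, ...],
) -> float:
    """Pooled proportional deviation of a species group.

    ``D_group = (sum_group O - sum_group E) / sum_group E``.  For a singleton
    group this reduces to :func:`proportional_deviation`.
    """
    if not group:
        raise ValueError("group is empty")
    missing = [s for s in group if s not in observed or s not in expected]
    if missing:
        raise KeyError(f"species missing from tables: {missing}")
    o = sum(observed[s] for s in group)
    e = sum(expected[s] for s in group)
    return proportional_deviation(o, e)


def _monoculture_reference(biomass: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Mean monoculture biomass per species x period over replicate pots."""
    mono_ids = {p.pot_id for p in design.pots if p.richness == 1}
    mono = biomass[biomass["pot_id"].isin(mono_ids)]
    ref = (
        mono.groupby(["species", "period"], as_index=False)["biomass"]
        .mean()
        .rename(columns={"biomass": "mono_mean"})
    )
    return ref


def partition_per_period(
    biomass: pd.DataFrame,
    design: DesignSpec,
    pool: list[SpeciesSpec],
    proportion_convention: str = "sown",
    level: str = "composition",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition diversity effects for every mixture composition and period.

    Parameters
    ----------
    biomass
        Long table with columns ``pot_id, period, species, biomass``.
    design
        Provides compositions, sown proportions and sward types.
    pool
        Species specifications (to split grasses from the legume).
    proportion_convention
        ``"sown"`` (default) uses the sown proportions; ``"observed"`` uses
        each species' realized share of mixture biomass.
    level
        ``"composition"`` (default) averages observed biomass over replicate
        pots of a composition before partitioning; ``"pot"`` partitions each
        pot separately.

    Returns
    -------
    (effects, deviations)
        ``effects`` has one row per (unit, period) with net effect,
        complementarity and selection plus sward-type aggregate rows
        (``unit_type == "sward"``); ``deviations`` holds per-species and
        per-group proportional deviations.
    """
    if proportion_convention not in ("sown", "observed"):
        raise ValueError(f"unknown proportion convention {proportion_convention!r}")
    if level not in ("composition", "pot"):
        raise ValueError(f"unknown aggregation level {level!r}")

    legume_ids = {s.species_id for s in pool if s.is_legume}
    ref = _monoculture_reference(biomass, design)
    ref_map = {(r.species, r.period): r.mono_mean for r in ref.itertuples()}

    period_labels = [p.label for p in design.periods]
    mix_comps = design.compositions(min_richness=2)

    eff_rows: list[dict] = []
    dev_rows: list[dict] = []
    for comp in mix_comps:
        pots = design.pots_for_composition(comp)
        sward = pots[0].sward_type
        sown = dict(zip(pots[0].composition, pots[0].proportions))
        comp_id = "-".join(comp)
        sub = biomass[biomass["pot_id"].isin({p.pot_id for p in pots})]
        if level == "composition":
            units = [(comp_id, sub)]
        else:
            units = [(pid, g) for pid, g in sub.groupby("pot_id")]
        for unit_id, unit_df in units:
            for period in period_labels:
                pdf = unit_df[unit_df["period"] == period]
                obs_by_species = pdf.groupby("species")["biomass"].mean()
                obs = np.array([obs_by_species.get(s, 0.0) for s in comp])
                mono = []
                for s in comp:
                    m = ref_map.get((s, period))
                    if m is None:
                        raise ValueError(
                            f"species {s!r} has no monoculture reference for period {period!r}"
                        )
                    mono.append(m)
                mono = np.array(mono)
                if proportion_convention == "sown":
                    prop = np.array([sown[s] for s in comp])
                else:
                    total = obs.sum()
                    if total <= 0:
                        raise ValueError(
                            f"observed-proportion convention undefined for {unit_id} "
                            f"period {period}: zero total biomass"
                        )
                    prop = obs / total
                res = additive_partition(
                    obs, mono, prop, species=comp,
                    proportion_convention=proportion_convention,
                )
                eff_rows.append({
                    "unit_type": level, "unit": unit_id, "composition": comp_id,
                    "sward_type": sward, "period": period,
                    "n_species": res.n_species,
                    "net_effect": res.net_effect,
                    "complementarity": res.complementarity,
                    "selection": res.selection,
                    "proportion_convention": proportion_convention,
                })
                obs_map = dict(zip(comp, res.observed))
                exp_map = dict(zip(comp, res.expected))
                for s in comp:
                    dev_rows.append({
                        "unit": unit_id, "composition": comp_id, "sward_type": sward,
                        "period": period, "group": s, "group_type": "species",
                        "D": proportional_deviation(obs_map[s], exp_map[s]),
                    })
                grasses = tuple(s for s in comp if s not in legume_ids)
                legs = tuple(s for s in comp if s in legume_ids)
                if grasses:
                    dev_rows.append({
                        "unit": unit_id, "composition": comp_id, "sward_type": sward,
                        "period": period, "group": "grass", "group_type": "group",
                        "D": group_deviation(obs_map, exp_map, grasses),
                    })
                if legs:
                    dev_rows.append({
                        "unit": unit_id, "composition": comp_id, "sward_type": sward,
                        "period": period, "group": "legume", "group_type": "group",
                        "D": group_deviation(obs_map, exp_map, legs),
                    })

    effects = pd.DataFrame(eff_rows)
    deviations = pd.DataFrame(dev_rows)

    # sward-type aggregates (means over compositions/pots within a sward type)
    agg = (
        effects.groupby(["sward_type", "period"], as_index=False)[
            ["net_effect", "complementarity", "selection"]
        ]
        .mean()
    )
    agg.insert(0, "unit_type", "sward")
    agg.insert(1, "unit", agg["sward_type"])
    agg.insert(2, "composition", agg["sward_type"])
    agg["n_species"] = np.nan
    agg["proportion_convention"] = proportion_convention
    effects = pd.concat([effects, agg[effects.columns]], ignore_index=True)
    return effects, deviations
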