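"""Community-weighted mean traits and Rao's quadratic entropy.

A community-weighted mean (CWM) aggregates species trait values with
abundance weights, ``CWM = sum_i p_i t_i``.  Which abundance is the right
weight depends on the trait: leaf dry matter content is weighted by each
species' share of total biomass, nitrogen content by its share of green-leaf
biomass (N is measured on green leaves), and carbon isotopic composition by
its share of community leaf area (d13C integrates over transpiring area).
Variables measured directly at the community level (leaf area, WUE,
Nyield/ET, REW, deep-root growth, the community top-layer percentage) pass
through unweighted.

Functional diversity is Rao's quadratic entropy,
``FD_Q = sum_i sum_j p_i p_j d_ij``, the expected trait dissimilarity of two
randomly drawn individuals.  The default dissimilarity is Gower distance on
range-standardized traits (d in [0, 1]); squared Euclidean distance on
z-scores divided by twice the trait count is available as an alternative.
The convention used is recorded in every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignSpec

__all__ = [
    "WEIGHTING_RULES",
    "FD_TRAITS",
    "CwmResult",
    "FdqResult",
    "resolve_weighting",
    "cwm",
    "fd_rao",
    "build_cwm_table",
    "build_fdq_table",
]

#: Registered abundance weighting per trait.  ``total_biomass`` weights that
#: lack an explicitly stated rule are marked as defaults in the results.
WEIGHTING_RULES: dict[str, tuple[str, bool]] = {
    # trait -> (rule, is_default_assumption)
    "LDMC": ("total_biomass", False),
    "N": ("green_leaf_biomass", False),
    "d13C": ("leaf_area", False),
    "H.growth": ("total_biomass", True),
    "Biom st1": ("total_biomass", True),
    # community-level variables pass through unweighted
    "L.area": ("community", False),
    "WUE": ("community", False),
    "Nyield/ET": ("community", False),
    "REW": ("community", False),
    "R.growth": ("community", False),
}

#: The six species-level traits entering the functional-diversity index.
FD_TRAITS = ("Biom st1", "d13C", "H.growth", "L.area", "LDMC", "N")


@dataclass(frozen=True)
class CwmResult:
    community: str
    trait: str
    weighting: str
    value: float
    weighting_is_default: bool = False


@dataclass(frozen=True)
class FdqResult:
    community: str
    traits: tuple[str, ...]
    value: float
    distance: str
    dropped_traits: tuple[str, ...] = ()


def resolve_weighting(trait_name: str) -> str:
    """Abundance rule for a trait: a weighting name or ``"community"``."""
    if trait_name not in WEIGHTING_RULES:
        raise KeyError(
            f"unknown trait {trait_name!r}; registered: {sorted(WEIGHTING_RULES)}"
        )
    return WEIGHTING_RULES[trait_name][0]


def _check_weights(weights: dict[str, float]) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"abundance weights must sum to 1, got {total!r}")
    if any(w < 0 for w in weights.values()):
        raise ValueError("abundance weights must be >= 0")


def cwm(
    weights: dict[str, float],
    trait_values: dict[str, float],
    trait: str = "",
    community: str = "",
    weighting: str = "total_biomass",
) -> CwmResult:
    """Community-weighted mean ``sum_i p_i t_i`` of one trait.

    Raises if the weights do not sum to 1 or a species with positive weight
    has no trait value.
    """
    _check_weights(weights)
    missing = [s for s, w in weights.items() if w > 0 and s not in trait_values]
    if missing:
        raise KeyError(f"trait {trait!r} missing for weighted species {missing}")
    value = sum(w * trait_values[s] for s, w in weights.items() if w > 0)
    is_default = WEIGHTING_RULES.get(trait, ("", False))[1]
    return CwmResult(community=community, trait=trait, weighting=weighting,
                     value=float(value), weighting_is_default=is_default)


def _gower_matrix(T: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Pairwise Gower dissimilarity on range-standardized trait columns.

    Constant columns carry no dissimilarity information and are dropped
    (their indices are returned).  Distances lie in [0, 1].
    """
    S, k = T.shape
    ranges = T.max(axis=0) - T.min(axis=0)
    dropped = [j for j in range(k) if ranges[j] == 0]
    keep = [j for j in range(k) if ranges[j] > 0]
    if not keep:
        return np.zeros((S, S)), dropped
    Z = T[:, keep] / ranges[keep]
    D = np.abs(Z[:, None, :] - Z[None, :, :]).mean(axis=2)
    return D, dropped


def _euclidean_matrix(T: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Squared Euclidean distance on z-scored traits, scaled into [0, ~1]."""
    S, k = T.shape
    sds = T.std(axis=0, ddof=0)
    dropped = [j for j in range(k) if sds[j] == 0]
    keep = [j for j in range(k) if sds[j] > 0]
    if not keep:
        return np.zeros((S, S)), dropped
    Z = (T[:, keep] - T[:, keep].mean(axis=0)) / sds[keep]
    diff = Z[:, None, :] - Z[None, :, :]
    D = (diff**2).sum(axis=2) / (2.0 * len(keep) * max(S - 1, 1))
    return D, dropped


def fd_rao(
    weights: dict[str, float],
    trait_matrix: pd.DataFrame,
    distance: str = "gower",
    community: str = "",
) -> FdqResult:
    """Rao's quadratic entropy of a community.

    Parameters
    ----------
    weights
        Abundance fractions per species, summing to 1.
    trait_matrix
        Species (rows, indexed by id) x traits (columns); only species with
        positive weight need rows.
    distance
        ``"gower"`` (range-standardized, default) or ``"sq_euclidean"``
        (z-scored).  All-constant trait columns are dropped with a warning.
    """
    _check_weights(weights)
    species = [s for s, w in weights.items() if w > 0]
    missing = [s for s in species if s not in trait_matrix.index]
    if missing:
        raise KeyError(f"trait rows missing for species {missing}")
    if len(species) == 1:
        return FdqResult(community=community, traits=tuple(trait_matrix.columns),
                         value=0.0, distance=distance)
    T = trait_matrix.loc[species].to_numpy(dtype=float)
    if np.isnan(T).any():
        raise ValueError("trait matrix contains missing values")
    if distance == "gower":
        D, dropped_idx = _gower_matrix(T)
    elif distance == "sq_euclidean":
        D, dropped_idx = _euclidean_matrix(T)
    else:
        raise ValueError(f"unknown distance convention {distance!r}")
    dropped = tuple(trait_matrix.columns[j] for j in dropped_idx)
    if dropped:
        warnings.warn(f"constant trait column(s) dropped from FD_Q: {dropped}",
                      stacklevel=2)
    p = np.array([weights[s] for s in species])
    q = float(p @ D @ p)
    return FdqResult(community=community, traits=tuple(trait_matrix.columns),
                     value=q, distance=distance, dropped_traits=dropped)


# ---------------------------------------------------------------------------
# table assembly


def _abundance(sub: pd.DataFrame, rule: str) -> dict[str, float]:
    col = {"total_biomass": "biomass", "green_leaf_biomass": "green_leaf_biomass",
           "leaf_area": "leaf_area"}[rule]
    v = sub[col].to_numpy(dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError(f"cannot form {rule} abundance weights: zero total")
    return dict(zip(sub["species"], v / total))


_SPECIES_COLUMN = {
    "LDMC": "LDMC", "N": "N", "d13C": "d13C",
    "H.growth": "height_growth",
}
_COMMUNITY_COLUMN = {
    "L.area": "leaf_area", "WUE": "wue", "Nyield/ET": "nyield_per_et",
    "REW": "rew", "R.growth": "root_growth", "Biom st1": "biom_st1",
}


def build_cwm_table(
    design: DesignSpec,
    species_table: pd.DataFrame,
    period_metrics: pd.DataFrame,
) -> pd.DataFrame:
    """CWM values of the ten community variables per pot x period.

    Species-level traits (LDMC, N, d13C, H.growth) are weighted with their
    registered abundance rule from the biomass splits of ``species_table``;
    community-level variables are copied from ``period_metrics`` with
    weighting ``"community"``.
    """
    rows: list[dict] = []
    for (pot_id, period), sub in species_table.groupby(["pot_id", "period"], sort=False):
        for trait, col in _SPECIES_COLUMN.items():
            rule = resolve_weighting(trait)
            vals = dict(zip(sub["species"], sub[col]))
            if any(np.isnan(v) for v in vals.values()):
                value, is_default = float("nan"), WEIGHTING_RULES[trait][1]
            else:
                res = cwm(_abundance(sub, rule), vals, trait=trait,
                          community=pot_id, weighting=rule)
                value, is_default = res.value, res.weighting_is_default
            rows.append({"pot_id": pot_id, "period": period, "trait": trait,
                         "weighting": rule, "weighting_is_default": is_default,
                         "value": value})
    for r in period_metrics.itertuples():
        for trait, col in _COMMUNITY_COLUMN.items():
            rows.append({"pot_id": r.pot_id, "period": r.period, "trait": trait,
                         "weighting": "community", "weighting_is_default": False,
                         "value": getattr(r, col)})
    return pd.DataFrame(rows).sort_values(["pot_id", "period", "trait"],
                                          ignore_index=True)


def build_fdq_table(
    design: DesignSpec,
    species_table: pd.DataFrame,
    distance: str = "gower",
) -> pd.DataFrame:
    """FD_Q per pot x period on the six species-level traits."""
    trait_cols = {"Biom st1": None, "d13C": "d13C", "H.growth": "height_growth",
                  "L.area": "leaf_area", "LDMC": "LDMC", "N": "N"}
    rows: list[dict] = []
    n_dropped = 0
    for (pot_id, period), sub in species_table.groupby(["pot_id", "period"], sort=False):
        sub = sub.set_index("species")
        tm = pd.DataFrame(index=sub.index)
        for trait, col in trait_cols.items():
            if trait == "Biom st1":
                with np.errstate(invalid="ignore", divide="ignore"):
                    tm[trait] = 100.0 * sub["top_layer_biomass"] / sub["biomass"]
            else:
                tm[trait] = sub[col]
        weights = {s: b / sub["biomass"].sum() for s, b in sub["biomass"].items()}
        if tm.loc[[s for s, w in weights.items() if w > 0]].isna().any().any():
            value, dropped = float("nan"), ()
        else:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                res = fd_rao(weights, tm, distance=distance, community=pot_id)
            value, dropped = res.value, res.dropped_traits
            n_dropped += len(dropped)
        rows.append({"pot_id": pot_id, "period": period, "fdq": value,
                     "distance": distance, "n_traits_dropped": len(dropped)})
    out = pd.DataFrame(rows)
    out.attrs["n_traits_dropped_total"] = n_dropped
    return out
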