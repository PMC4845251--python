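# swardlab

Analysis tools for **grass–legume mesocosm diversity experiments**: pot
experiments in which grasses and a legume (typically white clover,
*Trifolium repens*) are grown in monocultures and mixtures to ask whether —
and through which resources — mixtures over-yield their monocultures.

The package is aimed at plant community ecologists running
biodiversity–ecosystem-function experiments. It covers the full analysis
chain:

- **Resource-use metrics** — daily evapotranspiration from pot weight
  balances, relative extractable water
  `REW_t = (SM_t − SM_min)/(SM_max − SM_min)`, water-use efficiency
  (biomass/ET), nitrogen yield and Nyield/ET, community leaf area, maximum
  height and deep-root growth rates per cutting period, top-canopy biomass
  share.
- **Community trait structure** — community-weighted means
  `CWM = Σ p_i t_i` with trait-specific abundance weights, and functional
  diversity as Rao's quadratic entropy `FD_Q = Σ_i Σ_j p_i p_j d_ij` (Gower
  distance by default).
- **Diversity-effect partition** — the additive partition of the net
  diversity effect, `net = CE + SE` with
  `CE = N·mean(ΔRY)·mean(M)` and `SE = N·cov(ΔRY, M)`, where
  `ΔRY_i = O_i/M_i − p_i`, plus proportional deviations `D = (O − E)/E` per
  species and per functional group (D_Grass, D_Leg).
- **Trait-based model selection** — exhaustive best-subset OLS of biomass,
  net effect and complementarity on ten community trait variables, scored
  by exact leave-one-out cross-validation, with relative importance of each
  predictor by LMG (equal ordering weights) and PMVD (proportional marginal
  variance decomposition).
- **A seeded synthetic-data generator** that emulates the canonical 53-pot
  design (5 monocultures × 4 replicates, 10 pairs × 3, one five-species
  mixture × 3; six cutting periods) with injected, exactly known diversity
  effects — used throughout the test suite for oracle and recovery checks.

See `docs/methods.md` for the full model description and conventions.

## Worked example

Partition one mixture against its monocultures — a clover–cocksfoot pair
whose monocultures average 134.8 and 74.1 g pot⁻¹ in the same period, sown
50:50, observed at 88 and 96 g pot⁻¹:

```python
from swardlab.diversity_effects import additive_partition

res = additive_partition(
    observed=[88.0, 96.0], mono_means=[134.8, 74.1],
    proportions=[0.5, 0.5], species=("tr", "dg"),
)
print(f"net = {res.net_effect:.1f} g, CE = {res.complementarity:.1f} g, "
      f"SE = {res.selection:.1f} g")
```

```
net = 79.5 g, CE = 99.1 g, SE = -19.5 g
```

The mixture produced 79.5 g more than expected from its monocultures.
Both species exceeded their expected relative yields (ΔRY = 0.15 and 0.80),
so complementarity is strongly positive (99.1 g); the surplus is
concentrated in the *lower*-yielding monoculture species, making the
selection effect negative (−19.5 g) — over-yielding here is not driven by a
dominant high-yielder.

The full pipeline runs from one seed:

```sh
swardlab run --seed 1 --out out/
```

which generates the 53-pot dataset, computes all metric/CWM/FD tables,
partitions diversity effects, and fits the trait models. The 2+ sward
aggregates (two-species mixtures with clover) from `diversity_effects.tsv`:

```
 period  net_effect  complementarity  selection
113-143        -4.1            -14.0       10.0
144-190       -37.0            -39.1        2.1
191-224        17.8             21.0       -3.2
225-280         9.3             20.5      -11.2
281-101        18.9             26.1       -7.3
102-161        30.2             34.8       -4.7
```

showing the generator's injected story: clover mixtures under-yield while
the legume establishes, then over-yield increasingly from late summer of
year 1 onward, driven by complementarity with a nil-to-negative selection
effect. `importance.tsv` summarizes the selected five-trait model per
response with each trait's percentage of the model R².

Other entry points: `swardlab generate` (raw tables only),
`swardlab analyze --data <dir>` (your own tables in the same TSV schema),
`swardlab validate --data <dir>` (schema checks, exit code 2 on issues).

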