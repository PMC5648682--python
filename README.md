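# raydisp

Local dispersal and fine-scale spatial genetic structure for nest-box
breeding bird populations.

Long-term nest-box studies produce three intertwined datasets: georeferenced
boxes, longitudinal capture-mark-recapture (CMR) records, and multilocus
microsatellite genotypes of the breeders.  Linking them answers a classic
question in avian population biology: *does sex-biased natal dispersal leave
a detectable genetic footprint at the scale of a few hundred metres, and
does that footprint differ between contrasting habitats?*  Answering it
requires a chain of analyses usually scattered across GIS, MARK-style
CMR software and population-genetics packages.  `raydisp` implements that
chain as one tested Python library:

* **Territories** - Dirichlet (Voronoi) tessellation of the boxes occupied
  each season, annual mean territory diameter with its 95% CI, and the
  derived dispersed/nondispersed threshold (moved >= upper CI limit).
  Distances convert to territory units, tU = d / mean diameter.
* **Dispersal statistics** - natal and breeding dispersal events from
  captures; Kolmogorov-Smirnov sex comparisons (Z = D*sqrt(nm/(n+m)));
  Monte Carlo null models for median distances (uniform assignment, and a
  random-walk model weighting boxes by exp(-lambda d) with lambda from the
  recapture-probability distance decay); hierarchical log-linear analysis
  (backward G2 elimination) of the status x sex x population table.
* **Demography** - Cormack-Jolly-Seber apparent survival phi and recapture
  probability p (m-array maximum likelihood; constant/time/sex structures;
  AICc), static life tables l_x, m_x, and the Euler-Lotka solution of the
  first-year survival that holds the population constant:
  s0 = 1 / sum_x (prod_{i<x} phi_i) m_x.
* **Genetic structure** - pairwise squared codominant genetic distances,
  the spatial autocorrelation coefficient r per distance class (Gower-
  centred covariance, pair-symmetric normalization), increasing-distance
  classes, bootstrap CIs and permutation envelopes with the conservative
  dual significance rule, t2/omega correlogram heterogeneity between
  groups, two-dimensional local autocorrelation lr over n nearest
  neighbours, and Mantel tests.
* **Synthetic data** - landscapes (continuous grids and fragmented
  patches), multi-year populations with sex-specific dispersal kernels and
  habitat saturation, and genotypes gene-dropped through the simulated
  pedigree, so the whole pipeline is testable end to end without any field
  data.

See `docs/methods.md` for the statistical conventions and the generator's
calibration.

## Worked example

Simulate the fragmented high-density study system (female natal kernel
740 m, male 100 m), model territories, extract dispersal events, and ask
whether philopatric males are genetically structured at short distances:

```python
from raydisp import synthetic as syn, territory as terr
from raydisp import dispersal as disp, genetics as gen
from raydisp.io import breeding_adult_coordinates

sim = syn.simulate_site("fray_jorge", seed=1)
models = terr.territory_models_by_year(sim["captures"], sim["boxes"])
m = models[4]
print(f"year 4: {len(m.tiles)} pairs, mean territory diameter "
      f"{m.mean_diameter_m:.1f} m, dispersal threshold {m.ci95_upper_m:.1f} m")

events = disp.extract_dispersal_events(sim["captures"], sim["boxes"], models)
natal = events[events["type"] == "natal"]
for sex in "FM":
    med = natal.loc[natal.sex == sex, "distance_m"].median()
    print(f"natal dispersal median ({sex}): {med:.0f} m")

coords = breeding_adult_coordinates(sim["captures"], sim["boxes"],
                                    years=range(3, 9))
g = gen.genotype_matrix_from_tables(sim["genotypes"], coords)
males = g.subset(g.sex == "M")
D = gen.squared_genetic_distance(males)
geo = gen.geographic_distances(males.coords)
for c in gen.multi_dclass(D, geo, [100, 150, 300, 450],
                          n_boot=999, n_perm=999, seed=1):
    print(f"  d <= {c.upper_m:>3.0f} m: r = {c.r:+.3f} "
          f"(CI {c.ci_lower:+.3f}..{c.ci_upper:+.3f}), "
          f"significant: {c.significant}")
```

Output:

```
year 4: 22 pairs, mean territory diameter 56.7 m, dispersal threshold 66.8 m
natal dispersal median (F): 518 m
natal dispersal median (M): 60 m
  d <= 100 m: r = +0.079 (CI +0.054..+0.103), significant: True
  d <= 150 m: r = +0.065 (CI +0.044..+0.088), significant: True
  d <= 300 m: r = +0.065 (CI +0.043..+0.086), significant: True
  d <= 450 m: r = +0.034 (CI +0.020..+0.050), significant: True
```

Females disperse an order of magnitude farther than males, and the
male-male autocorrelation r is significantly positive out to 450 m under
the dual rule (bootstrap CI excludes 0 and r exceeds the permutation
envelope) - restricted male dispersal has produced spatial clusters of
male kin.  Running the same analysis on the continuous low-density system
(`simulate_site("navarino", ...)`, unbiased 450 m kernels) yields no
significant class for either sex.

The same pipeline is scriptable from the shell:

```bash
raydisp simulate --site fray-jorge --seed 1 --out data/
raydisp territory --captures data/captures.csv --boxes data/boxes.csv --out terr.csv
raydisp genetics --genotypes data/genotypes.csv --captures data/captures.csv \
                 --boxes data/boxes.csv --classes 150,300,450 --out genetics.json
```

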