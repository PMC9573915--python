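# icarlap

Maximum-likelihood estimation of Besag intrinsic conditional autoregressive
(ICAR) Poisson models for small-area disease counts. The latent spatial
field is integrated out of the joint likelihood by a Laplace approximation;
the resulting marginal likelihood is maximized by quasi-Newton, giving MLEs,
standard errors from the inverse observed information, and plug-in latent
field estimates with conditional uncertainties.

Model, for region *i* with observed count *y*, expected count (offset) *E*,
optional covariates *x* and spatial effect *s*:

```
y_i ~ Poisson(E_i * lambda_i)
log lambda_i = beta0 + x_i' beta + s_i
p(s | tau) ∝ exp( - s' (D_w - W) s / (2 tau^2) )
```

`W` is the binary first-order contiguity matrix, `D_w` the neighbour-count
diagonal. `Q = D_w - W` is singular (rank `n - k` for `k` connected
components); identifiability comes from a per-component sum-to-zero
constraint, imposed by hard reparameterization onto an orthonormal basis of
the constrained subspace (default) or by a stiff quadratic penalty.

## Layout

| module | contents |
|---|---|
| `icarlap.graph` | contiguity graphs from polygons (queen/rook, shared-vertex matching) or edge lists / GAL files; `W`, `D_w`, `Q`, components |
| `icarlap.model` | data containers, joint negative log-likelihood, ICAR log-density with pseudo-determinant normalization, relative risks |
| `icarlap.laplace` | inner Newton mode, Laplace marginal nll, outer MLE with finite-difference gradients, SEs, plug-in latent field |
| `icarlap.simulate` | lattice graphs, exact constrained ICAR field draws (spectral), Poisson count simulation with ground truth |
| `icarlap.oracle` | brute-force marginal likelihood by tensor-product Gauss–Hermite quadrature with node doubling; pseudo-determinant |
| `icarlap.mcmc` | self-contained Metropolis-within-Gibbs sampler used to cross-check the MLEs |
| `icarlap.io` / `icarlap.cli` | case-study loaders, fit reports (JSON/CSV/text), `icarlap` command line |
| `icarlap._shp` | minimal ESRI shapefile reader/writer (polygons + DBF labels) |

## Command line

```bash
# simulate a 10x10 rook lattice and fit it back
icarlap simulate --rows 10 --cols 10 --tau-scale 0.5 --offset 50 --seed 1 --out sim/
icarlap fit --data sim/data.csv --edges sim/edges.txt --labels-from sim/labels.csv \
            --seed 1 --out fit/

# fit areal data with a polygon source (shapefile, GeoJSON, or CSV with a wkt column)
icarlap fit --data counts.csv --shapefile counties.shp --contiguity queen \
            --covariates x1,x2 --report-scale tau --out results/

# Laplace vs brute-force quadrature on the built-in tiny fixture set
icarlap validate --json-out oracle.json

# Laplace MLEs vs a Metropolis sampler on simulated data
icarlap crosscheck --rows 8 --cols 8 --iterations 4000 --seed 1
```

`fit` writes `fit.json` (estimates, SEs, marginal nll, max outer gradient,
convergence flag), `regions.csv` (per-region latent effect, conditional SD,
relative risk, fitted count) and a readable `fit.txt` table, plus an audit
of the derived adjacency (`edges.csv`, `degrees.csv`).

The spatial dispersion is reported as `tau` (the scale in `1/(2 tau^2)`)
by default; `--report-scale tau2` reports its square. SEs follow by the
delta method.

## Case studies

- **Pennsylvania lung cancer 2002** (67 counties): bundled as plain text
  (counts, indirectly standardized expected counts over 16 race×gender×age
  strata, county polygons as WKT), extracted from the SpatialEpi R package.
  Load with `icarlap.io.load_bundled_pennsylvania()`.
- **Mississippi West Nile virus 2002** (82 counties): requires the
  publication's supplementary files `ms_human_wv_data.R` and
  `mississippi_county.shp`. Place them in `data/mississippi/` (or point
  `ICARLAP_SUPPLEMENT_DIR` at them) and use
  `icarlap.io.load_case_study("mississippi", dir)`.
- **London suicides** (32 boroughs, two covariates): external; supply
  `data/london/london_suicides.csv` (`region_label,y,E,x1,x2`) plus a
  polygon file to enable the corresponding checks.

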