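# crossconn

Comparative analysis of mammalian cortical connectomes. The package relates
the existence of directed cortico-cortical connections to physical distance
and cytoarchitectonic similarity (per-species and pooled logistic models
with a species-by-cytoarchitecture interaction), predicts the laminar
origin of connections (NSG%, the percentage of supragranular labeled
neurons) from cytoarchitectonic versus rostrocaudal predictors with
repeated out-of-sample support vector regression, and maps the clique-based
structural network core together with its shortest-path and random-walk
communication efficiency. A synthetic-cortex generator with retained ground
truth backs every stage with parameter-recovery tests, so the whole
pipeline is testable without external tract-tracing data.

## Layout

| module                 | contents |
|------------------------|----------|
| `crossconn.connectome` | tri-state (present/absent/unknown) connectome data model, CSV I/O, pair-table construction, edge-complete restriction |
| `crossconn.synth`      | synthetic cortices: spatial layouts, cytoarchitectonic gradients, logistic wiring model, NSG% generation, planted cores |
| `crossconn.stats`      | energy test (log-potential), KS permutation test, Spearman / partial Spearman, ROC AUC, add-one permutation p-values |
| `crossconn.wiring`     | logistic IRLS fits, species-interaction model + LR test, present/absent comparisons, ordinal-type reassignment robustness |
| `crossconn.laminar`    | NSG% computation, SVR out-of-sample evaluation, permutation nulls, FF/FB classification, cross-species extrapolation |
| `crossconn.core`       | Bron-Kerbosch maximal cliques (pivoting + degeneracy order), core = union of largest cliques, degree-matched surrogate nulls |
| `crossconn.comm`       | shortest-path and mean-first-passage-time (diffusion) efficiency, core-vs-periphery comparisons |
| `crossconn.cli`        | `crossconn` command-line interface |

## CLI

```sh
# synthetic cortex from a YAML spec (fields of SyntheticSpec)
crossconn simulate --spec spec.yaml --seed 1 --out out/sim

# one- or two-species wiring analysis (two species adds the interaction + LR test)
crossconn wiring \
  --adjacency a_adj.csv --areas a_areas.csv --species alpha --distance a_dist.csv \
  --adjacency b_adj.csv --areas b_areas.csv --species beta  --distance b_dist.csv \
  --n-perm 1000 --seed 1 --out out/wiring

# laminar origin prediction and nulls
crossconn laminar --laminar-csv laminar.csv --areas areas.csv \
  --predictors cyto_diff --n-rep 1000 --seed 1 --out out/laminar

# cross-species NSG% extrapolation via a region/area correspondence table
crossconn laminar-extrapolate --laminar-csv laminar.csv --areas areas.csv \
  --correspondence regions.csv --out out/human

# core-periphery with degree-matched nulls, then efficiency comparisons
crossconn core --adjacency adj.csv --areas areas.csv --distance dist.csv \
  --edge-rule mutual --n-null 1000 --seed 1 --out out/core
crossconn efficiency --adjacency adj.csv --areas areas.csv --distance dist.csv \
  --partition-json out/core/core.json --out out/eff

# ordinal-type reassignment robustness
crossconn robustness --adjacency adj.csv --areas areas.csv --distance dist.csv \
  --fractions 0,0.2,0.4,0.6,0.8 --out out/robust

# end-to-end synthetic pipeline from a YAML run config
crossconn run-all --config run.yaml --seed 1 --out out/run
```

File formats: adjacency CSVs carry area ids as header row and first column
with cells `1`/`0`/`NA` (NA = unknown status, never coerced to absent);
area CSVs have columns `id,name,cyto,x,y,z` plus optional `rostrocaudal`
and `cyto_kind` (`type` for ordinal cortical types, `density` for neurons
per mm³); laminar CSVs have `origin,termination` and either `nsg`,
`n_supra`/`n_infra` counts, or a `label` column.

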