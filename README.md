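# crispr-di

Distributed immunity in CRISPR host–phage communities: metrics, stochastic
eco-evolutionary simulation, and estimation from sequencing data.

## The problem

When microbes with an active CRISPR-Cas system coevolve with lytic viruses,
many host genotypes can become immune to the *same* virus through
*different* spacers — many genotypes, one phenotype. This "distributed
immunity" changes the coevolutionary dynamic: a single viral escape
mutation can no longer unlock most of the host population. This package is
for modellers and microbial ecologists who want to quantify that structure,
simulate the dynamics that generate it, and estimate it from host spacer
arrays and phage SNP frequencies.

## The metrics

For a community with host strain proportions `N_i` (spacer sets `G_i`) and
viral strain proportions `V_k` (protospacer sets `H_k`):

* **PDI** (population-wide distributed immunity) scores all host–host–virus
  triplets:

  `PDI = Σ_{i≠j} Σ_k N_i N_j V_k σ(N_i,N_j) D(G_i,G_j,H_k)`

  where `D = 1` iff the two hosts match *different* protospacers of virus
  `k`, and `σ(N_i,N_j) = 1 − |N_i−N_j|/max(N_i,N_j)` discounts uneven
  pairs. With `n` equally abundant, mutually distributed host strains the
  maximum is `1 − 1/n`.
* **IDI** (individual distributed immunity) is the abundance-weighted mean
  number of distinct protospacers a host matches per viral strain:
  `Σ_{i,k} N_i V_k R(G_i,H_k)`.
* **HVI** is the abundance-weighted fraction of host–virus pairs with no
  match — the share of hosts a virus can infect.

The simulator couples Lotka–Volterra ecology (logistic hosts, mass-action
adsorption, burst-size replication, virion decay) with stochastic spacer
acquisition and protospacer mutation; see `docs/methods.md` for the
equations, parameters and conventions.

## Worked example

Score a toy community — two equally abundant host strains, each carrying
one spacer that targets a different protospacer of a single virus:

```sh
$ crispr-di metrics --community community.json
{
 "pdi": 0.5,
 "idi": 1.0,
 "hvi": 0.0,
 "max_pdi": 0.5,
 "n_host_strains": 2
}
```

PDI reaches its two-strain maximum `1 − 1/2 = 0.5`: immunity is fully
distributed. Each host matches the virus exactly one way (IDI = 1), and no
host is susceptible (HVI = 0). Had both hosts carried the *same* spacer,
PDI would be 0 with IDI and HVI unchanged — that is precisely the structure
PDI detects.

Run a short simulation from a naive host and a single virus:

```sh
$ crispr-di simulate --config sim.yaml --seed 7 --out traj.tsv
outcome=completed snapshots=9 acquisitions=37 mutations=250
```

The trajectory TSV (`time, strain_id, side, density`) plus its
`.registry.json` sidecar (genotype per strain id) feed `crispr-di analyze`,
which writes final-window medians, outcome classes and Spearman
correlations. Other subcommands: `sweep` (replicates over a parameter
grid), `empirical` (reads + SNP + spacer-map TSVs → DI estimates),
`fixtures` (synthetic communities and read sets).

As a library:

```python
from crispr_di import SimParams, run_simulation, compute_metrics

traj = run_simulation(SimParams(t_end=3000, seed=1))
print(compute_metrics(traj.community_at(-1)))
```

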