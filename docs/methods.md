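# Methods

## The model

`crispr_di` simulates a well-mixed (1 mL) community of bacterial or archaeal
hosts carrying a single CRISPR locus and a lytic virus population, and
quantifies how immunity is *distributed* across and within host genotypes.

### Ecology

Host strains `i` and viral strains `k` follow density-dependent
Lotka–Volterra dynamics. Let `m_ik ∈ {0,1}` indicate that host `i` carries at
least one spacer matching a protospacer of virus `k`, and let

```
s_ik = (1 − m_ik) + m_ik · f
```

be the effective susceptibility (immunity fails with probability `f`). Then

```
dN_i/dt = r N_i (1 − ΣN/K) − (1−q) φ N_i Σ_k V_k s_ik
dV_k/dt = β (1−q) φ V_k Σ_i N_i s_ik − φ V_k ΣN − m_v V_k
```

Every adsorption removes a virion regardless of outcome. An adsorbing virion
meeting a vulnerable host triggers spacer acquisition with probability `q`
(the host survives) and lysis otherwise; an immune host deactivates the
virion. Only vulnerable, non-acquiring encounters produce bursts, hence the
`(1−q)` factors.

### Evolution

Strain creation is stochastic, layered on the deterministic ecology:

* **Spacer acquisition.** Founder events arrive at rate `q φ N_i V_k` per
  host–virus pair. Each copies one uniformly chosen protospacer allele of
  virus `k` to the leader end of host `i`'s locus; when the locus already
  holds `S` spacers the trailer-end spacer is lost (leader-proximal
  acquisition, FIFO loss). Copying an allele already in the locus changes
  nothing. Founder density (1 cell) moves from parent to the new genotype;
  a genotype identical to an existing strain merges into it.
* **Protospacer mutation.** Mutants arrive at rate
  `μ P · β (1−q) φ V_k Σ_i N_i s_ik` per viral strain (per-protospacer
  probability `μ` per newly produced virion). Each replaces one uniformly
  chosen position with a globally novel allele (infinite-alleles model; no
  back-mutation; double mutants neglected at O(μ²)).

Event counts per step are Poisson draws of the rate fluxes. Because both
rate matrices factorize, the implementation draws one Poisson total and
attributes events to pairs/strains proportionally, keeping steps O(strains).
Strains below the density cutoff (0.1 /mL) are pruned and never resurrected;
allele identifiers are never reused.

### Distributed-immunity metrics

For a community with host proportions `N_i` and viral proportions `V_k`:

* **PDI** (population-wide distributed immunity) sums over ordered host
  pairs and viruses: `Σ_{i≠j,k} N_i N_j V_k σ(N_i,N_j) D(G_i,G_j,H_k)`,
  where `D = 1` iff both hosts match virus `k` and their matched protospacer
  sets are not one identical singleton, and
  `σ(N_i,N_j) = 1 − |N_i−N_j| / max(N_i,N_j)` discounts uneven pairs. With
  `n` equal, mutually distributed strains PDI attains its maximum `1 − 1/n`;
  `max_pdi` generalizes the bound to arbitrary abundances
  (`Σ_{i≠j} N_i N_j σ`). A variant σ that divides by the population-wide
  maximum proportion instead of the pairwise maximum is available behind the
  `sigma="population"` flag for sensitivity analysis; the pairwise form is
  the default.
* **IDI** is the abundance-weighted mean number of *distinct* protospacers
  of a viral strain matched by a host strain — above 1, typical hosts are
  immune in several independent ways.
* **HVI** is the abundance-weighted fraction of host–virus pairs with no
  match: the average share of hosts a virus can infect.

Matching is identifier equality (a spacer is an exact copy of the
protospacer allele it targets); there is no sequence-level or partial
matching. `match_count` counts matched *positions*, so an allele occupying
several positions counts each position.

## Parameters

| name | meaning | default | unit |
|---|---|---|---|
| S | max spacers per locus | 10 | – |
| P | protospacers per virus | 10 | – |
| q | acquisition probability per adsorption | 1e-5 | – |
| μ | mutation probability per protospacer per virion | 5e-7 | – |
| r | host growth rate | 1.0 | 1/h |
| K | carrying capacity | 3.158e5 | cells/mL |
| φ | adsorption rate | 1e-7 | mL/h |
| β | burst size | 50 | – |
| m_v | virion decay | 0.1 | 1/h |
| f | immunity failure probability | 1e-5 | – |
| dt | RK4 step | 0.05 | h |
| cutoff | extinction density | 0.1 | 1/mL |

One hour equals one host generation (1/r). K is chosen so that the 3e5
stability threshold sits at ≈95% of carrying capacity. φ, β, m_v, f and the
initial densities (host 1e5, virus 1e6 /mL) are standard phage–host
modelling values; all are configurable, and the analysis constants (500 h
final window, 3e5 stability threshold over ≥100 consecutive hours, PDI bins
of 0.1, IDI bins of 0.6) live in `RunConfig`.

## Analysis conventions

Each replicate is summarized by the **median over recorded points in the
final 500 h** of PDI, IDI, HVI, total densities and strain counts.
Replicates are excluded from population statistics when the spacer loci were
not all full throughout that window, or when the virus died before the loci
ever filled ("unfilled locus"); post-fill viral extinctions form their own
outcome class. Stability means the host total stays strictly above 3e5 for
a run of consecutive recorded points spanning ≥100 h. Host peaks are local
maxima of the total host density with prominence ≥0.05·K and ≥10 h
separation (the prominence/separation values are this package's
operationalization — exposed in config — since "maximum" has no printed
operational definition). Sweep statistics use Spearman rank correlations,
one-way ANOVA for unbalanced groups with Holm-adjusted pairwise Welch
t-tests (the adjustment procedure is this package's choice), and
linear-vs-quadratic least-squares fits compared by
`AIC = n ln(RSS/n) + 2k` with an RSS floor at machine-residual scale so an
exact fit by both models falls back to the parsimony penalty.

## Numerical choices

* Fixed-step RK4 for the ecology; the susceptibility sums are computed as
  `ΣV − (1−f)·(M·V)` so no `s` matrix is materialized. The 0/1 match matrix
  is stored in single precision (exact for 0/1), which keeps the infection
  sums accurate to ~1e-6 relative at half the memory traffic; with φ=0 the
  viral decay reproduces the closed form to ~1e-10 relative.
* Sweep-scale runs (the directional protospacer/mutation-rate comparison:
  20 replicates per condition, t_end = 3000 h) integrate with dt = 0.2 h and
  record every 5 h. A dt = 0.1 vs 0.2 pilot gave the same PDI regimes and
  identical rank ordering; dt = 0.2 keeps λ·dt well inside RK4 stability for
  the rates involved. Defaults remain dt = 0.05, record 1 h.
* Pruned strains are tombstoned (density zeroed — exactly no influence on
  the dynamics) and buffers compacted when 25% of slots are dead.
* Reconstruction tie-breaks: a truncated read extended by several equally
  supported groups takes the lexicographically smallest completed locus,
  with a warning.
* Strains below figure display thresholds are never dropped before metric
  computation.

## The synthetic data generators

`fixtures.make_community` builds the canonical immunity structures (clonal;
all hosts sharing one matching spacer; fully distributed, where every host
targets a distinct protospacer of every virus; mixed), with equal or
Dirichlet abundances to exercise the evenness factor. `fixtures.make_reads`
emulates sequencing of CRISPR loci: reads sample loci proportionally to
abundance and independently lose a uniform positive number of spacers from
the leader and/or trailer end with a stated probability, with novelty
flagged against a declared ancestral spacer set. This emulates the read
truncation the reconstruction pipeline must undo. It does **not** model
sequencing error, chimeras, PCR duplicates, alignment ambiguity, or
coverage bias along the locus — so passing round-trip tests shows the
grouping logic is correct under ideal base-calling, not that the pipeline
is robust to real-read artifacts.

The empirical pipeline consumes a spacer-per-read table, an escape-SNP
frequency table and a spacer→protospacer map (read alignment and SNP
calling are upstream, external steps). Viral strains are enumerated as
independent combinations of segregating escape SNPs on top of fixed ones
(proportion = Π f over carried × Π (1−f) over absent); a carried SNP removes
its protospacer from the match set (protospacer and PAM mutations treated
identically).

## Known limitations

* The ecological constants φ, β, m_v, f and initial densities are
  declared modelling choices, not fitted values; quantitative sweep
  statistics therefore reproduce regimes and directions, not printed
  numbers. At these defaults and a 3000 h horizon, most low-μ replicates
  end in viral extinction — the high-DI extinction effect, amplified at the
  reduced horizon — so final-window medians there rest on few completers.
* Single CRISPR locus per host; no spatial structure, no CRISPR-lacking
  competitors, no latent period, no plasmids/HGT.
* The independence assumption for escape-SNP combinations ignores linkage
  between mutations on the same genome.
* PDI comparisons between reconstructions of different read depths inherit
  binomial sampling noise in the strain proportions; no shrinkage is
  applied.
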