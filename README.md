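# multibarcode

Multilocus DNA barcoding for closely related species.

Single-locus barcoding (typically COI) fails exactly where taxonomy needs it
most: recently diverged sister species and species pairs exchanging genes,
where incomplete lineage sorting leaves intra- and interspecific p-distance
distributions overlapping — no "barcoding gap".  `multibarcode` implements
the multilocus alternative end to end for researchers working with
target-capture panels of hundreds of nuclear markers:

* **Distance analytics** — p-distance with pairwise deletion, concatenated
  multilocus distances, locus ranking and two-step marker-panel selection,
  and barcoding-gap profiles as a function of the number of loci
  (`multibarcode.seqstore`, `multibarcode.barcode_gap`).
* **Identification** — the *all species barcodes* criterion (a query is
  correct iff all conspecifics rank closer than any heterospecific), spider-
  style threshold optimization with *best close match*, and success-rate
  estimation over locus-resampling replicates (`multibarcode.identify`).
* **Power simulation** — a two-species isolation-with-migration structured
  coalescent with Jukes–Cantor finite-sites mutation, used to map
  identification success over splitting times and migration rates
  (`multibarcode.coalsim`).
* **A three-step barcoding pipeline** — distance screen → exact
  maximum-quartet-support species tree from neighbor-joining gene trees →
  Bayes-factor species delimitation by path sampling, with 2·lnBF read on the
  Kass–Raftery scale (`multibarcode.pipeline`).

## The core quantities

For sequences a, b aligned over L sites, p = (mismatches)/(valid sites) with
a site valid iff both characters ∈ {A,C,G,T}; the multilocus distance
concatenates counts across loci.  In the simulator a pair of lineages in a
deme of N gene copies coalesces at rate 1/N per generation; lineages migrate
backward in time at rate m per generation; demes merge at the split time
t_split; mutations fall as Poisson(μ·L·branch length).  Delimitation compares
lump vs. split hypotheses with a composite pairwise-difference likelihood —
within-population pairs have P(K=k) = (1/(1+θL))(θL/(1+θL))^k with θ = 2Nμ
per site, between-population pairs add a Poisson(2τL) divergence term — and
path sampling (power posteriors at β = (k/K)^(1/0.3)) yields marginal
likelihoods and 2lnBF = 2(lnML₁ − lnML₂).  See `docs/methods.md` for
assumptions and caveats.

## Worked example

Simulate two species that split 700,000 generations ago (N = 20,000 gene
copies, μ = 2×10⁻⁸, 300-bp loci, 5 samples each) and ask how identification
success depends on the number of loci, then compare with a very recent split:

```python
from multibarcode import IMModel, success_vs_loci

deep = success_vs_loci(IMModel(t_split=700_000.0), levels=[1, 30],
                       pool_size=20_000, n_reps=200, seed=201)
recent = success_vs_loci(IMModel(t_split=1_000.0), levels=[1000],
                         pool_size=20_000, n_reps=200, seed=204)
print(deep)
print(recent)
```

```
   level  success_rate  n_reps
0      1           1.0     200
1     30           1.0     200
   level  success_rate  n_reps
0   1000        0.1135     200
```

A deep split is identified essentially always, even from a single 300-bp
locus; after a 1,000-generation split the two species are nearly
indistinguishable (success ≈ 0.11) even with 1,000 loci — lineage sorting,
not information quantity, is the bottleneck.  The same machinery drives the
CLI (`multibarcode simulate | gap | identify | power | run | fixture`), e.g.

```sh
multibarcode power --t-split 10000 --levels 10,100,500 \
    --pool-size 2000 --n-reps 200 --seed 1 --out power.tsv
```

For a full identification, `multibarcode run --query QUERY_DIR --db DB_DIR`
screens the database, prints the species tree, and reports lnML(lump),
lnML(split), 2lnBF, its Kass–Raftery category, and the verdict (assignment
or new species) as JSON.

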