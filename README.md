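# netprop-gwas

Network-assisted gene prioritization from GWAS summary statistics.

A genome-wide association study (GWAS) reports a p-value per SNP, but
most true risk genes never reach genome-wide significance on their
own.  When several genes in the same molecular pathway each carry
nominal signal, a network can aggregate that signal: `netprop-gwas`
converts SNP-level p-values into gene-level scores, spreads the scores
over a protein–protein interaction (or any other molecular) network by
random walk with restart, and returns a ranked gene list together with
enrichment and AUROC validation against a gold-standard gene set.  It
is aimed at statistical geneticists and systems biologists who already
have summary statistics and want network-boosted candidate genes
without touching genotype-level data.

## Method

1. **Gene scoring.** Each gene *g* gets the seed score
   `F0(g) = -log10( min p  over SNPs within [start - w, end + w] )`
   with window *w* = 10 kb by default (boundary inclusive, min-p over
   candidates, p floored at 1e-300).
2. **Propagation.** With W′ the degree-normalized adjacency
   (column-stochastic `W D^-1` by default, or symmetric
   `D^-1/2 W D^-1/2`), iterate

   ```
   F(t+1) = α · W′ · F(t) + (1 − α) · F0
   ```

   until the L1 change falls below `tol`.  The fixed point is
   `F* = (1 − α)(I − α W′)^-1 F0`; α = 0.5 by default.
3. **Validation.** Genes are ranked by `F*`; against a gold-standard
   set the package reports the upper-tail hypergeometric p of the
   top-k overlap (k = 100) and the AUROC (Mann–Whitney identity, ties
   half credit).
4. **Export.** The induced subnetwork of the top-N genes is written as
   NDEx CX JSON (with seed score, propagated score, rank and gold
   membership as node attributes) and SIF.

Inputs: PLINK `.assoc`-style summary statistics (column names
remappable), BED or 4-column gene annotations, and a network as CX
JSON, SIF or 2/3-column edge list.

## Worked example

No downloads are needed — the package ships a deterministic generator
that plants a 20-gene disease module (half its genes carry a
significant SNP, p ≈ 1e-6) inside a 300-gene study with a
planted-partition network:

```sh
netprop-gwas fixtures --out demo/study --seed 7
netprop-gwas run \
    --summary-stats demo/study/summary_stats.assoc \
    --genes demo/study/genes.tsv \
    --network demo/study/network.txt \
    --gold demo/study/gold.txt \
    --out demo/results
```

which prints

```
Network-assisted GWAS prioritization
====================================================
network nodes         300
network edges         938
scored genes in net   300
scored genes missing  0
unscored net genes    0
----------------------------------------------------
alpha                 0.5
normalization         column-stochastic
iterations            19 (converged=True)
final residual (L1)   4.22e-07
----------------------------------------------------
top 10 genes (rank, symbol, seed, propagated):
     1  G237           6.0819   4.508283
     2  G255           6.0540   4.418694
     3  G147           6.1614   4.379628
     ...
----------------------------------------------------
universe              300
gold in universe      20
top-100 overlap        20
hypergeometric p      7.15e-11
AUROC                 0.9738
```

All 20 planted-module genes — including the ten that never received a
significant SNP — land in the top 100 (hypergeometric p = 7.15e-11),
and the module AUROC is 0.97.  Ranking by raw seed scores alone can
only place the ten seeded genes.  `demo/results/` holds the ranked TSV,
the evaluation JSON, the exported `subnetwork.cx`/`.sif`, the exact run
configuration and a log.

The same workflow is available as a library:

```python
from netprop_gwas import NetworkGWAS

model = NetworkGWAS.from_files(
    "demo/study/summary_stats.assoc", "demo/study/genes.tsv",
    "demo/study/network.txt", gold="demo/study/gold.txt")
results = model.fit(alpha=0.5)
print(results.summary())
results.export_subnetwork("demo/top100", top_n=100)
```

Stage-wise subcommands (`score`, `propagate`, `evaluate`, `export`)
operate on the intermediate TSVs when you want to swap in your own
scoring or network.

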