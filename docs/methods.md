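# Methods

## Model

The package treats gene prioritization as linear signal diffusion on a
molecular network.  Let W be the symmetric weighted adjacency of an
undirected network on n genes, D the diagonal weighted-degree matrix,
and F0 the non-negative seed vector of gene scores.  The propagated
score is the fixed point of the random walk with restart

    F(t+1) = α W′ F(t) + (1 − α) F0,      0 ≤ α < 1,

equivalently F* = (1 − α)(I − α W′)⁻¹ F0.  Because ‖α W′‖ < 1 for both
supported normalizations, the iteration is a contraction: it converges
monotonically from any start, preserves non-negativity, and is
equivariant under node relabeling.  The implementation iterates
sparsely (cost per iteration linear in edges) and keeps the dense
closed-form solve as an exact cross-check for small graphs.

Assumptions worth stating plainly: edges are treated as undirected and
(by default) unweighted evidence of functional relatedness; diffusion
is linear, so doubling all seed scores doubles all outputs and the
ranking is scale-invariant; and no attempt is made to model linkage
disequilibrium — the windowed min-p score deliberately stays simple so
that any locus-level scoring method can be substituted upstream via
the stage-wise interfaces.

## Seed scores

A gene's seed is −log10 of the smallest SNP p-value within a symmetric
window around the gene body, inclusive at exactly `window_bp` on both
sides.  A SNP inside two genes' windows contributes to both; a gene
with no candidate SNP scores 0 and is reported.  The transform keeps
the full continuous range of association evidence (rather than a
significant/not-significant cut), which is what lets downstream AUROC
evaluation use the whole genome-wide ranking.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `window_bp` | 10 000 | bp | symmetric window from the gene body; standard locus-to-gene heuristic, exposed as a flag |
| `p_floor` | 1e-300 | – | keeps −log10 finite when p underflows to 0 without perturbing rank order |
| `alpha` | 0.5 | – | equal weight on diffusion and restart; the ranking is stable over a broad middle range of α, and 0 / →1 are the degenerate extremes |
| `normalization` | column-stochastic | – | W D⁻¹ makes every column a probability distribution, so the total score is conserved at every iteration — a useful invariant to monitor; `symmetric` (D⁻¹ᐟ² W D⁻¹ᐟ²) is provided for users who prefer the spectral form |
| `tol` | 1e-6 | L1 | change between iterates; L1 pairs naturally with the conservation invariant |
| `max_iter` | 1000 | – | far above what the contraction needs at α = 0.5 (typically ~20 iterations) |
| `k` | 100 | genes | top-k for the hypergeometric test |
| `top_n` | 100 | genes | exported subnetwork size, matching the top-k analyses |

Seed scores are not rescaled before propagation: in a linear system a
global scale factor cannot change the ranking.

No post-propagation renormalization (e.g., z-scores against
degree-matched null seeds) is applied; raw propagated scores rank
genes.  This is the main extension point for users worried about hub
bias (see Limitations).

## Evaluation

The universe for both metrics is the set of genes in the propagation
network: only networked genes receive propagated scores, and gold
genes outside the network are dropped with a logged count.  The
enrichment p-value is the upper-tail inclusive hypergeometric
P(X ≥ overlap) for the top-k list.  AUROC is computed by the
Mann–Whitney rank-sum identity on the raw propagated scores with
midranks, so ties contribute exactly 1/2 — this makes it invariant
under any strictly monotone transform of the scores and maps a
reversed ranking to 1 − AUROC.  Both statistics are verified in the
test suite against exhaustive enumeration (all subsets, universes ≤ 12)
and all-pairs brute force (universes ≤ 200).

## Numerical and degenerate-input choices

- Ranking ties break by higher seed score, then lexicographic symbol:
  output files are byte-reproducible.
- Node order is always lexicographic regardless of input file order.
- Self-loops are dropped, parallel edges collapse to the maximum
  weight, and isolated nodes are removed before propagation (a
  zero-degree node has no defined transition probability); all three
  events are counted and logged.
- An all-zero seed vector is an error (propagation of nothing);
  failure to converge within `max_iter` returns a result flagged
  `converged=False` rather than raising.
- Chromosome names are normalized (leading `chr` stripped, X/Y/MT
  uppercased) so PLINK- and BED-dialect inputs agree; gene symbols are
  matched exactly and case-sensitively, with a coverage report instead
  of silent alias guessing.
- Duplicate gene annotations merge to the union span — conservative in
  the sense that no candidate SNP is ever missed.

## Synthetic studies

`netprop_gwas.simulate` generates complete, deterministic studies for
testing and demonstration.  Genes are laid out as 10-kb bodies
separated by 10-kb gaps on synthetic chromosomes (25 genes each), so
with the default window every within-body SNP maps to exactly one
gene.  All SNP p-values are uniform(0, 1) — the null of a
well-calibrated GWAS — except that each *seeded* member of the planted
module receives one SNP with p near `signal_p` (default 1e-6: clearly
elevated, short of the conventional 5e-8 genome-wide threshold, which
is precisely the regime network aggregation targets).  The network is
a planted-partition graph: module pairs connect with probability 0.25,
all other pairs 0.02.  Defaults: 300 genes, 5 SNPs per gene, module of
20 with half seeded.

What the generator emulates: sub-threshold signal concentrated in a
connected module, recoverable by diffusion.  What it does not emulate:
linkage disequilibrium between SNPs, realistic allele-frequency and
gene-length spectra, scale-free degree distributions, or annotation
noise.  Passing the recovery tests therefore shows the machinery
amplifies modular signal as designed — not that any particular real
GWAS/network pair will yield a given AUROC.

The planted-partition topology makes module genes higher-degree than
background genes (≈10 vs ≈6 expected neighbors).  Under a fully null
signal this degree difference alone pulls module genes up the
*propagated* ranking, so the null-calibration check targets the
seed-score ranking, where enrichment p-values are indeed approximately
uniform; degree confounding in the propagated ranking is a known
property of diffusion methods, untested here by design (a
degree-matched rewired null would be the extension).

## Problem sizes

The shipped tests and the acceptance script use studies of 300 genes /
1500 SNPs / ~950 edges with 20 replicates, and random graphs up to 500
nodes for the fixed-point and conservation checks — sizes chosen so
the whole suite runs in well under a minute while leaving the module
recovery effect unambiguous (mean propagated AUROC ≈ 0.94 vs ≈ 0.75
for seed-only ranking).  The iterative solver itself scales to
genome-scale networks (10⁴–10⁵ nodes) since each iteration is one
sparse matrix–vector product.

## Limitations

- No LD correction; a gene's score can be inflated by one strong,
  widely tagged locus.  Swap in a locus-aware scorer via the `score`
  stage if this matters.
- No hub/degree correction after propagation (see above).
- Gene identifiers are bare symbols with exact matching; cross-naming
  between annotation and network resources must be resolved upstream.
- Heat-diffusion (matrix-exponential) and related kernels are out of
  scope; the restart walk is the only implemented propagator.
- NDEx is supported as a file format (CX), not as a live service.
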