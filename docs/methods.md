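# Methods

## Model and assumptions

The package operates entirely on GWAS *summary statistics*: one record per
SNP–phenotype test carrying a p-value and an effect size (beta per
minor-allele dose). It assumes the upstream association model (e.g. a
mixed model accounting for kinship) has already been run; computing
p-values is out of scope. Genes are treated as genomic intervals — coding
sequence plus UTRs, read verbatim from the `gene` features of a GFF3 —
and a SNP belongs to a gene iff its position lies inside the interval
(1-based inclusive on both ends, strand ignored). A SNP covered by
overlapping genes counts for all of them; no flanking window is added.

The central object is the binary profile matrix `M` over in-gene,
significant SNPs. Association modules are the equivalence classes of
identical rows of `M`. Because the rows are binary, a Proportional
Similarity of exactly 1 is equivalent to identical profile supports, so
the threshold-1 clustering is evaluated as exact set equality rather than
floating-point comparison; this removes tolerance artifacts and makes the
exact partition the ground truth that the MCL route must reproduce. The
identity `GP = GM ∘ MP` (boolean matrix product) then holds by
construction over the genes whose SNPs entered module construction; it is
still verified explicitly after every run as a regression guard, and a
deliberate edge deletion is tested to confirm the verifier can fail.

By default module construction is restricted to SNPs residing in MPA
genes (genes with ≥ 2 associated phenotypes), so the decomposition
identity is stated over MPA genes; an `include_spa` flag lifts the
restriction, extending the identity to every gene with a hit and letting
single-phenotype genes participate in signature clustering.

## Classification and precedence

A gene with ≥ 2 modules is Type 2 even when one of its modules is
multi-phenotype; the `complex` flag preserves that distinction. This
precedence makes the three classes (SPA, Type 1, Type 2) a partition of
the genes, matching how disjoint genome-scale counts are usually
reported. The toggle lives in the classification output (`label` exposes
the four-way split), not in the class assignment itself.

## FDR procedures

`bh_stepup` implements Benjamini–Hochberg step-up literally (reject the
largest k with p₍ₖ₎ ≤ kq/m, ties resolved by rejecting everything ≤ the
cutoff). `gbs_stepdown` implements the Gavrilov–Benjamini–Sarkar adaptive
step-down with critical values `cᵢ = iq / (m + 1 − i(1 − q))`. The
composition of the two levels is not uniquely determined by a q₁/q₂ pair
alone, so three modes are provided:

* `hierarchical` (default): Simes-combine each phenotype family, BH
  step-up across families at q₁ = 0.1, GBS step-down at q₂ = 7.9·10⁻⁶
  within selected families — a two-stage family screen in the style of
  hierarchical FDR procedures for grouped hypotheses;
* `flat`: one pooled GBS run at q₂ over all tests;
* `fixed`: a plain p ≤ t cut with an explicit threshold.

The defaults q₁ = 0.1 and q₂ = 7.9·10⁻⁶ are the reference operating
point for metabolomics-scale multi-phenotype GWAS; both are recorded in
every run's metadata. Whether q₂ acts per-family or globally is exactly
the difference between the hierarchical and flat modes, which is why both
are kept runnable.

Calibration: on all-null uniform p-values (m = 1,000, 200 replicates) the
empirical FDR of the GBS step-down at q = 0.05 measures ≈ 0.05–0.075
depending on seed, consistent with its nominal level (under a global
null, the false discovery proportion is 1 whenever anything is rejected,
so the empirical FDR is the rejection probability, ≈ 1 − (1 − q/m)^m ≈
0.049).

## Outlier QC

Metabolite intensities are right-skewed, so the MAD is computed
separately per tail: values strictly below the median form the lower
tail, strictly above the upper tail; values equal to the median belong to
neither (keeping the two MADs independent). MADs are raw — no 1.4826
consistency constant — because the k = 5 cutoff is calibrated against raw
MAD distances. A tail with an undefined or zero MAD flags nothing (with a
logged warning): a lone extreme point in an otherwise empty tail has a
tail-MAD equal to its own distance and can never exceed k, which is the
intended conservative behavior for degenerate columns. Zeros participate
in the median (low intensities are the common case and censoring them
would bias it) but always count as invalid for the ≥ 100 non-zero,
non-outlier retention rule; the boundary is inclusive (exactly 100 keeps
the metabolite).

## Markov clustering

`mcl_cluster` is a direct sparse implementation: add self-loops (weight
1), column-normalize, then iterate expansion (matrix power, default 2),
inflation (entrywise power, default 2.0, then renormalize) and pruning of
entries below 1e-5, until the max entrywise change drops below 1e-8 or
200 iterations. Clusters are the connected components of the symmetrized
support of the converged matrix; component extraction is deterministic,
and clusters are ordered by their smallest member. Non-convergence
returns the current partition with a flag rather than failing. On the
weight-1 clique graphs this package feeds it (identical-profile SNPs,
identical-signature genes) the output equals the clique components for
any inflation in [1.2, 5], which the tests assert; a hypothetical MCL
split of a large clique would therefore surface as a test failure, never
be silently accepted. The parameters used by any given run are
config-exposed and logged since there is no single canonical setting.

## Synthetic data

The generator is the package's study-conditions oracle, not a dial. Class
mixture defaults (72% SPA, 5% Type 1, 18% plain Type 2, 5% complex)
follow the genome-scale proportions observed in poplar metabolomics GWAS,
where Type 2 signatures outnumber Type 1 roughly five-fold among MPA
genes; the complex share is a design choice since published counts fold
complex genes into Type 2. Genes are 2 kb intervals separated by 1 kb
gaps, 20 per synthetic chromosome. Planted subsets per gene are pairwise
distinct and sized 1–3 phenotypes; each subset receives 1–3 SNPs
(emulating LD only as SNP multiplicity within a module — no haplotype
simulation). Planted p-values are Uniform(0, 10⁻⁹] — safely below the
per-family GBS critical value at desk-scale family sizes — and null
p-values Uniform(0, 1]; betas are |N(0, 1)| magnitudes with the sign
forced negative with probability 0.8, reflecting the empirical
predominance of minor alleles that lower metabolite levels. Phenotype
matrices use a log-normal baseline (log-sd 0.15) truncated at 2 log-sd so
that clean variation stays strictly inside the 5-MAD band by
construction: planted outliers, displaced ≥ 8 tail-MADs, are then the
only values beyond the cutoff, making recovery scoring exact rather than
probabilistic. Consequences for interpretation: passing recovery tests
demonstrate correctness of the decomposition and QC logic under planted
truth, not statistical power on real, correlated, heavy-tailed data —
the generator has no kinship structure, no LD beyond module multiplicity,
and no metabolite correlation.

All generator randomness derives from a single seed via independent
spawned streams (`[seed, k]` seed sequences), so the emit → analyze →
score path is fully deterministic.

## Numerical and design choices

* Profile matrices use lexicographic row/column order; module and cluster
  ids are SHA1 digests of the sorted phenotype/module sets, so ids are
  stable across runs on identical input.
* Zero-weight similarity edges are never materialized; the all-vs-all PS
  network is stored sparsely with identical semantics (binary rows make
  Σ min a dot product, so the network is one sparse matrix product).
* `verify_decomposition` reports each mismatch as (gene, phenotype,
  missing|extra) and errors if GM references modules absent from MP.
* Pipeline runs are deterministic: identical config and inputs give
  byte-identical primary outputs (the manifest and report embed input
  paths and are compared structurally in tests).
* Problem sizes in tests and the acceptance script (e.g. 1,000 random
  identity configurations of 4–15 genes; threshold-1 fixtures up to 500
  SNPs / 200 genes; a 200-gene, 40-phenotype recovery run) were chosen as
  the smallest scales at which every structural case — shared modules,
  overlapping genes, all four signature classes — occurs repeatedly.

## Known limitations

* Sub-threshold (PS < 1) fuzzy module construction and LD-aware module
  merging are out of scope; modules are exact profile classes.
* The MCL implementation targets the package's clique-structured graphs;
  it is not tuned for performance parity with the native `mcl` binary on
  million-node general graphs.
* Functional enrichment, co-expression integration, and pathway-level
  interpretation of signatures are downstream concerns not covered here.
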