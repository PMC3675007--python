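# Methods

This note documents the statistical procedures implemented in `cnvnet`,
the assumptions behind them, the synthetic-data generator's design, and the
numerical choices a maintainer would want to know about.

## Gene assignment

Coordinates are 1-based and fully closed (Ensembl convention); overlap
means a shared interval length of at least 1 bp; strand is ignored.  A gene
is assigned to a CNV iff **every** transcript of the gene has at least one
coding exon overlapping the CNV.  The rule is deliberately conservative: it
guarantees that the expressed coding sequence of every isoform is affected,
at the cost of missing genes where only some isoforms are hit.  Assignment
is monotone (enlarging a CNV never un-assigns a gene), which the test suite
checks against a brute-force per-exon oracle on random catalogues.

A duplication is flagged *partial* for a gene when at least one coding exon
of any transcript falls outside the duplicated interval.  A partial extra
copy is likely to disrupt rather than dose the gene, so the dosage-direction
stage can reclassify genes whose every duplication is partial as
deletion-like.  Partially deleted genes are treated the same as fully
deleted ones (any coding loss is a loss).

Genes copy-number variable in the same direction in the control cohort are
removed per (gene, direction) pair; the opposite direction is kept.  A gene
hit by both gains and losses is retained in both direction sets, and the
*All* set is their union.  Cohorts are analysed independently; patients
shared between source studies are not deduplicated.

## Enrichment testing

The background universe is the set of genes with ≥1 propagated annotation
in the relevant resource — not all genes — because genes without phenotype
data carry no information for or against enrichment.  Each term is tested
one-sided (enrichment only) by the hypergeometric upper tail
P(X ≥ k | N, K, n); the fold is k/(n·K/N), undefined (reported missing)
when K = 0 or n = 0.  Query genes are counted once per (cohort, direction)
regardless of how many CNVs hit them.

Annotation propagation follows `is_a` edges only (`part_of` is ignored;
the mammalian-phenotype-style ontologies the pipeline targets are
is_a-dominated).  Only *populated* terms are testable: a term must annotate
at least 1% (inclusive, plain real arithmetic — 2 genes in a 200-gene
category passes) of the genes of at least one of its top-level categories.
Top-level categories are taken from the ontology file (terms without
parents), never hard-coded, since the category count is data-dependent.

The scan is hierarchical to limit the multiple-testing burden:

* **Stage 1** tests only the category roots; the BH family is the set of
  roots for one (cohort, direction).
* **Stage 2** tests the populated descendant terms of each stage-1
  significant category, plus any categories force-included via
  `gate_extra_categories` (the mechanism for a-priori categories that miss
  the gate, e.g. a nervous-system category in a behavioural disorder).
  By default all stage-2 terms of a (cohort, direction) form one joint BH
  family; `stage2_family="per_category"` corrects within each category
  instead.  The family boundary is genuinely a convention choice; both are
  supported and the joint default is the more conservative bookkeeping.

Significance is `p_bh ≤ alpha` with alpha = 0.05.  A term BH-significant in
≥3 distinct cohorts is flagged replicated ("triplicated").

## Matched-region randomization

The null control re-places region sets matched in number and length to the
observed CNVs: for each template region, a chromosome is chosen with
probability proportional to its length among chromosomes long enough to
hold the region, and the start is uniform over valid positions.  Regions
may overlap each other; a mask hook (rejection sampling) exists for
assembly gaps but is off by default since synthetic genomes have none.
Gain and loss templates are randomized separately.  Placement is
genome-wide by default (same-chromosome placement is a config switch).

Per replicate, assignments are rebuilt and the raw stage-1 category
p-values recorded; the report summarises each category against
Uniform(0, 1) with a Kolmogorov–Smirnov test.

**Discreteness caveat.**  Exact-test p-values are discrete, hence
stochastically *larger* than uniform under the null.  Where query sizes
vary across replicates (cohort-level nulls) the mixture smooths the
support and the two-sided KS behaves well.  With matched regions the
template lengths are fixed, per-replicate query sizes barely vary
(n ≈ 80 ± 7 under the default conditions), and the two-sided KS can reject
even for an ideally calibrated null — we verified side-by-side that an
exact conditional-hypergeometric simulation with the same query sizes
deviates as much as the pipeline does.  The bias check that matters —
"no excess of spuriously small p-values" — is therefore the one-sided KS
in the anti-conservative direction, which discreteness cannot trigger;
the test suite asserts it on the default world, and an adversarial fixture
(annotations concentrated in long genes, long template regions) confirms
the control fires when genuine length bias exists.

## PPI connectivity

Edges are undirected, deduplicated, self-loops dropped.  The connectivity
statistic is the number of edges with both endpoints in the query set.
The null re-draws gene sets of the query's size uniformly without
replacement from a caller-supplied pool — all network genes, or an
annotation-matched pool (e.g. genes with behavioural/neurological
phenotypes) to discount the tendency of functionally similar genes to
interact; pool membership is data, not code.  The empirical p uses the
add-one estimator (1 + #{null ≥ observed})/(n_perms + 1): it can never be
0, and with 500 permutations an unexceeded observation reports exactly
1/501 ≈ 0.002.

Network expansion adds CNV genes with ≥1 direct edge to a seed gene;
degrees, for the hub analysis, are counted **within the induced candidate
subgraph**, not the full interactome.  The singleton-hub test compares,
by two-sided Mann–Whitney U (sidedness switchable), the degrees of
candidate genes of patients carrying exactly one candidate against those
of patients carrying several, one observation per (patient, gene) record.
Cross-study connectivity counts edges between two disjoint sets (shared
genes removed first) and permutes the second set.

## Dosage direction

Candidates split into duplication-only, deletion-only and both; `both`
genes are excluded from the direction tests to avoid double counting.
Regulator flags derive from the propagated GO-style table (annotation to
the positive- or negative-regulation root; a gene may carry both).  Each
direction set is tested one-sided against the GO-annotated genome
background, with BH over the batch of regulator tests.

## The synthetic world

The generator emulates the *structure* of the real resources at desk
scale, with all sampling driven by one seed (byte-identical outputs per
seed; the seed is recorded in every file header):

* **Genome/genes** — 3,000 genes on 6 chromosomes (~50–100 Mb each),
  roughly 1/7 of the human gene complement.  Genes have 1–3 transcripts;
  alternative isoforms keep a random non-empty subset of the exon pool
  (2–8 coding exons of 80–400 bp, introns 0.5–5 kb); intergenic gaps
  20–350 kb.
* **Ontology** — 6 top-level categories, depth 4, ~360 terms.  Category
  sizes are deliberately heterogeneous (the first category is the small
  one), as in real phenotype ontologies where top categories range from a
  couple of terms to hundreds.  Extra `is_a` edges *within* a category
  subtree make the tree a genuine DAG; a few dedicated leaves have parents
  in two categories (multi-category terms).  Cross-subtree shortcuts are
  avoided because they would let one category inherit another's genes
  wholesale.
* **Annotations** — 60% of genes carry phenotype data (through a 95%
  1:1 orthology map; ~1,700 annotated genes, comparable in spirit to the
  5,671 human genes with mouse-phenotype data in the real resource), with
  1–4 direct terms each; a handful of annotated mouse genes lack
  orthologues to exercise the mapping-drop path.
* **Planted phenotype term** — a leaf of the small first category,
  directly annotated to 50 genes.  A `signal_fraction` of case CNVs is
  placed to fully cover a planted-term gene; 0.5 is the default effect
  size for recovery runs.  The term is a leaf so its gene count is not
  inflated by inherited annotations, and it is sized so that the planted
  signal lifts its whole category through the stage-1 gate — the planted
  signal is meant to be recoverable by design.
* **PPI** — preferential-attachment graph (mean degree 4) over all genes,
  plus a planted 20-gene module with internal edge probability 0.5.  The
  module members are drawn from the planted-term genes: genes sharing the
  planted phenotype are the ones whose products act (and interact) in a
  common process, so cohorts enriched for the term also contain the
  module.
* **Cohorts** — 60 patients, 1–3 CNVs each, lengths log-uniform
  10 kb–5 Mb, 55% gains; controls 60 patients placed uniformly.  With
  `regulator_skew`, each patient instead carries one single-gene deletion
  and one single-gene duplication, with deletion targets carrying the
  positive-regulator flag (and duplication targets the negative flag) at
  rate 0.40 versus the 0.18 genome base rate, 100 patients by default —
  so 100 candidate genes per direction.

What the generator does **not** emulate, hence what passing tests do not
show about real data: realistic human coordinates and gene structure
statistics; annotation biases of curated databases (study-frequency,
date-of-curation effects); true interactome topology (hubs from study
bias, complexes); linkage between neighbouring genes' functions (except
the planted signals); and any relationship between network degree and
mutational deleteriousness — the singleton-hub statistic is therefore
expected to be null on synthetic cohorts, and its correctness is checked
against exact rank-permutation enumeration instead.

## Numerical choices and problem sizes

* Fisher p-values come from `scipy.stats.hypergeom.sf`; the test suite and
  acceptance script verify them against exact integer-arithmetic tail
  summation to 1e-10, exhaustively for all tables with N ≤ 40 (~350k
  tables) plus 5,000 random tables with N up to 200.
* BH is `statsmodels.multipletests(method="fdr_bh")`; significance uses
  `p_bh ≤ alpha`.
* Calibration runs use 500 no-signal cohorts (family-wise false-positive
  rate ≤ 0.07 at BH α = 0.05; per-category two-sided KS p > 0.01 for the
  stage-1 p-values, feasible because cohort-to-cohort query-size variation
  smooths the discrete support — see the discreteness caveat above).
  Recovery runs use 100 cohorts each for the planted term (top stage-2 hit
  ≥ 90%) and the regulator skew (joint deletion→positive +
  duplication→negative recovery ≥ 90%).
* Permutation tests default to 500 permutations; fold = observed / null
  mean (NaN when the null mean is 0).
* Empty direction sets, queries without annotated genes, and missing terms
  degrade explicitly: skipped-with-warning in the scan, K = 0 ⇒ p = 1 in
  single tests, errors where the operation is undefined (empty catalogue,
  empty hub-test group, pool smaller than query).
* Ties in BH and in the Mann–Whitney test are handled by the underlying
  library routines; the hub-test oracle comparison uses tie-free fixtures
  so the exact enumeration is well-defined.

## Known limitations

* The hierarchical gate tests categories before fine terms; a signal
  confined to a term of an otherwise unenriched large category is missed
  unless that category is force-included (`gate_extra_categories`).
* The matched-region null's two-sided KS summary is conservative-biased at
  small query sizes (discreteness); use the one-sided statistic for bias
  detection.
* DAPPLE-style indirect (common-interactor) connectivity and per-protein
  statistics are out of scope; connectivity is direct-edge counting only.
* The generator's interactome is preferential-attachment; degree
  distributions are heavy-tailed but clustering is unrealistically low
  outside the planted module.
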