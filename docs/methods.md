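# Methods

## Data model and coordinates

All intervals are held internally as 0-based half-open `[start, end)`;
VCF and GFF3 positions (1-based) and the companion TSVs (1-based
inclusive `start`/`end`) are converted at the I/O boundary.  A
variant's genomic footprint is `[pos−1, pos−1+len(ref))`, so an
insertion occupies its single anchor base.  Variants are used as read:
inputs are assumed normalized (left-aligned, trimmed) by the upstream
caller, and no liftover is attempted (one assembly throughout).
Multiallelic VCF rows are decomposed into one biallelic record per
alternate allele, with per-sample allele counts recomputed against
that alternate; any genotype containing a missing allele (including
half-calls such as `./1`) is treated as missing, since family-based
callers do not document a more permissive convention.  Chromosome
names are normalized to one `chr`-prefixed style on read.

## Segregation model

The engine reimplements strict family-based inheritance tests
(GEMINI-style `autosomal_dominant` / `autosomal_recessive` /
`de_novo`) from scratch, per family and per phenotype.  Design
choices, all of which the exhaustive oracle tests pin down:

* **Strictness.**  Required individuals — every affected, both parents
  of each examined affected, and every unaffected consulted by a
  no-carrier rule — must have non-missing genotypes; one relevant
  missing genotype vetoes the call.  At least one affected proband
  must have both parents in the pedigree (full trio).
* **Unknown affection** for the phenotype removes an individual from
  the carrier predicates entirely: unknowns neither support nor veto.
  A parent of an examined proband must still satisfy the parental
  genotype rule regardless of affection status.
* **Dominant** requires every affected heterozygous (a
  homozygous-alternate affected fails by default; a configurable flag
  admits it), no unaffected carrier, and at least one affected
  parent→affected child transmission edge with a carrier parent.  In
  multi-generation families any one satisfied edge suffices provided
  the global predicates hold.
* **De novo** additionally requires every genotyped parent of *any*
  affected to be homozygous-reference.  This parental rule is what
  makes dominant and de novo mutually exclusive for one
  (variant, family, phenotype): dominant demands a carrier parent of
  an affected, which de novo forbids.
* Sex chromosomes (X, Y, MT) are excluded from all modes; X-linked
  and compound-heterozygote models, and incomplete-penetrance scoring,
  are out of scope.

## Filters

* **Allele frequency.**  Strict inequality against mode-specific
  cutoffs (defaults: 1% dominant/recessive, 0.1% de novo), required in
  every reference dataset where the variant is reported; records the
  reference database flags as QC-failed are discarded before the test.
  Variants absent from all references fall back to the cohort: the
  cohort AF denominator is twice the number of samples with a
  non-missing genotype at the site over all sequenced samples
  (relatedness deliberately ignored — no founder-only rule is defined
  for the fallback), and the de novo fallback demands zero alternate
  alleles outside the candidate's whole family, a conservative reading
  of "absent in all other samples".
* **Brain expression.**  A feature is brain-expressed when any dataset
  reports TPM strictly greater than the cutoff (default 5); features
  without records are not expressed.  miRNA expression is matched
  mature-name-first with precursor-name fallback, case-insensitively,
  because expression resources disagree on which identifier they
  report; both join keys are supported.
* **Region/site rules.**  miRNA variants continue only from seed or
  mature regions (precedence seed > mature > loop > arm over the
  footprint, one call per overlapped precursor).  3′UTR variants
  continue only when they intersect a broadly-conserved or conserved
  predicted site with context++ score < −0.4, applied at the site
  level (not a gene aggregate).  Site coordinates are taken as
  genomic; projecting UTR-relative coordinates through transcript
  models is the annotation provider's job.

Every filter is a pure per-variant predicate, so the final candidate
set is independent of stage order; the fixed reporting order
(inheritance → region/site → expression → AF) defines the funnel
counts only.

## Seed definition

For synthetic annotation the seed is bases 2–8 of the mature miRNA
counted 5′→3′ on the miRNA strand, mapped strand-aware to the genome
(on `−` hairpins the seed sits at the genomic end of the mature
interval).  Real-annotation users supply region intervals explicitly;
arm/loop boundaries are whatever the annotation source defines, since
hairpin secondary structure is not modelled here.

## Integration and statistics

Gene identity is by symbol; synonym resolution is the caller's
responsibility.  Per-phenotype × mode tables count unique genes, and
all marginals are set unions, never sums.  Family Venn cells partition
families by their exact phenotype combination within one mode, so the
cells of a mode sum to the number of families with any call in it.
GO over-representation uses the exact hypergeometric upper tail
P(X ≥ k) (`scipy.stats.hypergeom.sf`) per term, restricted to terms
with fewer than 600 genes, with Benjamini–Hochberg correction
(`statsmodels`) across tested terms and an FDR threshold of 0.05.  The
background defaults to all genes in the annotation table (the external
enrichment service's background is not reproducible) and is
configurable; per-phenotype queries combine the phenotype's
miRNA-target and 3′UTR gene lists, and genes absent from the
annotation are dropped from the query before testing.

Consensus PPI edges require support from ≥2 distinct source databases;
a database contributes at most one unit of support per unordered gene
pair regardless of row count or direction, and self-interactions are
removed.  Disease-gene-augmented subnetworks exclude edges between two
non-candidate genes and flag nodes of degree > 13 in a display mask
while leaving the analysis graph intact.

## Synthetic cohort generator

The generator's defaults emulate the study conditions of a
multi-phenotype family cohort: 73 families (30 trios, 33 quads, 10
three-generation families; 272 samples), five phenotypes with
per-role prevalences (first child always an ASD proband; parents never
ASD-affected, which makes ASD-dominant plants structurally infeasible
— requesting one raises an error), 22 planted variants covering every
mode × genomic stratum × AF stratum × expression stratum, 200
intergenic background variants with stratified population frequencies
(40% rare < 10⁻³, 30% low, 30% common; 5% of AF rows QC-failed), and
one chrX decoy with a dominant-looking genotype pattern that the
autosomal-only rule must reject.

Plants are placed one per family; within a plant's family the
affection pattern and genotypes realize the mode exactly and all other
phenotypes are set unaffected, so each plant segregates for exactly
its designated (family, phenotype, mode).  Everywhere else the
alternate allele is absent, and carrier chains in three-generation
families are constructed through founders so that, apart from planted
de novo alleles, every genotype is Mendelian-consistent.  Background
variants are confined to intergenic space so they can never enter
either funnel; this is what makes the truth table's per-stage
expectations exact.  Reference AF values per stratum are drawn from
ranges that cannot straddle a cutoff (rare < 10⁻³, low in
(1.1×10⁻³, 9×10⁻³), common in (0.02, 0.5)), with one dataset missing
its value 25% of the time to exercise the available-databases rule.
All randomness flows from a single seed; one configuration yields
byte-identical files.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: linkage disequilibrium and haplotype
structure, sequence context (no FASTA), realistic site/annotation
density, genotyping error and missingness patterns (missingness is
off by default and injectable only into background variants), related
reference-population individuals, and ascertainment effects.  Planted
recovery demonstrates the correctness of the filtering logic, not the
power of the design on real cohorts.

## Problem sizes and numerics

Test and acceptance runs use the default cohort (73 families, ~220
variants, 41 hairpins, 60 genes), exhaustive segregation enumeration
over three pedigree shapes up to five members (199,017 predicate
evaluations), and 100 random enrichment triples with backgrounds up to
1,500 genes; these sizes were chosen so the full planted-truth
recovery remains exhaustive rather than sampled.  Enrichment p-values
are compared with integer-combinatorics tail sums at 10⁻¹²; observed
deviations are at the 10⁻¹⁶ floating-point floor.  Ties in enrichment
output are broken by term id; interval queries return precursor hits
sorted by start position and name so outputs are order-stable.

## Known limitations

* The AF filter treats each reference dataset independently; no
  population-stratified AF handling.
* No compound-heterozygote, X-linked, or penetrance-aware models.
* Gene symbols are not resolved through synonym tables.
* Graph outputs carry attributes suitable for export; layout and
  rendering are out of scope.
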