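# Methods notes

## The simulated study

The generator emulates a crossover benchmark of two sequencing modalities
on identical biological material. The design is fixed by default at
5 subjects × days (1, 2, 8, 9) × 2 DNA extractions × 2 library preps,
giving 80 samples per modality; week 1 covers days ≤ 7 and week 2 the
rest, so the design contains day pairs at gap 1 (within-week) and gap 7
(across-week) but classifies nothing at gaps 6 or 8.

### Compositional noise model

Latent community compositions are log-additive Gaussian: every taxon has a
global log-abundance drawn once from N(0, 1), and each level of the nested
design adds an independent per-taxon perturbation with its own standard
deviation. The measured composition is the softmax of the summed
log-abundances. This model was chosen because it parameterizes each level
of the hierarchy independently — the mean pairwise dissimilarity between
two samples differing only at one level is a monotone function of that
level's sigma alone — which is exactly the property the partitioning
analysis is meant to recover. It deliberately ignores taxon–taxon
correlation of effects (each taxon's subject/day/technical effects are
independent) and any mean–variance coupling beyond what softmax induces.

Defaults (log-scale standard deviations):

| parameter | default | role |
|---|---|---|
| `sigma_subject` | 1.0 | stable person-to-person differences (dominant, per the ecology of the gut microbiome) |
| `sigma_week`, `sigma_day` | 0.4 | temporal drift within a person |
| `sigma_extraction`, `sigma_libprep` | 0.1 | technical noise, well below biology |
| `amplicon_bias_sigma` | 0.5 | study-fixed per-taxon amplification (primer) bias, amplicon only |
| `amplicon_extra_libprep_sigma` | 0.2 | extra per-library amplification stochasticity, amplicon only |

The amplicon modality applies the fixed bias plus the extra per-library
noise to the latent log-abundances and renormalizes; the shotgun modality
observes the latent composition directly. The fixed bias models the
reproducible distortion of amplicon profiles (it cancels within a study
when comparing amplicon samples to each other at identical conditions);
the extra per-library term is what makes amplicon technical replicates
noisier than shotgun ones. The sigma ordering subject > day = week >
technical, and a nonzero amplicon-only term, are the study conditions all
recovery claims are evaluated under; they were fixed when the generator
was written.

Sequencing is a multinomial draw (10,000 reads per sample per modality by
default). Shotgun reads are fixed-length 100 bp and error-free; each read
hits its taxon's genome at a uniform position, and with probability
`p_tie` (default 0.2) is reported as tied across all genomes of the same
genus, which is what exercises the LCA machinery. Alignment itself —
identity thresholds, gapped alignment, sequencing error — is out of scope;
the hit table is the interface.

Amplicon features are emitted as 1–2 ASVs per taxon with genus-level
lineages, except a `p_species_16s` = 0.1 fraction resolved to species,
reflecting how rarely a short 16S region resolves species. Shotgun
resolution is not set by a dial: it emerges from the tie structure
(untied reads resolve to species, genus-tied reads truncate at genus).

### Toy reference database

One genome per taxon (no pan-genomes), lengths uniform on 200 kb–1 Mb,
one contiguous "unique region" covering `unique_fraction` = 0.3 of the
genome, and 10 gene records per genome laid out in non-overlapping slots,
annotated with KO ids drawn from a shared pool; each KO maps to 1–2
enzymes. Genera hold one or two species (so same-genus ties exist),
families pair genera, and two phyla partition the genera.

## Profiling rules and their interpretation

Three readings in the filtering step were genuinely open and are exposed
as configuration, with these defaults:

* **Coverage filter is conjunctive** — an OTU is discarded only when its
  unique-region coverage is below 0.01% *and* its whole-genome coverage is
  below 1%; passing either check retains it.
* **"One millionth of all counts"** is evaluated on pooled raw assigned
  counts across the whole study (marker genes are not modeled; the intent —
  removing globally negligible OTUs — is preserved at profile level).
* **Filter order** is fixed: sample depth → abundance → coverage.
  Filtering is idempotent.

The mean genome length used in normalization is computed over the OTUs
detected in that sample, not the whole database, keeping per-sample totals
comparable. Capitalist tie-breaking is a greedy hitting-set heuristic
(exact minimization is NP-hard): repeatedly assign the genome covering the
most unresolved reads, ties broken by lexicographic genome id; tests check
it equals the exhaustive minimum on small instances and stays within +1 on
random ones. The LCA threshold comparison is inclusive: support of exactly
80% accepts the rank. Per-read taxonomy keeps the full tie set, so the
taxa table reflects LCA truncation even after tie-breaking has chosen a
single genome for OTU counting.

## Diversity and ordination choices

Shannon uses the natural log (a `base` flag gives log2); Chao1 is always
the bias-corrected form, which is defined when no doubletons exist.
Rarefaction is multivariate-hypergeometric subsampling without
replacement, seeded; count tables are rarefied before alpha/beta
computation, and relative-abundance conversion happens after rarefaction
on the taxa path (the enzyme table, already relative, is used as is — the
interleaving of rarefaction and normalization is supported in both orders
but this is the default). PCoA drops negative-eigenvalue axes and excludes
them from the proportion-explained denominator; no Cailliez/Lingoes
correction is applied. The dispersion test consumes the full embedding,
subtracting squared distances on the imaginary axes (Anderson's
correction) and truncating negatives at zero.

## Partitioning conventions

Each pair must isolate a single design variable: library-prep pairs share
subject, day and extraction; extraction pairs share subject, day and
library-prep index; pairs differing in both replicate indices are
unclassified, as are day gaps of 6 or 8. Daily/weekly categories include
all replicate cross-pairs, since replicate labels are arbitrary across
days. All cross-subject pairs enter the subject category regardless of
day. On the default design this yields 40/40/160/160/2560 pairs with 200
unclassified. Genus concordance pools all matched sample × genus cells
into one correlation (a per-sample averaging mode exists); features
lacking a genus rank are excluded, and genera absent from one table score
zero.

## Statistics

All procedures are written from their defining formulas; scipy supplies
ranks and reference distributions only. Permutation p-values use
(count + 1)/(n_perm + 1), so 999 permutations floor at p = 0.001;
`n_perm="all"` switches to exact enumeration over label permutations and
returns the raw proportion. The two-way ANOVA is additive (no
interaction) with Type-II sums of squares, which coincide with Type-I on
the balanced modality × category layout it is applied to. Dunn's z uses
the pooled tie correction and BH adjustment within the family of pairwise
comparisons. PERMANOVA's R² is reported as SS_between/SS_total.

Degenerate inputs are reported, not hidden: zero within-group variance
yields NaN statistics with a warning; singleton groups get dispersion 0
with a warning; all-zero samples are rejected by Bray–Curtis with the
offending ids named.

## What the replicate studies show — and what they do not

The recovery study (20 seeds) checks that median category dissimilarities
order technical < daily/weekly < subject whenever the generating sigmas
do; the power study (50 seeds) checks that pooled t-tests detect the extra
amplicon technical noise; the calibration study (500 null datasets,
n = 12, 199 permutations) checks both tests hold their nominal 5% level.
These replicate runs use the composition → multinomial → Bray–Curtis path
directly — the quantities under test do not depend on the read-level
machinery, which is exercised by its own unit tests and the single full
pipeline run. Problem sizes (10,000 reads/sample, 50 taxa) are the
package's chosen scaled-down study conditions.

Passing these studies shows the pipeline recovers the structure its own
generator encodes. It does not show that real 16S amplification bias is
log-Gaussian, that real technical noise is taxon-independent, or that
real reference databases resemble the toy one; absolute dissimilarity
values are not comparable to any real cohort's. One known consequence of
the simulated separation: with between-subject pairs (2,560 of 2,960)
cleanly above all within-subject pairs, Dunn's rank-based contrasts
between the small categories (e.g. daily vs extraction) have bounded mean
rank differences against a variance term that grows with total N, so only
the technical-vs-subject contrasts are reliably significant — the
headline comparison, and the one the replicate criterion tracks.

## Known limitations

No sequencing-error or chimera model; no FASTQ/SAM ingestion; one genome
per taxon; no strain-level variation; single-factor PERMANOVA only (no
strata); no phylogeny-aware beta diversity. The CLI stages read and write
only the documented TSV/JSON formats, so real data can be substituted at
any stage boundary in those formats.
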