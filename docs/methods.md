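# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that
matter for reproducibility.

## Coordinate conventions

All internal computation uses 0-based half-open intervals (the BED
convention).  VCF positions are 1-based and converted exactly once, at
the I/O boundary: a variant at VCF position *p* with reference allele
of length ℓ occupies `[p−1, p−1+ℓ)`.  Sequence names are matched as
exact strings; no "chr" aliasing is attempted, because silent renaming
is a classic source of silent zero-overlap bugs — callers who need an
alias map should rename at load time.

## Variant annotation

The annotation checklist records each evidence criterion
independently; the final causal call is a conjunction so that every
verdict can be audited field by field.

**Chromatin state.** An interval is a *promoter* when it overlaps both
an H3K27ac peak and an H3K4me3 peak by at least `min_overlap_bp`
(default 1 bp), an *enhancer* when it overlaps H3K27ac and H3K4me1
likewise, and *unclassified* otherwise.  When both mark pairs fire the
promoter call wins: TSS-proximal H3K4me3 is the more specific signal,
whereas H3K4me1 commonly flanks active promoters.  The rule is monotone
— adding peaks can change an enhancer into a promoter but can never
de-classify an element.

**Methylation.** "Low to moderate" methylation is operationalised as:
every overlapping methylation record has level ≤ `methylation_max`
(default 0.6, i.e. up to 60% methylated).  No quantitative threshold is
standard in the literature for this filter, so it is configurable; the
default is deliberately permissive since the criterion is meant to
exclude only clearly silenced, heavily methylated chromatin.

**Genic context** uses the precedence exonic > intronic > five_prime >
three_prime > intergenic, with strand-aware 5′/3′ flanks of
`tss_flank_bp` (default 5 kb).  The same flank defines promoter-RNA
consistency (a promoter-class variant should lie within the flank of
some TSS); enhancer-RNA consistency requires overlap with an annotated
eRNA interval.

**Motif disruption** scans every window of the motif length that
covers the variant, on both strands, scoring log2-odds against the
motif background, and reports `max(alt) − max(ref)` together with the
best-scoring window.  Maximisation before differencing matches how
binding-site gain/loss is usually argued: what matters is the best
site either allele can form, not a positional average.  The score is
exactly antisymmetric under allele swap.  PWMs parsed from count
matrices receive a pseudocount of 0.5 per cell before normalisation, a
standard small-sample correction that also keeps the log-odds finite.

**Allele bias** implements the deltaSVM *scoring* rule: the sum of
k-mer weights over the (2k−1)-bp window centred on the variant, alt
minus ref, with missing k-mers weighing zero (default k = 8).
Training the weight table (a gapped-k-mer SVM fit to open-chromatin
data) is deliberately out of scope — it is bound to large external
data sets — so the scorer accepts any table, including the synthetic
generator's planted one.  The score is linear in the weight table and
antisymmetric under allele swap, and both properties are tested
exactly.  Only SNVs are scored; indels are rejected explicitly rather
than given a misleading number.

**Hi-C connectivity** of the containing element (the DNase peak
holding the variant, else the variant's own footprint) counts distinct
far-end anchors of contacts touching the element; self-loops are
skipped.  The degree is reported as evidence but does not enter the
causal call, because contact lists vary too much in depth for a fixed
degree cutoff to be meaningful across data sets.

**Causal call.** open chromatin ∧ methylation ok ∧ classified element
∧ |allele bias| ≥ `bias_threshold`.  The default threshold of 2.0 is
half the generator's planted effect size of 4.0, placed midway between
the planted signal and the near-zero background scores so that neither
dropout of a single background k-mer weight nor a rare k-mer collision
flips a verdict.  With real weight tables the threshold should be set
from the table's score distribution.  The remaining criteria
(QTL labels, bound proteins, motif deltas, RNA consistency, contact
degree) are reported for human judgement, mirroring how such checklists
are used in practice: the mechanical part is made mechanical, the
judgement part stays visible.

## Hub extraction

A contact participates when exactly one end overlaps the anchor (pairs
overlapping with both ends are self-loops and are skipped with a
warning) and its count is ≥ `min_count` (default 1 — public contact
lists are usually pre-filtered).  The far end maps to every gene whose
body or TSS flank (± `promoter_flank_bp`, default 2 kb) it overlaps;
genes split cis/trans by chromosome and order deterministically by
descending summed contact count, then name.  Hub membership is binary;
no distance-decay normalisation is attempted (that belongs to Hi-C
matrix processing, upstream of this tool).

The significance support permutes far ends: the number of
anchor-touching contacts *m* is held fixed, *m* far ends are redrawn
uniformly without replacement from the far ends of the whole list, and
the hub size is recomputed; `p = (1 + #{null ≥ obs}) / (n_perm + 1)`.
This tests "does this anchor touch more genes than a random set of
ligation partners would", which is the right null when the contact
list's marginal end distribution is taken as given.

## Differential expression and network statistics

Genes enter the up/down sets at |log2FC| ≥ 1.0 and p ≤ 0.05 by
default; both are configurable since expression platforms differ.
Duplicate gene symbols keep the smallest-p record with a warning.

The two-sided Fisher's exact p-value follows the minimum-likelihood
rule (sum of hypergeometric probabilities of all same-margin tables no
more probable than the observed one, with a ~1e-7 relative tolerance
on the comparison to absorb floating-point ties).  The summation is
delegated to `scipy.stats.fisher_exact`, which implements exactly this
rule; the test suite checks it against an independent exact-rational
full enumeration to 1e-12 relative error.  The odds ratio reported is
the sample odds ratio ad/bc, infinite when bc = 0.  Multiple testing
uses Benjamini–Hochberg within each analysis batch; raw p-values are
always reported alongside.

Regulon coverage is |targets ∩ DE| / |DE|; it is scale-free in the
edge list (duplicated edges change nothing).  The enrichment universe
defaults to all measured genes — the least presumptuous choice when
the platform's expressed fraction is unknown — and is configurable by
filtering the expression table beforehand.

Network assembly replaces proprietary "grow/connect" expansion tools
with a one-hop expansion over the supplied edge list: nodes are the DE
genes, any seed genes, and their direct interactors; degrees count
distinct neighbours.  This is a reproducible, auditable equivalent of
"direct interactions" reported by commercial pathway tools.  Edge sign
(activation/repression) is carried through to reports but does not
enter coverage, which is deliberately unsigned.

Master TFs are TFs whose gene body or TSS flank (default 2 kb)
overlaps a super-enhancer interval; TFs without gene models are
excluded with a warning rather than silently counted as non-masters.

## The synthetic-data generator

The generator emulates the *statistical structure the analysis
assumes*, with every planted feature recorded in a ground-truth object:

- co-occurring histone-mark peaks (jittered ±50 bp) with DNase and low
  Beta(1, 19) methylation at planted enhancers (with eRNAs) and
  promoters (at gene TSSs); background methylation Beta(2, 2);
- causal variants at element centres with an exactly planted k-mer
  allele bias (weights are assigned only to alt-window k-mers absent
  from every reference window, summing to ±`bias_effect_size` = 4.0)
  and a consensus PWM per causal reference window; decoys never touch
  an element;
- one contact hub of `hub_size` = 12 genes around a promoter anchor
  over 1,000 uniform noise pairs that are rejected if they touch the
  anchor, so the planted hub is exactly recoverable by construction;
- an expression table with a 6% DE fraction (120 of 2,000 genes),
  log2 fold-changes ±Normal(2.0, 0.35) for DE genes — matching the
  1.2–3.2 magnitude range typical of strong microarray responses —
  Normal(0, 0.25) otherwise, with p-values from the same one-sample z
  model so thresholds act consistently;
- one planted TF regulon covering 60% of the DE set plus a 35%-sized
  draw of non-DE targets, other TF regulons of uniform size 10–60;
- super-enhancers over the bodies of 8 master-TF genes, and HOT
  regions tiled as 100-kb blocks covering exactly 19% of the 40-Mb
  genome (4 chromosomes × 10 Mb).

Structural defaults (hub of 12, 19% HOT coverage, 8 master TFs, 3
causal variants among 100 candidates, 60%-coverage regulon) are the
scale of the system the pipeline targets, so closed-loop tests
exercise realistic set sizes.  Peak dropout (default 0) removes each
histone-mark peak independently; DNase and methylation stay
noise-free, so at dropout rate *d* a planted element classifies
correctly with probability (1−d)² — the quantity the recall tests
bound.

Deliberately **not** modelled: sequence composition (the genome is
uniform random), Hi-C distance decay, TAD structure, microarray
probe-level noise, linkage between variants, and correlated expression
within regulons.  Passing closed-loop tests therefore demonstrates the
correctness of the overlap logic, scoring arithmetic and statistics —
not robustness to the correlated noise of real data.

Determinism: one `numpy.random.Generator` seeded from the config
drives every draw in a fixed order, so identical configs give
byte-identical files (each file carries a provenance header with the
seed).

## Problem sizes used in tests

The closed-loop test suite runs the annotation loop on a reduced
fixture (4 × 1.5 Mb genome, 300 genes, same 200 elements and 100
variants) and the hub/regulon recoveries at full default scale
(2,000 genes, 1,012 contacts, 100 and 50 seeded replicates
respectively); null calibration uses 2,000 hypergeometric tables over
a 20,000-item universe.  These sizes were chosen so the whole suite
exercises every statistic at meaningful scale while remaining quick to
run during development.

## Known limitations

- The causal-call rule is a fixed conjunction; no learned weighting of
  evidence criteria is attempted, and the combination rule should be
  revisited per application.
- `pwm_delta`/`allele_bias` handle SNVs only.
- The hub null conditions on the observed far-end pool; it does not
  model distance-dependent contact probability, so cis hubs in real
  data will look more significant than they should — use the p-value
  as a screen, not an inference.
- The Fisher universe choice (all measured genes) materially affects
  enrichment p-values; sensitivity to it should be checked on real
  data.
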