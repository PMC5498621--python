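# epiregnet

Tools for explaining how a noncoding pharmacogenomic SNP can act through
the regulatory genome: functional annotation of candidate variants from
chromatin evidence, extraction of the transcriptional hub a regulatory
element contacts in Hi-C data, and reconstruction of a TF→target
regulatory network from two-condition differential expression, with
regulon-coverage and Fisher's-exact enrichment statistics.  A
synthetic-data module generates every input format with planted,
recorded ground truth so the whole chain can be tested closed-loop
without external downloads.

The package is aimed at regulatory-genomics and pharmacoepigenomics
analysts who have a handful of association SNPs, standard epigenomic
tracks (DNase, histone ChIP-seq, methylation), a chromatin-contact
list, an expression table and a TF interaction database, and want an
auditable, scriptable version of the usual "is this variant a
functional enhancer/promoter, what does it touch, and which regulons
moved" workflow.

## What it computes

**Variant annotation.** A variant's footprint is scored against an
evidence checklist: open chromatin (DNase peak overlap), low-to-moderate
CpG methylation, combinatorial chromatin state

    H3K27ac ∧ H3K4me1 → enhancer        H3K27ac ∧ H3K4me3 → promoter

genic context (exonic > intronic > 5′ > 3′ > intergenic), molecular-QTL
labels, ChIP-bound proteins, motif disruption, RNA-species consistency
(eRNA for enhancers, TSS proximity for promoters), Hi-C connectivity of
the containing element, and a k-mer allele-bias score.  Motif
disruption is the best log-odds change over all windows and strands,

    Δ = max_w,s Σ_i log2( p_i(alt window) / bg ) − max_w,s Σ_i log2( p_i(ref window) / bg )

and allele bias applies the deltaSVM scoring rule to a supplied k-mer
weight table *w*:

    bias = Σ_{m ∈ kmers(alt window)} w(m) − Σ_{m ∈ kmers(ref window)} w(m)

over the (2k−1)-bp window centred on the variant (training the weights
is out of scope; any gkm-SVM-style table can be supplied).  The causal
call is a transparent conjunction: open chromatin ∧ methylation ok ∧
classified element ∧ |bias| ≥ threshold.

**Hub extraction.** Given an anchor element and a BEDPE contact list,
the hub is every gene whose body or TSS flank overlaps the far end of a
contact touching the anchor, partitioned cis/trans by chromosome, with
an empirical p-value from permuting far ends over the contact list's
far-end pool.

**Network statistics.** From an expression table, genes pass into
up/down sets by |log2FC| and p thresholds.  For a TF with target set T
and DE set D over universe U, regulon coverage is |T ∩ D| / |D|, tested
with the two-sided Fisher's exact test on the 2×2 of target × DE
membership over U, with Benjamini–Hochberg correction across batches.
Master TFs are those whose gene body or TSS flank overlaps a
super-enhancer; HOT-region overlap and regional TF-catalogue coverage
use the same interval logic.

## Worked example

```python
from epiregnet import (SimulationConfig, simulate, extract_hub,
                       hub_null_distribution, select_differential,
                       regulon_coverage, identify_master_tfs)

data = simulate(SimulationConfig(seed=1))

de = select_differential(data.expression, min_abs_log2fc=1.0, max_p=0.05)
print(f"differential genes: {len(de.de)} of {len(de.universe)} "
      f"({len(de.up)} up / {len(de.down)} down)")

tf = data.truth.planted_tf
coverage, enr = regulon_coverage(tf, data.edges, de)
print(f"{tf} regulon coverage: {100*coverage:.0f}% of DE genes "
      f"(Fisher p = {enr.p_two_sided:.2e}, OR = {enr.odds_ratio:.1f})")

hub = extract_hub(data.truth.hub_anchor, data.contacts, data.genes)
p, _ = hub_null_distribution(data.truth.hub_anchor, data.contacts,
                             data.genes, n_perm=999, seed=1)
print(f"hub: {hub.size} genes ({len(hub.cis_genes)} cis / "
      f"{len(hub.trans_genes)} trans), empirical p = {p:.3f}")

masters = identify_master_tfs(data.truth.tf_names,
                              data.tracks.super_enhancers, data.gene_models)
print(f"master TFs (super-enhancer overlap): {len(masters)}")
```

prints

```
differential genes: 120 of 2000 (56 up / 64 down)
TF001 regulon coverage: 60% of DE genes (Fisher p = 2.25e-77, OR = 111.3)
hub: 12 genes (3 cis / 9 trans), empirical p = 0.001
master TFs (super-enhancer overlap): 8
```

i.e. the planted regulon (60% of the 120-gene differential set), the
planted 12-gene contact hub and the 8 super-enhancer-assigned master
TFs are all recovered exactly from the generated files, and the hub is
significant against the far-end permutation null.

The same chain is available from the shell:

```bash
epiregnet simulate --seed 1 -o fixture/
epiregnet all -c fixture/manifest.json -o run/
cat run/closed_loop.json
```

which writes per-stage TSV/JSON reports plus a closed-loop summary
scoring every stage against the recorded ground truth.

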