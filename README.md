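# rnea — regulatory network enrichment analysis

Given a genome-wide differential-expression (DE) table and a curated
reference network of regulator→target interactions, `rnea` answers two
questions a transcriptomics analyst asks after every DE experiment:

1. **Which regulators (TFs, miRNAs) and functional categories (GO, KEGG)
   are driving the observed deregulation?**  Answered by ranked
   over-representation tables computed separately for all, up- and
   down-regulated genes.
2. **What does the active piece of the regulatory network look like?**
   Answered by extracting a hierarchical subnetwork of the reference
   network around the deregulated regulators, including "hidden"
   intermediate regulators whose own transcript did not change.

## The statistics and the rules

**Over-representation.**  For a category of size *K* (a regulator's target
set or a functional gene set) inside a universe of *N* measured genes of
which *n* are deregulated, with *k* deregulated category members, the
enrichment p-value is the hypergeometric upper tail

&nbsp;&nbsp;&nbsp;&nbsp;P(X ≥ k),  X ~ Hypergeom(N, K, n),

Benjamini–Hochberg adjusted within each (category type × partition)
family.  TF categories use **two-level profiles**: a regulator's direct
targets plus the targets of those direct targets that are themselves
regulators ("targets and targets' targets"); miRNA categories are
one-level target sets.

**Subnetwork extraction.**  For each seed regulator (by default every
deregulated regulator) three rules walk its two-level profile:

- **R1** — the seed regulator node is included;
- **R2** — an edge regulator→t is included when the first-level target *t*
  is deregulated (and a deregulated target that is itself a regulator
  contributes its own edges to deregulated daughters);
- **R3** — a first-level target that is *not* deregulated is still kept,
  flagged as a **hidden intermediate**, when its parent regulator and one
  of its own daughter targets are both deregulated; both edges of the
  regulator→t→daughter chain enter the subnetwork.

A synthetic module generates scale-free reference networks (degree-rank
exponent near −2) and DE profiles with planted active master regulators,
so the whole pipeline is testable without any external download.

## Worked example

Simulate a study (200 regulators, 2 000 leaf genes, one planted master
regulator whose two-level profile is 90 % deregulated over a 5 %
background), then run the pipeline:

```bash
rnea simulate --seed 7 --out-dir demo
rnea run --de-table demo/de_table.tsv --interactions demo/interactions.tsv \
         --network regulatory --output both --out-dir demo/out
```

The run prints its manifest counts:

```json
{
  "de_genes": 522,
  "down_genes": 267,
  "enrichment_tables": 3,
  "hidden_intermediates": 31,
  "measured_genes": 2107,
  "mirna_interactions": 0,
  "reference_interactions": 6600,
  "subnetwork_edges": 1736,
  "subnetwork_nodes": 552,
  "up_genes": 255
}
```

522 of 2 107 measured genes pass |log2FC| ≥ 1 and p ≤ 0.05; the extracted
regulatory subnetwork keeps 1 736 of the 6 600 reference edges, 31 of its
552 nodes being hidden intermediates.  The top of
`demo/out/enrichment_TF_all.csv` recovers the planted regulator (the
simulator planted `TF0171`):

```
category_id,type,partition,k,K,n,N,p,p_adj,rank
TF0171,TF,all,439,498,522,2107,2.89898e-293,2.34817e-291,1
TF0149,TF,all,84,111,522,2107,4.01068e-31,1.62433e-29,2
```

i.e. 439 of the 498 genes in TF0171's two-level profile are deregulated —
astronomically more than the ~123 expected by chance.  The edge table
`demo/out/subnetwork_regulatory.tsv` loads directly into Cytoscape-style
viewers:

```
source  interaction  target  rule          source_status  target_status  source_type  target_type
TF0011  TF_target    G00033  R2_target_de  down           down           TF           gene
```

The same analysis is available as a library (`rnea.run_pipeline`,
`rnea.enrich`, `rnea.extract_regulatory`, ...), and real data plug in the
same way: any tab/comma-separated DE table with gene, log2FC and p-value
columns, an interaction flat file (`regulator⇥target⇥type⇥sources`), and
standard GMT gene-set files.

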