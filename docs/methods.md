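# Methods

## Model and procedure

The package implements over-representation analysis (ORA) of regulator
target sets and functional categories, followed by rule-based extraction
of an active regulatory subnetwork.  The underlying model is deliberately
simple: deregulated genes are treated as draws without replacement from a
finite universe, and regulation is treated as a two-level hierarchy over a
static, curated reference network.

**Universe.**  The finite population N of the hypergeometric test is the
set of genes present in the DE input table (`universe_policy="measured"`,
the default).  A genome-wide DE table is required input, which makes the
measured gene list the natural population; testing against it avoids the
classic ORA bias of counting unmeasured annotation genes as "not
deregulated".  `universe_policy="annotation"` extends the universe with
all category members for users who want the annotation-wide convention.

**Hypergeometric tail.**  `hypergeom_pvalue(k, K, n, N)` returns
P(X ≥ k) for X ~ Hypergeom(N, K, n) via `scipy.stats.hypergeom.sf`,
exact at double precision for the population sizes that occur here
(N up to ~10⁴).  P(X ≥ 0) = 1 by construction.  Extremely strong
enrichments underflow double precision; the value is clamped to the
smallest positive float (5e−324) so that downstream BH adjustment and the
0 < p ≤ 1 invariant survive.  An independent log-factorial summation
oracle in the test suite pins the implementation to relative error
< 1e−10 over random count tuples.

**Multiple testing.**  Benjamini–Hochberg step-up (via
`statsmodels.stats.multitest.multipletests`), applied within one
(category type × partition) family — TF/all, TF/up, ... each adjusted
separately.  Adjusting per family keeps the adjusted values comparable
within one reported table; adjusting jointly across types would let a
large GO collection inflate the correction applied to a handful of TFs.
Categories with K = 0 after universe intersection are skipped, not
reported at p = 1, so they do not dilute the family.

**Partitions.**  A gene is up if log2FC ≥ fc_threshold and
p ≤ p_threshold, down if log2FC ≤ −fc_threshold and p ≤ p_threshold,
otherwise unchanged.  Both inequalities are inclusive, so boundary values
count as deregulated.  Up, down and unchanged are disjoint and exhaustive
over the measured genes, and n_up + n_down = n_all in every enrichment
family; this is asserted in tests and holds by construction.

**Two-level profiles.**  A regulator's profile is its direct targets plus
(intermediate, daughter) pairs for direct targets that are themselves
regulators.  Depth is capped at two: in curated regulatory networks the
large majority of interactions lead directly to leaf genes, and deeper
expansion mostly enumerates cycles.  The parent is excluded from its own
profile set, truncating two-cycles (A→B→A contributes only B to A's
profile).  TF enrichment uses the full two-level profile set as the
category (a `first_level_only` flag restricts to direct targets); miRNA
categories are always one-level, since expanding through miRNA targets
has no comparable hierarchical reading.

**Subnetwork rules.**  For each seed regulator R, over its two-level
profile:

- R1: R's node is included.
- R2: edge R→t for every deregulated first-level target t; when such a t
  is itself a regulator, its edges t→d to deregulated daughters join too,
  so fully deregulated chains appear regardless of seeding depth.
- R3: when R is deregulated, a non-deregulated first-level target t with
  at least one deregulated daughter d contributes both edges R→t and
  t→d, and t is flagged a hidden intermediate.  Rule 3 deliberately
  places no condition on t beyond being a first-level target — a hidden
  intermediate needs no enrichment of its own.

Duplicate edges keep the highest-priority tag, R2 > R3 > R1: direct
DE-to-DE evidence outranks inferred hidden-chain evidence.  Seeding
defaults to `seed_mode="de"` (every deregulated regulator); `"enriched"`
seeds regulators whose target set is enriched (adjusted p ≤ alpha in any
partition) and `"union"` takes either.  Under enrichment seeding a
non-deregulated seed can contribute R2 edges but never R3 chains, because
rule 3 requires a deregulated parent.  miRNAs are absent from an mRNA
profile, so they are seeded by enrichment only and contribute one-level
edges to deregulated targets.  The extracted subnetwork is always a
subset of the reference network and is monotone in the DE set: adding DE
genes never removes an edge.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `fc_threshold` | 1.0 | |log2FC| cutoff (log2 units, inclusive) |
| `p_threshold` | 0.05 | DE p-value cutoff (inclusive) |
| `alpha` | 0.05 | adjusted-p cutoff for subnetwork/category inclusion |
| `seed_mode` | `de` | how regulators qualify as extraction seeds |
| `universe_policy` | `measured` | population N of the hypergeometric test |
| `first_level_only` | off | restrict TF categories to direct targets |

The defaults (|log2FC| ≥ 1, p ≤ 0.05, alpha 0.05 on adjusted values)
are the field's conventional thresholds and are applied inclusively.

## Synthetic data generator

`rnea.synthetic` emulates the study conditions the pipeline is built for:

- **Topology.**  Directed regulator→target edges are laid down by
  preferential attachment on regulator out-degree with initial
  attractiveness 0.08; each new edge picks its source with probability
  ∝ (out-degree + 0.08) and its target uniformly, pointing at another
  regulator with probability `regulator_fraction_as_targets` (0.15) so
  that genuine two-level parent/daughter chains exist.  The
  attractiveness value was calibrated so the log-log degree-rank slope of
  the generated networks sits near −2, the exponent curated regulatory
  networks exhibit.  Defaults: 200 regulators, 2 000 leaf genes, 3 edges
  per node (6 600 edges).
- **Planted signal.**  Planted regulators are emitted as deregulated
  (|log2FC| = `effect_size_log2fc` = 2, p ~ U(0, 0.01)); each member of
  their two-level profile is deregulated with probability
  `p_target_de` = 0.9 and every other gene with probability
  `background_de_rate` = 0.05.  Signs follow `direction_bias` (0.5).
  Non-DE genes draw log2FC from N(0, 0.1·effect) clipped strictly inside
  the fold-change threshold and p ~ U(0.1, 1), so they can never cross
  the DE thresholds — only the threshold-crossing behaviour of the noise
  matters to the pipeline, so the exact distribution family is a free
  choice.
- **Planted-regulator selection.**  When no explicit ids are given, the
  planted regulator is sampled uniformly among regulators with out-degree
  ≥ `min_planted_out_degree` (20, i.e. regulating ≥ ~1 % of the default
  genome).  The planted signal models an *active master regulator*, and a
  master regulator without a regulon is a contradiction; in a scale-free
  network a uniformly random regulator is almost always a degree-1 node.
  If no regulator qualifies, the largest one is used.

Everything is deterministic given the spec seed, and emitted tables
round-trip through the package's own readers.

**What the generator does not model:** count-level noise (negative
binomial reads, library size), correlated expression within pathways,
indirect effects beyond two levels, miRNA-mediated repression dynamics,
and identifier messiness.  Passing tests therefore demonstrate that the
statistics and rules are implemented exactly and that strong planted
hierarchical signals are recovered — not that the tool's biological
conclusions on any real dataset are correct.

## Numerical and determinism choices

- Enrichment tables sort by (p_adj, p, category_id); degree-rank tables
  break degree ties lexicographically; edge files sort by (source,
  target, interaction).  Every output is byte-reproducible for identical
  inputs and configuration.
- Duplicate DE rows collapse to the minimum p-value (ties: larger
  |log2FC|, then first occurrence) — deterministic and conservative.
- p-values are printed with `%.6g`, switching to scientific notation
  exactly below 1e−4; CSV and HTML renderings share the formatted values.
- Replicate counts in the validation scripts (100 recovery replicates,
  50 topology seeds, 100 oracle-equivalence networks) keep a full
  from-scratch rerun under a minute on one CPU.

## Known limitations

- ORA treats genes as exchangeable; no gene-length, expression-level or
  network-topology bias correction.
- The reference network is static and unsigned: activation and repression
  are not distinguished, so "active" means deregulation-consistent, not
  direction-consistent.
- Hidden-intermediate inference (rule 3) is correlational; a deregulated
  daughter shared with another deregulated regulator can implicate an
  innocent intermediate.
- BH assumes independence/PRDS across categories within a family;
  overlapping target sets violate this, as in every ORA tool.
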