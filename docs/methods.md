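# Methods

## Model

The package treats ortholog-group classification as a deterministic decision
procedure on species presence–absence patterns. A group is a set of genes
labelled by species; presence is binary per species (paralogs never add to
counts, because the question is whether a *genome* retains the family, not
how often it duplicated). Two error processes of real clustering output are
modelled explicitly:

* **Incompleteness.** Genes can be absent from a genome's annotation rather
  than from the genome. Rather than gating on measured completeness, the
  classifier absorbs this with slack in its thresholds: a clade of 11 may be
  represented by 9, and the overall count may miss up to 4 of 24 metazoans.
  Completeness itself is estimated, for QC only, as coverage of a
  user-supplied reference list of widely conserved, low-copy eukaryotic
  groups — a species covers a reference group if it has ≥ 1 member.
* **Foreign leakage.** MCL-style clustering occasionally attaches a single
  non-target-lineage gene to an otherwise clean group via one or two
  spurious reciprocal-best-BLAST-hit (RBBH) edges. A group therefore
  tolerates up to `max_foreign_species` (default 2) counted non-metazoan
  species, provided each foreign *gene* has at most `max_foreign_rbbh_links`
  (default 3) RBBH links to the group's metazoan members. The threshold is
  applied per gene, not summed over the group: each spurious attachment is
  an independent clustering event, and summing would punish a group for
  having two independently weak contaminants. A foreign species contributing
  paralogs has each gene checked separately for the same reason.

All thresholds live in `CladeSchema` and are configurable; the defaults are
the standard values quoted in the README. The counted rosters (24 metazoans,
112 non-metazoans) are explicit sets, never derived by subtracting totals,
so a genome can be carried in the data but excluded from counting (the
default species table ships one such poorly sequenced non-metazoan).

The focal species (default the placozoan *Trichoplax adhaerens*, the basal
outgroup to eumetazoans) contributes to no criterion; it only drives the
final present/absent partition of the metazoan-specific set. The
single-representative clades (Cnidaria, Urochordata) are handled through an
at-least-one-of rule rather than per-clade minima, since a 1-of-1 minimum
would forbid any dropout in those genomes.

The eukaryote-core control predicate (five-species panel present, no
prokaryotes) and the metazoan-specific predicate are mutually exclusive
under any sensible schema; `classify_collection` asserts this on every run
and raises on violation rather than silently preferring one label.

## Statistics

* Category enrichment: exact hypergeometric tails. Both one-sided tails are
  computed per category; each tail family is Benjamini–Hochberg-adjusted
  separately across categories and the reported q is that of the smaller-p
  direction. This reports over- and under-representation symmetrically
  without committing to a two-sided convention for a discrete test.
  Denominators include only genes with ≥ 1 category annotation.
* Set comparisons: two-sided Fisher's exact test with the probability-mass
  rule (sum of tables, at fixed margins, with conditional probability not
  exceeding the observed table's). Phenotype-class comparisons use
  genes-with-any-phenotype as the denominator; the any-phenotype comparison
  uses genes with RNAi data, mirroring how such proportions are reported.
* RNAi phenotype super-classes: a gene is Essential / Development /
  Movement-behaviour iff it carries ≥ 1 code of the class (codes:
  Emb,Ste,Stp,Lvl,Adl / Gro,Lva,Dpy,Bmd,Bli,Slm,Lon,Sma,Pvl,Muv /
  Unc,Prl,Rol,Egl); multi-class membership is allowed. Codes outside the
  three classes still count as "displays a phenotype" and are logged once.
* Expression tissue classification: case-insensitive plain substring match
  of the keyword stems (neuronal: nerv, neuron; muscle: muscle, myo;
  intestinal: gut, intestin; secretory/excretory: gland, secretory,
  excretory; hypodermal: hypoderm, epiderm; reproductive: uter, gonad,
  germ, sperm, oocyt, reproduct). No word boundaries, by design — stems like
  "intestin" and "germ" are meant to hit inflected forms. "Tissue-specific"
  means exactly one of the six flags.
* Interaction partitioning: edges are pooled into within-A / within-B /
  cross (edges touching genes outside A ∪ B are dropped and counted). Since
  "average proportion of interactions" is ambiguous between edge pooling and
  per-gene averaging, both are emitted: pooled proportions and the per-gene
  mean cross-set fraction.

The exact-test kernels are delegated to scipy (`hypergeom`, `fisher_exact`)
and statsmodels (`fdr_bh`); the test suite verifies them against independent
enumeration oracles (exhaustively over all 2×2 margins with N ≤ 40 for
Fisher, all parameter tuples with N ≤ 12 for the hypergeometric, and
hand-computed step-up values for BH).

## Synthetic worlds

`generate_world` plants six group archetypes (metazoan-core with the focal
species, eumetazoan-core without it, eukaryote-core, clade-restricted,
promiscuous, contaminated-metazoan) at configurable counts; the default
world holds 2,500 groups — roughly a tenth the size of a full
ortholog-clustering release — which keeps the whole suite fast while leaving
hundreds of groups per class. Defaults plant 346 focal-present and 180
focal-absent core groups, mirroring the canonical proportions of the
metazoan setting, and 1,004 control groups. Promiscuous groups always carry
at least one prokaryote so that no planted "other" group can legitimately
satisfy the eukaryote-core predicate; without this the truth labels would be
ambiguous. Per-species paralogs appear with probability 0.1 per group.

Dropout removes a species' genes from a group independently per (group,
species) with the configured rate, emulating genome incompleteness at the
annotation level; it deliberately ignores assembly structure (correlated
loss of syntenic genes), so recall under dropout in these worlds is, if
anything, optimistic about real data. Truth labels are recorded pre-dropout,
making recall under incompleteness a measurable quantity — the quantity the
relaxed thresholds exist to protect. Dropout draws come from a second RNG
stream spawned from the same seed, so a noisy world is a strict thinning of
the same-seed clean world. Contaminating singletons receive RBBH edges to a
configurable number of in-group metazoan genes (default uniform on 0–3,
i.e. below the leakage threshold).

`generate_annotations` samples annotation bundles with planted structure:
per-set any-phenotype and class probabilities (defaults 0.55/0.74 any and
0.56/0.80 essential for the metazoan-like vs eukaryote-like set), per-tissue
expression probabilities (e.g. 0.72 vs 0.54 neuronal), category assignment
with configurable fold-enrichment in the foreground set, and
Erdős–Rényi-style interaction edges. Expression texts are assembled from a
fixed vocabulary in which each phrase contains exactly one tissue's keyword
stems, so the keyword classifier recovers planted flags exactly; real
free-text annotations are messier, and passing tests here show correctness
of the Boolean scheme, not robustness to annotation vocabulary drift.

What the generator does **not** emulate: sequence evolution, phylogenetic
branch lengths, BLAST score distributions, correlated gene loss, and
biased annotation depth between gene sets. Conclusions about those require
real data.

## Numerical and design choices

* All files are UTF-8; TSVs use tabs, `.` decimals and `#` comments. Writers
  emit canonical sorted forms so parse ∘ write is the identity and reruns
  are byte-identical.
* Gene identifiers are opaque, case-sensitive tokens `species|local`;
  parsing splits on the first `|` only.
* Duplicate members within a group line are deduplicated with a warning
  (upstream redundancy should not abort a run); duplicate group ids and
  malformed members are hard errors.
* Degenerate inputs: empty reference list, all-zero contingency tables,
  foreground not a subset of background, overlapping comparison sets, and
  zero observed microtubule endpoints are all hard errors rather than NaNs.
* Determinism: every stochastic component takes a single integer seed
  through `numpy.random.default_rng`; identical seed and config give
  byte-identical serialized outputs.
* The microtubule estimator L = 2·N·a/T treats one reconstruction at a
  time (N is that reconstruction's mean profile count per section); pooling
  across reconstructions is left to the caller.

## Limitations

* The classifier consumes clustering output; it cannot rescue families the
  upstream clustering split or merged.
* Coverage QC is annotation-level only, not a BUSCO-style assembly measure.
* Enrichment assumes one draw per gene from a fixed background
  (hypergeometric); gene-length or annotation-depth biases are not modelled.
* The acceptance-level simulations run at the planted-proportion scale of
  the motivating setting (hundreds of genes, thousands of groups), not at
  the scale of a full multi-database analysis.
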