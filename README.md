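# epidiatom

Analysis toolkit for paired **morphology (microscopy)** and **metabarcoding**
observations of epibiotic diatom communities, with a matched synthetic-data
generator so every stage can be verified against ground truth.

The package covers:

- **`epidiatom.tables`** — abundance-table I/O (TSV/CSV), count↔percent
  normalization, per-sample richness summaries, FASTA sequence collections,
  and labeled distance matrices.
- **`epidiatom.community`** — Bray-Curtis dissimilarity, non-metric MDS
  (Kruskal stress-1, isotonic disparities, classical-scaling + random
  restarts), k-medoids (PAM) clustering on a distance matrix, the Mantel
  permutation test (exact enumeration for small n), and a two-sample
  comparison of two channels' distance distributions (pooled-variance t plus
  a permutation p).
- **`epidiatom.seqops`** — p-distance with pairwise deletion, a
  composite-frequency TN93-form substitutions/site distance, greedy centroid
  OTU clustering at an identity threshold (default 95%), nearest-reference
  taxonomy assignment with rank-level summaries, and neighbor-joining Newick
  export.
- **`epidiatom.cryptic`** — Spearman co-occurrence of OTU abundance profiles
  across hosts, a linear fit of co-occurrence against genetic distance with
  Mantel-style permutation significance, a deterministic maximal-separation
  estimator of the co-occurrence distance threshold, single-linkage grouping
  below the threshold, and a group co-exclusion permutation test.
- **`epidiatom.guilds`** — ecological guild assignment (high profile / low
  profile / motile / planktonic) from an editable genus(+size) lookup, and
  per-sample guild profiles with explicit unclassified mass.
- **`epidiatom.simulate`** — generator of paired observations from latent
  communities with cryptic lineages: biovolume-dependent gene copy number
  (`beta`), dead-frustule carryover (`phi`), fixed 400-valve microscopy
  draws, multinomial read depths, and a controllable within/between-group
  sequence divergence gap.
- **`epidiatom.pipeline`** / **`epidiatom.cli`** — end-to-end orchestration
  with per-stage seeding, JSON summary + schema, and a `click` CLI.

## CLI

```bash
epidiatom simulate --outdir sim --seed 1          # paired dataset + truth JSON
epidiatom dist sim/microscopy.tsv --out d.tsv     # Bray-Curtis
epidiatom nmds d.tsv --out nmds.tsv --seed 1
epidiatom cluster d.tsv --out part.tsv -k 3
epidiatom mantel d_micro.tsv d_meta.tsv
epidiatom compare-channels d_meta.tsv d_micro.tsv
epidiatom gendist sim/lineages.fasta --out g.tsv  # TN93 substitutions/site
epidiatom otu-cluster sim/lineages.fasta --out otus.tsv --similarity 0.95
epidiatom njtree g.tsv --out tree.nwk
epidiatom guilds sim/microscopy.tsv --out guilds.tsv
epidiatom cryptic sim/metabarcoding.tsv sim/lineages.fasta --out cryptic.json
epidiatom run --simulate --seed 1 --outdir run1   # full two-channel pipeline
```

`epidiatom run` executes: normalization → Bray-Curtis → NMDS → k-group
clustering (both channels) → Mantel across channels → channel distance
comparison → genetic distances on the focal OTU set → the cryptic chain
(co-occurrence, fit, threshold, groups, co-exclusion) → guild profiles, and
writes `summary.json` (validated against `epidiatom/schema/summary.schema.json`)
plus per-stage TSV/Newick outputs and a log. Identical config + seed gives a
byte-identical summary.

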