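# perimb

Perinatal 16S microbiome analysis toolkit: a tested re-implementation of a
full maternal/fetal/neonatal ASV-table workflow — batch-effect diagnostics,
low-biomass contaminant filtering, alpha/beta diversity (Shannon, weighted
UniFrac, PCoA), sequential multi-term PERMANOVA, ANCOM, a twin-similarity
bootstrap test and a mother–neonate shared-ASV test — exercised end-to-end on
a synthetic family-structured cohort generator, so every stage is verifiable
without any sequencing download.

## Layout

| module | contents |
| --- | --- |
| `perimb.core` | domain types (`FeatureTable`, `SampleMetadata`, `RootedTree`, `Taxonomy`, `DistanceMatrix`), `collapse_taxa` |
| `perimb.io` | TSV/Newick/JSON readers and writers (lossless round trips) |
| `perimb.synth` | `CohortConfig` / `generate_cohort`: site-, family- and twin-structured compositions, concentration-linked contamination, batch factors, random phylogeny, truth record |
| `perimb.decontam` | CLR transform, correlation/clustering batch diagnostics, frequency & prevalence contaminant scores, `classify_contaminants` |
| `perimb.diversity` | `rarefy`, `shannon`, `weighted_unifrac`, `pcoa`, `rarefaction_curves` |
| `perimb.stats` | sequential (Type I) `permanova`, `ancom` (pairwise log-ratio W), vaginal-health `screen_targets`, `summarize_clinical` |
| `perimb.family` | `twin_bootstrap_test`, `shared_asv_test` |
| `perimb.pipeline` | `run_pipeline` / `report`: the full staged workflow with a reproducibility manifest |

Note that multi-term PERMANOVA partitions variance sequentially in the
listed term order (adonis semantics): R² values depend on term order.

## CLI

All functionality is exposed through one entry point:

```sh
perimb simulate --config examples/cohort.yaml --out cohort/ --seed 1
perimb decontam --table cohort/feature_table.tsv --metadata cohort/metadata.tsv \
    --threshold 0.1 --method combined --out report.json --filtered-table filtered.tsv
perimb diversity --table filtered.tsv --tree cohort/tree.nwk --depth 5000 \
    --seed 1 --out div/
perimb permanova --dm div/weighted_unifrac.tsv --metadata cohort/metadata.tsv \
    --terms site,batch,DeliveryMethod --perms 999 --seed 1
perimb ancom --table filtered.tsv --metadata cohort/metadata.tsv \
    --taxonomy cohort/taxonomy.tsv --group DeliveryMethod --rank 6
perimb screen --table filtered.tsv --taxonomy cohort/taxonomy.tsv
perimb summarize --metadata cohort/metadata.tsv --spec spec.yaml
perimb twin-test --dm div/weighted_unifrac.tsv --metadata cohort/metadata.tsv \
    --stratum all --boot 1000 --conf 0.95 --seed 1
perimb shared-asv --table filtered.tsv --metadata cohort/metadata.tsv \
    --random-pairs 1000 --seed 1
```

The full staged workflow (simulate/load → batch diagnostics → contaminant
filtering → rarefaction → diversity → PCoA → PERMANOVA → ANCOM → twin tests
→ shared-ASV test → target screen → clinical summary):

```sh
perimb pipeline run --config examples/pipeline.yaml --out run/
perimb pipeline report run/
```

Identical config + seed reproduces every artifact bit-identically; the run
directory carries a `manifest.json` recording config, seed and stage order.

## File formats

Feature tables are TSV with features as rows and samples as columns (the
common QIIME export dialect; the reader takes an `orientation` flag for the
transpose). Metadata is QIIME-style TSV whose first column may be headed
`#SampleID`. Trees are Newick; distance matrices are labeled TSV; all
statistical results serialize to JSON.
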