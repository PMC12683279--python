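# viromarker

Marker selection and individual-specificity statistics for skin-virome
presence/absence profiles.

Starting from a taxon-by-sample abundance table (TSV), a taxonomy table and
sample metadata, the package:

- binarizes counts into presence/absence, filters taxa seen in negative
  controls, and aggregates to species/family rank (`viromarker.profiles`);
- selects **marker families**: families detected at ≥2 of 3 time points at
  all three skin sites of at least one subject (*stable*) **and** on ≥2 of
  the 4 objects that a subject touched (*transmissible*), then pulls the
  detected species of those families as candidate markers
  (`viromarker.markers`);
- quantifies individual specificity via Jaccard dissimilarity, per-subject
  within- vs between-subject mean distances and a Wilcoxon rank-sum test,
  plus Shannon diversity, classical PCoA, one-way PERMANOVA and ANOVA — all
  implemented from first principles (`viromarker.stats`);
- simulates complete, seeded studies (8 subjects × 3 sites × 3 time points
  + 4 objects + controls) with planted subject signatures, cosmopolitan and
  transient taxa, detection dropout and per-object transfer probabilities,
  so every stage is testable offline (`viromarker.simulate`).

## CLI

```sh
# write a synthetic study (abundance.tsv, taxonomy.tsv, metadata.tsv, truth.json)
viromarker simulate --output-dir study/ --seed 1

# marker selection -> marker_report.json + occurrence_{skin,objects}.tsv
viromarker markers --table study/abundance.tsv --taxonomy study/taxonomy.tsv \
    --metadata study/metadata.tsv --output-dir out/ \
    --min-count 1 --min-timepoints 2 --min-objects 2

# alpha/beta diversity: shannon.tsv, jaccard_objects.tsv, pcoa_objects.tsv,
# PERMANOVA/ANOVA in diversity_stats.json
viromarker diversity --table study/abundance.tsv --taxonomy study/taxonomy.tsv \
    --metadata study/metadata.tsv --output-dir div/ --permutations 999 --seed 1

# within/between comparison from a stored distance matrix
viromarker compare --distance dist.tsv --metadata study/metadata.tsv \
    --mode skin --out comparison.json
```

Options can also come from a YAML file (`--config`); explicit flags win.
Exit codes: 0 success, 2 input-validation error, 1 unexpected failure.

## File formats

- **Abundance table**: TSV, first column `taxon_id`, header row of sample
  ids, non-negative numeric cells.
- **Metadata**: TSV with columns `sample_id, subject_id, sample_class, site,
  time_point, object_type`; tokens are lower_snake_case
  (`skin|object|negative_control`, `forehead|left_hand|right_hand|none`,
  `t0|t1|t2|none`, `cell_phone|door_handle|fabric|plastic|none`); negative
  controls use `subject_id=none`.
- **Taxonomy**: TSV with `taxon_id, species, family, higher_rank`;
  `UNCLASSIFIED` marks unknown ranks (such taxa are excluded from
  family-level analyses by default).
- Distance matrices are square TSV; reports are JSON with the full resolved
  configuration embedded.

## Library example

```python
import viromarker as vm

cfg = vm.StudyConfig(seed=1, detection_prob=0.9, transfer_prob=0.8)
table, metadata, taxonomy, truth = vm.generate_study(cfg)
report = vm.run_marker_analysis(table, taxonomy, metadata, vm.MarkerConfig())
print(sorted(report.marker_families))
print(report.skin_comparison.wilcoxon.p_value)
print(vm.report_recovery(truth, report))
```
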