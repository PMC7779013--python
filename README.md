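# targetrank

Engine for evidence-based drug-target prioritisation and drug-safety
screening:

- **Evidence validation** — JSON Lines evidence records linking targets
  (`ENSG…`) to disease terms (`EFO_…`-style CURIEs) are checked against a
  versioned schema (`src/targetrank/schema/evidence.schema.json`) and
  deduplicated.
- **Ontology propagation** — the disease ontology (OBO file or
  `child<TAB>parent` table) is loaded as a DAG and each evidence record is
  propagated from its asserted term to every ancestor up to the designated
  therapeutic areas, yielding *direct* and *indirect* associations.
- **Association scoring** — per-source evidence scores in [0, 1] (with hard
  filters: GWAS p-value ≤ 5e−8, priority score ≥ 40, clinical-phase mapping)
  are aggregated per (target, disease, datasource) by a capped harmonic sum
  `Σ s₍ᵢ₎/i²` over descending-sorted scores, normalised so that the maximum
  attainable value is 1; data-type and overall scores apply the same
  reduction to weight-multiplied datasource scores.
- **Pharmacovigilance** — adverse-event report tables are filtered
  (reporter qualification, suspect-drug role, case-version deduplication,
  event blacklist), aggregated into drug×event contingency counts, and
  scored with a one-sided likelihood-ratio statistic; per-drug critical
  values come from Monte-Carlo simulation of the per-drug maximum statistic,
  controlling the family-wise false-positive rate at alpha.
- **Synthetic data** — seeded generators for toy ontologies, evidence sets
  with planted associations, and report tables with planted drug–event
  signals, so everything builds and tests offline.

## CLI

```sh
# generate a complete synthetic fixture
targetrank simulate all --seed 3 --out fixtures/

# validate evidence against the shipped schema
targetrank validate --in fixtures/evidence.jsonl \
    --out valid.jsonl --report report.json

# build association tables (validate + expand + score)
targetrank associations --evidence fixtures/evidence.jsonl \
    --ontology fixtures/ontology.obo \
    --therapeutic-areas EFO_0000002,EFO_0000003 --root-ids EFO_0000001 \
    --out assoc/

# adverse-event signal detection
targetrank faers --reports fixtures/reports.tsv \
    --alpha 0.05 --n-sims 1000 --seed 1 --out signals.tsv

# full pipeline from a YAML config (evidence/ontology/reports paths,
# therapeutic_areas, root_ids, scoring overrides, alpha/n_sims/seed, out_dir)
targetrank run --config run.yaml

# ranked targets for a disease (or diseases for a target)
targetrank rank --associations assoc/associations.tsv \
    --id EFO_0000010 --mode indirect --top-k 10
```

`run` exits 2 on missing inputs, 3 on schema/ontology errors, 4 on internal
invariant violations, and writes a `manifest.json` with config hash, input
digests, per-stage counts and artifact paths next to the outputs.

Scoring configuration (cap, per-source weights, datasource→datatype map,
phase→score map, thresholds) is YAML/JSON; all defaults are overridable via
`--config` / the `scoring:` block of the run config.

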