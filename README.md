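# macroscape

Mining, curation and chemical-space mapping of **macrocycle bioactivity
landscapes** for arbitrary target classes.

Macrocycles — molecules with a ring of 9–30 atoms — are a promising but
under-explored modality for hard target classes such as solute carrier
(SLC) transporters. `macroscape` turns a target list (a table of UniProt
accessions) plus ChEMBL-style bioactivity records into a curated
compound–target dataset, summary landscape statistics, and a 2D chemical
space map, entirely offline and reproducibly.

The pipeline:

1. **Classify structures** (`chem_core`): parse SMILES, canonicalize to
   InChI/InChIKey, perceive macro-rings (SSSR sizes in the inclusive
   window 9–30, hence 22 possible size values), and flag *peptide-like*
   macrocycles — those with ≥ 3 amide bonds whose backbone lies inside a
   macro-ring, matched by the ring-bond SMARTS
   `[NX3]-@[CX3](=[OX1])-@[#6]`.
2. **Ingest** (`ingest`): read target tables (CSV/XLSX), fetch activity
   records through a pluggable backend (live ChEMBL API, local JSON/CSV
   dump, or synthetic fixtures), and normalize to a common schema.
3. **Curate** (`cascade`): macrocycle filter → nanomolar-unit filter →
   interval-relation removal (`>`/`<`) → deduplication on
   (structure, target, type, value) → optional one-ring restriction →
   10 µM activity threshold → pChEMBL standardization
   (p = 9 − log₁₀ value\[nM\], so 10 µM ↦ 5.0). Every stage count is
   recorded in a `CascadeReport` with derived percentage ratios
   (one decimal, round-half-up).
4. **Embed** (`tsne`): a *parametric t-SNE* — a feed-forward network
   (2048→500→500→2000→2) trained with the t-SNE Kullback–Leibler loss on
   radius-3, 2048-bit ECFP fingerprints — maps compounds to 2D, with
   out-of-sample projection.
5. **Score familiarity** (`familiarity`): the count of database synonyms
   per compound as a recognition proxy, thresholded at five.
6. **Report** (`landscape`): scaffolds per target, targets per ring
   size, peptide-like breakdowns, two-cohort cascade comparisons, and a
   plot-ready map export.

## Worked example

```python
from macroscape import fixtures as fx, cascade as casc

records = fx.activity_table(fx.CascadePlan(20, 12, 10, 9, 7, 5, 4), seed=17)
pairs, report = casc.run_cascade(records)
print(report.n_retrieved, report.n_macrocycle_points, report.n_unique_pairs,
      report.n_one_ring_pairs, report.n_below_threshold)
# 20 12 7 5 4
print(round(pairs[0].pchembl, 3))  # 6.987  (a 103 nM measurement)
print(report.derived_ratios)
# {'macrocycle_share_of_retrieved': 60.0, 'unique_structure_share': 50.0,
#  'one_ring_share': 41.7, 'ic50_share': 33.3}
```

The planted fixture removes a known number of records at each stage
(8 acyclic, 2 micromolar, 1 interval, 2 duplicates, 2 two-ring, 1 above
10 µM), and the cascade report recovers those counts exactly. The same
API applied to real cohort stage counts gives the cohort comparison:

```python
slc  = casc.CascadeReport.from_counts(87_887, 825, 92, 169, 161, 141, 75, label="SLC")
print(slc.derived_ratios["macrocycle_share_of_retrieved"])  # 0.9 (%)
```

Command line (same steps as the library):

```bash
macroscape fixtures --out fx/ --seed 3
macroscape mine --targets targets.csv --backend dump --dump-path fx/activities.jsonl --out mined/
macroscape curate --in mined/activities.jsonl --targets targets.csv --out curated/
macroscape embed --pairs curated/curated_pairs.csv --epochs 300 --seed 5 --out model/
macroscape project --model model/ --pairs curated/curated_pairs.csv --out coords.csv
macroscape report --pairs curated/curated_pairs.csv --out reports/
```

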