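# dmpenrich

Cell-type enrichment analysis for EWAS probe sets in regulatory regions.

## The problem

An epigenome-wide association study (EWAS) on an Illumina methylation array
yields a list of differentially methylated positions (DMPs), usually measured
in a heterogeneous tissue such as whole blood. A central interpretive question
is *which cell type the signal comes from*: DMPs that preferentially fall in
the DNase I hypersensitive sites (DHSs) of, say, monocytes point either to a
monocyte-specific regulatory effect or to a shift in monocyte proportions
between groups (a cell-composition effect).

`dmpenrich` answers this by overlap enrichment with a matched-background
null. For a test set of `n` probes and each reference sample (a cell type's
DHS or histone-mark hotspot track):

1. Count `k`, the test probes whose CpG coordinate falls inside a hotspot.
2. Draw 1,000 random background probe sets from the array manifest, each
   matching the test set probe-for-probe on annotation: probes are stratified
   into **21 bins** — 7 gene-model categories (1stExon, 3UTR, 5UTR, Body,
   IGR, TSS1500, TSS200) × 3 CpG-island categories (Island, merged
   Shore/Shelf, open sea).
3. Let `p0` be the pooled overlap proportion across the background sets.
   The enrichment p-value is the one-sided binomial upper tail
   `P(X ≥ k), X ~ Bin(n, p0)`, computed **entirely in log space**
   (log-gamma binomial coefficients + log-sum-exp), so deep tails neither
   underflow nor slow the run. A Z-score
   `(k − mean(bg)) / sd(bg)` is co-reported.
4. Correct across the panel's samples with **Benjamini–Yekutieli** (valid
   under the dependence expected between related cell types; BH is
   co-reported as a diagnostic) and tier each sample:
   red `q < 0.01`, pink `0.01 ≤ q < 0.05`, blue otherwise.

Inputs are probe IDs or zero-based `chrN` BED records; probes off the array
are excluded, and a 1-kb proximity filter (random visiting order) drops
probes within 1 kb of an already-selected probe so correlated CpGs are not
tested twice. Overlaps come from a modular single-file SQLite store of
per-probe bitstrings, one table per dataset panel, so new panels append
without touching existing ones.

## Worked example

No downloads are needed: the package generates complete synthetic studies
(manifest, hotspot panel, planted test set, ground truth).

```python
import numpy as np
import dmpenrich as dm

spec = dm.FixtureSpec(n_probes=2100,
                      chromosomes={"chr1": 2_000_000, "chr2": 2_000_000,
                                   "chr3": 2_000_000},
                      n_samples=8, planted_set_size=30)
rng = np.random.default_rng(1)
manifest = dm.generate_manifest(spec, rng)
planted = dm.plant_test_set(manifest, spec, rng)        # the "EWAS hits"
tracks, meta, truth = dm.generate_hotspot_panel(manifest, spec, rng,
                                                planted_probes=planted)
matrix = dm.build_overlap_matrix(manifest, tracks)

model = dm.EnrichmentModel([p + "\n" for p in planted], (matrix, meta),
                           manifest, n_backgrounds=500)
res = model.fit(seed=3)
print(res.summary())
```

```
Probe-set regulatory-region enrichment
======================================================
Analyzable probes : 30   (off-array: 0, proximity-filtered: 0)
Reference samples : 8
Backgrounds       : 500 annotation-matched sets   seed: 3   rng: numpy PCG64 (default_rng)
Correction        : Benjamini-Yekutieli across the panel (BH co-reported)
------------------------------------------------------
sample      tissue          k     n        Z           p        q_BY  tier
S01         blood          22    30    10.86   6.834e-15   1.486e-13  red
S03         kidney          3    30    -0.17   6.562e-01   1.000e+00  blue
S06         brain           3    30    -0.27   6.920e-01   1.000e+00  blue
...
Tiers: 1 red (q<0.01), 0 pink (q<0.05), 7 blue
```

Sample `S01` is the planted enriched cell type: 22 of the 30 test probes sit
in its hotspots against a pooled background rate near 0.1, giving a binomial
p of 7e-15 and a BY q-value far below the red tier's 0.01 threshold — the
model calls the correct cell type, and every unenriched sample stays blue.
`res.to_tsv(...)` writes the per-sample table (Zscore, Pvalue, Cell, Tissue,
Datatype, File, Probe, Accession, Qvalue) and `res.plot(...)` draws the
−log10 p profile colored by tier with the q = 0.05 / 0.01 threshold lines.

The same flow is scriptable:

```bash
dmpenrich make-fixtures --out fx --seed 3
dmpenrich build-store --manifest fx/manifest.tsv --tracks-dir fx/tracks \
                      --metadata fx/metadata.tsv --out store.db
dmpenrich run --input fx/testset.txt --store store.db \
              --manifest fx/manifest.tsv --seed 5 --out results/
dmpenrich fp-benchmark --store store.db --manifest fx/manifest.tsv --seed 0
```

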