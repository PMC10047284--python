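# linc-chromatin

Analysis toolkit for studying how loss of the LINC complex (the
nucleoskeleton–cytoskeleton bridge; in *Drosophila*, the SUN-domain
gene *koi*) increases chromatin repression in muscle nuclei.  It is
aimed at chromatin and nuclear-organization labs who want to run, or
stress-test on synthetic data, the four computational analyses such a
study rests on:

1. **DamID differential occupancy** (`linc_chromatin.damid`) — per-gene
   log2(Dam-fusion/Dam-only) tables are filtered (FDR < 0.05, GATC
   sites > 1) and hits are called by PCA regression: for points
   (mean control, mean mutant occupancy), z_pca is the standardized
   perpendicular residual from the major principal axis, significant at
   |z_pca| > 1.96 (≈95% CI).  Includes group-overlap summaries, k-means
   clustering of fold changes with Gap-statistic model selection, and a
   Monte-Carlo test for genomic clustering of hits with
   p = (N_GE + 1)/(N_runs + 1).
2. **3D nuclear image quantification** (`linc_chromatin.imaging`) —
   Otsu-based 3D nucleus segmentation, masked intensity and volume
   measures, bright-puncta segmentation with a 0.01 µm³ volume filter,
   periphery-to-center radial profiles, and genotype comparison with a
   linear mixed model (genotype fixed; larva and muscle-within-larva
   random).
3. **Coarse-grained polymer simulation** (`linc_chromatin.genome`,
   `.simulation`, `.sim_analysis`) — the 176.2 Mbp genome as 35,240
   beads (5 kbp, σ = 30 nm) in four chains, 70% euchromatin / 30%
   pericentromeric heterochromatin, H3K27me3 patches (exponential
   lengths, mean 17 beads, 40% coverage), confined at 15% volume
   fraction, with truncated-LJ attractions (ε_HH = 0.5, ε_EE = 0.35,
   cross 0.3 kBT) and dynamic harmonic H3K27me3–lamina bonds (form at
   1.5σ, break at 2.5σ, stiffness K) integrated by overdamped Langevin
   dynamics.  Analysis covers nucleoplasmic H3K27me3 cluster sizes and
   radial chromatin density versus tether strength K (10 vs 1.5).
4. **Synthetic data** (`linc_chromatin.synthetic`) — seeded generators
   for every input above (occupancy tables, BED annotations, 3D
   two-channel nucleus cohorts with a larva → muscle → nucleus
   random-effect hierarchy), with ground truth for recovery tests.

## Worked example

Generate a synthetic DamID experiment with 40 spiked, genomically clustered genes, call hits,
and test whether the upregulated hits cluster along the genome:

```python
import numpy as np
from linc_chromatin.damid import call_hits, proximity_mc_test
from linc_chromatin.synthetic import SynthDamidSpec, gen_damid_table

spec = SynthDamidSpec(n_true_hits=40, clustering="clustered")
table, truth = gen_damid_table(spec, seed=3)
hits = call_hits(table)
called = hits[hits.significant & (hits.direction == "increased")]
print(f"{len(called)} genes with increased occupancy "
      f"of {truth.true_hit.sum()} spiked")

annotation = table.rename(columns={"gene_id": "name"})[
    ["chrom", "start", "end", "name"]].assign(score=0, strand="+")
res = proximity_mc_test(called["gene_id"], annotation, window=10_000,
                        nruns=1000, seed=5)
print(f"observed close genes: {res.observed_count}, "
      f"null median: {res.null_median:.0f}, p = {res.p_value:.4f}")
```

prints

```
60 genes with increased occupancy of 40 spiked
observed close genes: 40, null median: 0, p = 0.0010
```

i.e. the caller finds the spiked genes (plus the expected tail of the
null), 40 of the called genes have another called gene within 10 kbp,
no null redraw reached that count in 1000 runs, and the clustering is
significant at the resolution floor p = 1/1001.

The same style applies to the other stages: `gen_nuclei_cohort` →
`quantify_cohort` → `compare_groups` recovers injected genotype
effects on nuclear mark intensity, and `run_simulation` →
`compare_tether_strengths` reproduces the direction that weaker
lamina tethering (K = 1.5 vs 10) grows nucleoplasmic H3K27me3 clusters
and shifts chromatin away from the periphery.

A thin CLI mirrors the library:

```bash
linc-chromatin genome --seed 1 --out beads.tsv
linc-chromatin simulate --beads beads.tsv --steps 20000 --stride 1000 --seed 1 --out traj.npz
linc-chromatin analyze-sim --traj traj.npz --out stats.tsv
linc-chromatin generate damid --seed 1 --out damid/
linc-chromatin damid call --table damid/occupancy.tsv --out hits.tsv
```

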