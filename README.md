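# tandemapa

Probe-level analysis of tandem-3'UTR alternative polyadenylation (APA) for
tumor cohorts profiled on transcriptome microarrays, with APA-based
subtyping and pooled shRNA screen statistics.

## The problem

Most mammalian genes carry several polyadenylation sites in their 3'UTR.
Using a proximal site produces a short isoform that lacks the regulatory
elements of the *extended* region between the proximal and distal sites;
proliferating and malignant cells tend to shift toward the short isoform.
On a transcriptome array, probes in the *common* region (upstream of the
proximal site) see total transcript abundance while probes in the extended
region see only the long isoform, so a shift in isoform usage appears as a
step in the probe-intensity series along the 3'UTR.

`tandemapa` turns that observation into a pipeline:

1. **Tandem-UTR models** — group transcripts sharing a 3'UTR start with
   distinct APA sites, assign uniquely mapped probes, and keep tandems with
   at least four probes on each side of the proximal site.
2. **Change-point detection** — after normalizing each probe to its median
   across the normal samples, all samples' probe series for a tandem are
   modelled jointly with a multivariate Bayesian change-point
   (product-partition) model sharing a common partition. Gibbs sampling
   yields, per inter-probe boundary `j`, the posterior change probability
   `rho_j`, and per sample the posterior probe means. The boundary with
   maximal `rho` is the APA change point; tandems with multiple posterior
   peaks or unstable segment means are excluded.
3. **Short-3'UTR index (SUI)** — per sample `i`,
   `SUI_i = w̄_ic − w̄_ie`, the difference between the posterior mean of
   the common and extended segments. Larger SUI ⇒ more short isoform;
   normal-like samples sit at ~0.
4. **Subtyping** — tandems in the top 25% by coefficient of variation of
   SUI feed a non-smooth NMF (`X ≈ W S H`, `S = (1−θ)I + (θ/k)J`) with a
   2–10 rank survey scored by cophenetic, dispersion and silhouette
   metrics of the consensus matrix, cross-checked by consensus k-means
   over resampled sample subsets. New samples (cell lines) are assigned by
   a nearest-shrunken-centroid classifier after quantile normalization
   onto the training distribution.
5. **Differential APA** — an empirical-Bayes moderated two-group t-test
   per tandem with BH adjustment; events are called shortened/lengthened
   at `|ΔSUI| ≥ 0.2` and `q ≤ 0.05`.
6. **Screen statistics** — counts-per-million normalization of pooled
   shRNA barcode counts, per-gene mean log2(day d / day 0) enrichment
   scores, one-sided Mann–Whitney depletion tests against the
   non-targeting controls, Spearman replicate concordance, and a
   Kolmogorov–Smirnov diversity-shift test.

A synthetic-data module generates probe-level datasets and screen count
tables with planted ground truth (isoform fractions, change points,
subtypes, depleted genes), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from tandemapa import (SimulationConfig, simulate_probe_dataset, identify_tandems,
                       assign_probes, normalize_to_normal_median, profile_tandems)

effects = np.tile([0.0, -1.0], (8, 1))      # subtype S2 halves the long isoform
cfg = SimulationConfig(n_tandems=8, probes_per_segment=(4, 4), n_normals=10,
                       subtype_sizes=(6, 6), subtype_effects=effects,
                       noise_sd=0.1, seed=42)
matrix, probe_map, annotation, truth = simulate_probe_dataset(cfg)
tandems = assign_probes(identify_tandems(annotation), probe_map)
sui, qc = profile_tandems(normalize_to_normal_median(matrix), tandems, seed=0)
print(qc.head(3))
group = matrix.sample_groups.copy()
group[truth.true_subtype.index] = truth.true_subtype
print(sui.iloc[:3].T.groupby(group).mean().round(2))
```

prints

```
              change_index  max_rho qc_status
tandem_id
G0001:10000              3      1.0        OK
G0002:60480              3      1.0        OK
G0003:110000             3      1.0        OK

        G0001:10000  G0002:60480  G0003:110000
S1             0.10         0.06          0.07
S2             1.03         1.11          1.06
normal         0.04         0.02          0.08
```

The sampler puts the change point at boundary 3 with posterior probability
1.0 — exactly the planted proximal APA site after the fourth probe. The
recovered SUI separates the groups as planted: normals and the unshifted
subtype S1 sit near 0, while S2, whose long-isoform fraction was halved
(a −1 log2 shift), shows SUI ≈ 1.

A CLI wraps the same stages for shell use:

```sh
tandemapa simulate --config config.yaml
tandemapa profile  --config config.yaml
tandemapa subtype  --config config.yaml --seed 7
```

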