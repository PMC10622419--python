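# subtyper

Tissue-based spatial-metabolomics subtyping of tumor and stroma
compartments, for computational pathology and cancer-metabolism groups
working with MALDI imaging mass spectrometry (IMS) of tissue microarrays.

Starting from pixel-level IMS intensity matrices and co-registered
pan-cytokeratin / vimentin immunofluorescence, the package

1. **annotates** each pixel as tumor (panCK⁺), stroma (panCK⁻ vim⁺) or
   unassigned, RMS-normalizes the spectra and aggregates one mean
   metabolite profile per patient × compartment;
2. **clusters** each compartment's cohort by resampling **consensus
   clustering**: per iteration an 80% subsample is hierarchically
   clustered (average linkage on 1 − Pearson) and, per candidate K, the
   consensus matrix M_K(i,j) = #co-clustered / #co-sampled is accumulated.
   The number of subtypes K\* is chosen by the **CDF delta-area rule**:
   with A(K) the area under the empirical CDF of consensus values,
   Δ(K) = (A(K) − A(K−1)) / A(K−1), and K\* is the largest K with
   Δ(K) ≥ τ (default τ = 0.1);
3. **characterizes** subtypes: one-vs-rest Spearman correlation with
   immunomarkers (CD3, CD8, PD-L1, γH2AX) with Benjamini–Hochberg
   adjustment, Kruskal–Wallis + Dunn group tests, clinicopathological
   chi-square / Fisher exact tests, Kaplan–Meier / log-rank survival
   comparisons and multivariate Cox proportional-hazards fits (Efron
   ties), per-subtype metabolite correlation networks (BH-adjusted
   Spearman, q < 0.001) and hypergeometric pathway over-representation;
4. **transfers** the subtypes to an independent chemotherapy-treated
   cohort via a metabolite-panel nearest-centroid classifier (top-H
   Kruskal–Wallis panel, median centroids in z-space) and tests the
   assigned subtypes against chemotherapy response (pairwise Fisher) and
   outcome (log-rank, Cox with MPR and UICC stage).

A bundled synthetic-data generator plants known subtypes, marker
associations and survival hazards at every level (pixels, IF images,
tables), so the whole pipeline is testable end-to-end without any
external data.

## Worked example

```python
from subtyper import SynthConfig, run_consensus
from subtyper.experiments import annotate_cohort

cfg = SynthConfig(n_patients=100, seed=1)        # 4 planted subtypes
cohort, truth = annotate_cohort(cfg, "tumor")    # pixel -> profile stage
res = run_consensus(cohort, iters=200, seed=1)
print(res.summary().round(3))
print(res.assignment.summary())
```

```
     area  delta  selected
K
2   0.347  0.347     False
3   0.602  0.737     False
4   0.746  0.240      True
5   0.761  0.020     False
...
         count  percent
subtype
T1          34       34
T2          23       23
T3          22       22
T4          21       21
```

The area under the consensus CDF rises sharply up to K = 4 and the
relative gain collapses beyond it (Δ(5) = 0.020 < τ), so the delta-area
rule selects four subtypes — matching the four planted ones; the final
labels recover the planted partition with adjusted Rand index 1.0.
Subtypes are numbered by descending size (T1 largest).

The same objects drive the rest of the analysis:
`subtyper.association.subtype_marker_correlation(res.assignment, markers)`
returns the per-subtype signed Spearman table, `subtyper.survival.cox_fit`
the hazard ratios, and `subtyper.transfer.fit_classifier` /
`assign_cohort` the independent-cohort transfer.

There is also a CLI (`subtyper simulate | cluster | associate | survive |
transfer | run`); `subtyper run --seed 1 --outdir out/` executes the whole
pipeline and writes every stage artifact plus `report.json`.

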