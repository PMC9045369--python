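# petatn

Template-based PET quantification and A/T/N biomarker classification for
neurodegenerative dementia cohorts, exercised end-to-end on synthetic 3D
brain phantoms.

Clinical PET studies of dementia quantify three tracers — a tau ligand
(¹¹C-PBB3), an amyloid-β ligand (¹¹C-PIB) and ¹⁸F-FDG for glucose
metabolism — as **standardized uptake value ratios**,

    SUVR(v) = median uptake in VOI v / median uptake in cerebellar crus grey matter,

and classify each patient on the A/T/N scheme: amyloid status (A) from the
global cortical PIB SUVR against a ROC/Youden cutoff (or CSF Aβ42 < 600
ng/L when no amyloid scan exists), neurodegeneration status (N) from
single-subject FDG hypometabolism mapping against a control cohort (or CSF
t-tau > 450 ng/L). A+ patients form the *AD continuum*, A−N+ is *SNAP*
(suspected non-AD pathophysiology), A−N− is *biomarker-negative*. Group
differences in regional tau uptake are then tested nonparametrically
(Kruskal–Wallis + Bonferroni-adjusted rank-sum tests, Cliff's delta effect
sizes) and voxel-wise (Welch t-maps with permutation cluster-extent FWE,
voxel p < 0.01, cluster k > 100).

Because amyloid-positive and -negative scans have different activity
distributions, amyloid images are matched to **adaptive templates**: the
scan is compared with a positive and a negative PIB template by slice-wise
normalized cross-correlation,

    NCC_z = (1/n) Σ_{x,y} (I − Ī)(T − T̄) / (σ_I σ_T),

and the template with the higher mean NCC is adopted.

No patient data ship with the package. Instead, `petatn.synthetic`
generates atlas phantoms and multi-tracer cohorts with known ground truth
— regional tau uptake, global amyloid load, FDG hypometabolism, CSF values
and modality availability all parameterised from published cohort tables —
so every downstream stage is testable from scratch. See
[docs/methods.md](docs/methods.md) for the full model description and
its limitations.

## Worked example

```python
import petatn as pa

cfg = pa.PipelineConfig(output_dir="run", n_permutations=200, seed=1)
report = pa.run_pipeline(cfg)
print(report["group_sizes"], round(report["cutoff"], 3), report["loocv_accuracy"])
```

prints

```
{'SNAP': 9, 'AD_CONTINUUM': 7, 'BN': 7} 1.648 1.0
```

— the pipeline simulated 23 subjects (7 AD-continuum-like, 10 SNAP-like, 6
biomarker-negative-like), derived a global-PIB amyloid cutoff of 1.648 by
ROC/Youden (leave-one-out accuracy 1.0) and recovered the group structure
up to one FDG false negative (a SNAP subject whose marginal hypometabolism
did not survive Bonferroni correction — the conservative direction).
`run/atlas_comparison.tsv` then holds the meta-VOI comparison; the
AD-continuum-vs-BN rows from the run above:

```
                voi  median_AD  iqr_AD  median_BN  iqr_BN  delta  p_adjusted
           temporal      1.109   0.027      0.938   0.017  1.000       0.002
            frontal      1.073   0.014      0.881   0.095  1.000       0.002
posterior_cingulate      1.165   0.078      1.033   0.067  0.796       0.033
             global      1.101   0.020      0.936   0.034  1.000       0.002
```

i.e. complete or near-complete effect-size separation of tau uptake
between the amyloid-positive and biomarker-negative groups, with medians
close to the injected ground truth (e.g. temporal 1.11 vs 0.95). The
voxel-wise contrast writes a t-map NIfTI and a cluster table
(`cluster_comparison.tsv`) with cluster extent, peak t, permutation-
corrected p and per-group median (IQR) plus delta.

The same stages are scriptable from the shell:

```bash
petatn run-all --output-dir run --seed 1
petatn validate --config my_config.yaml
```

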