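# modparc

Signed-modularity parcellation of small brain regions of interest from
resting-state fMRI, with seed-based partial-correlation connectivity
mapping, test-retest reliability statistics, and task-GLM integration —
exercised end to end on synthetic phantoms with known ground truth.

## The problem

Small subcortical structures such as the amygdala are composed of
functionally distinct subnuclei that conventional fMRI analyses treat as
one blob.  A data-driven way to recover the subdivisions is to treat
every ROI voxel as a node of a fully connected signed weighted graph `M`
(edge weights = Pearson correlations of voxel time series, averaged
across subjects and runs, diagonal removed) and to find the community
affiliation vector `C` that maximizes the signed modularity

```
Q* = (1/v+) Σᵢⱼ (w⁺ᵢⱼ − s⁺ᵢ s⁺ⱼ / v⁺) δ(cᵢ, cⱼ)
   − (1/(v⁺+v⁻)) Σᵢⱼ (w⁻ᵢⱼ − s⁻ᵢ s⁻ⱼ / v⁻) δ(cᵢ, cⱼ)
```

where `w± = max(±w, 0)` are the positive/negative weight layers, `s±`
node strengths and `v±` layer totals.  Optimization is a signed-weighted
Louvain algorithm wrapped in a restart protocol: blocks of 100
independent runs, each block's maximum Q rounded to 4 decimals, stopping
when two consecutive blocks agree, followed by single-node border
fine-tuning under the same rule.  The resulting modules are used as
seeds for partial-correlation functional connectivity maps (each seed's
mean signal vs. every brain voxel, with the other seeds' mean signals
regressed out of both sides), Fisher r-to-z transformed, averaged across
runs, and carried into group statistics: one-sample t and seed-contrast
maps with Monte-Carlo cluster-extent correction, a session × seed
repeated-measures ANOVA over four subseries, ICC(3,1) reliability, and a
block-design task GLM in percent-signal-change units whose ROI betas are
correlated with connectivity strength across subjects.

The package is for methods developers and imaging scientists who want a
tested, seed-reproducible reference implementation of this pipeline, and
a phantom test-bed that scores every stage against planted ground truth.
See `docs/methods.md` for the full model description and the phantom's
scope.

## Worked example

Run the demo pipeline (6-subject phantom, ~1 minute) from Python:

```python
from modparc import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_out", seed=3, n_subjects=6)
manifest = run_pipeline(cfg)
print([s["name"] for s in manifest["stages"]])
print(manifest["stages"][3])
print(manifest["validation"])
```

which prints

```
['simulate', 'preprocess', 'graph', 'parcellate', 'fcmap', 'stats', 'task']
{'name': 'parcellate', 'n_modules': 3, 'q': 0.380369}
{'ari': 1.0, 'n_modules_recovered': 3, 'n_modules_true': 3,
 'module_count_match': True, 'target_detection_rate': 0.666...,
 'task_beta_rmse': 0.00335...}
```

Reading: the pipeline preprocessed 6 subjects × 2 runs of phantom data
(drop 4 volumes, 0.01–0.10 Hz band-pass, motion + WM/CSF-PC regression,
4 mm smoothing, FD/DVARS censoring), built the 200-voxel signed
correlation graph, and the max-Q protocol found exactly the 3 planted
communities (adjusted Rand index 1.0) with signed modularity Q ≈ 0.38.
Task betas were recovered to ~0.003 percent-signal-change RMS error; at
this small n, 2 of 3 planted connectivity targets survived cluster
correction (all 3 survive at the 12-subject scale used in the tests).
`demo_out/` contains the labeled parcellation (`labels.nii.gz`), the
protocol trace, the per-module volume table (`modules.tsv`), per-seed
cluster tables, and `manifest.json` with seeds and per-stage provenance.

The same pipeline is scriptable from the shell:

```
modparc run-all --seed 3 --n-subjects 6 --out demo_out
modparc parcellate --graph demo_out/graph_M --block-size 100 --seed 3 \
    --out labels.nii.gz --trace trace.json --table modules.tsv
modparc validate --labels labels.nii.gz --truth ground_truth.json
```

Real acquisitions preprocessed to NIfTI + 6-column motion text can enter
at any stage (`modparc preprocess`, `modparc graph`, `modparc fcmap`).

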