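# sock

Automated artifact classification of spatial-ICA components from
resting-state fMRI.

Spatial independent component analysis (e.g. FSL MELODIC) decomposes an
fMRI run into components (ICs), each a 3D spatial map with a time course.
Many ICs are dominated by artifact — head motion, cardiac/respiratory
noise, scanner noise — and are routinely removed by hand, which is slow
and subjective. `sock` labels each IC **Artifact** or
**UnlikelyArtifact** automatically, using no training data and no task
timing: all thresholds adapt to the decomposition at hand or are fixed
anatomically/physiologically motivated constants.

## Features and decision rules

For each IC *i* four features are computed:

* **Smoothness ratio curve** — with *Fⁱ* the 3D DFT of the unthresholded
  map (frequencies in cycles/mm, so voxel anisotropy is respected),

  *Rⁱ(r) = Lⁱ(r) / Hⁱ(r)*,

  where *Lⁱ(r)* sums |*Fⁱ*| strictly inside the sphere of spectral radius
  *r* and *Hⁱ(r)* sums the rest. Smooth (plausibly neuronal) maps give
  uniformly high curves; "spotty" noise gives low ones. A nested
  two-stage 2-means on the curves yields *Smooth / Subsmooth / Unsmooth*
  labels.
* **Edge activity** — *EAⁱ = Σₖ OEₖ / Eᵥ*: the full volume of every
  contiguous suprathreshold cluster touching the brain-edge mask, over
  the mask volume *Eᵥ*. Motion artifact concentrates at the brain
  boundary. A scalar 2-means yields *High/Low* labels.
* **CSF activity** — *CAⁱ = Σₖ OCₖ / CSFᵥ*, the same construction
  against a lateral-ventricle mask; physiological noise concentrates
  there. *High* when *CAⁱ* ≥ 10% (fixed threshold, no clustering).
* **Temporal frequency noise** — *TFNⁱ* = Σ of the component's power
  spectrum from 0.08 Hz (the dominant hemodynamic-response frequency) to
  Nyquist 1/(2·TR). A scalar 2-means yields *High/Low*.

An IC is **Artifact** iff any rule fires:

| rule | condition |
|------|-----------|
| R1 | Unsmooth |
| R2 | Subsmooth **and** High TFN |
| R3 | Smooth **and** High edge activity **and** High CSF activity |
| R4 | ≥ 50% of suprathreshold volume inside the edge mask |
| R5 | ≥ 30% of suprathreshold volume inside the CSF mask |

Every verdict carries the list of rules that fired.

## Worked example

Generate a 15-component synthetic phantom (three components each of five
classes: neuronal-like, spotty noise, edge/motion, CSF/physiological, and
smooth-but-high-frequency) and classify it:

```sh
$ sock phantom --out ph --seed 9
wrote 15-component phantom to ph

$ sock classify --melodic-dir ph --edge-mask ph/edge_mask.nii.gz \
    --csf-mask ph/csf_mask.nii.gz --tr 2.0 --seed 9 --out results
12 Artifact / 3 UnlikelyArtifact of 15 components
```

`results/sock_report.tsv` has one row per IC:

```
component  smoothness  edge_activity  edge_label  edge_fraction  csf_activity  csf_label  csf_fraction  tfn           tfn_label  verdict           triggered_rules
1          Smooth      0.0222392638   Low         0.03558718861  0             Low        0             1.120608e-27  Low        UnlikelyArtifact
```

and `results/sock_report_summary.json` counts verdicts and rule firings —
here the three neuronal-like components survive, and each artifact class
is caught by its intended rule (3 × R1, 3 × R2, 3 × R4, 3 × R5):

```json
{
  "artifact": 12,
  "n_components": 15,
  "rule_counts": {
    "R1_unsmooth": 3,
    "R2_subsmooth_highTFN": 3,
    "R3_smooth_edge_csf": 0,
    "R4_edge50": 3,
    "R5_csf30": 3
  },
  "unlikely_artifact": 3
}
```

The same pipeline runs on real MELODIC output directories
(`melodic_IC.nii.gz`, `stats/thresh_zstat*.nii.gz`, `melodic_mix`,
`melodic_FTmix`) given user-supplied edge and CSF masks; `sock.masks`
provides a morphological fallback to derive both from a brain mask.

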