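# seegwm — white-matter tract sampling analysis for SEEG implantations

Stereo-electroencephalography (SEEG) implants multi-contact depth electrodes
to localize the epileptogenic zone in drug-resistant epilepsy. The electrodes
are aimed at gray matter, but on their way to deep targets they traverse
white-matter pathways — which makes every implantation an (unplanned)
white-matter sampling experiment, and a potential platform for direct
white-matter stimulation mapping. `seegwm` quantifies that sampling: given
electrode positions in a common analysis space, a labelled tissue atlas and a
set of probabilistic tract atlases, it reports which tissue compartment each
contact sits in, which tracts each contact crosses, and how reliably each
tract is sampled across a cohort.

The package is aimed at epilepsy-surgery and white-matter-mapping researchers
who have contact coordinates (from any localization pipeline) and want
reproducible, scriptable sampling statistics — plus a synthetic phantom
generator with analytic ground truth so the whole pipeline can be validated
without clinical data.

## The method

1. **Contact reconstruction.** Each electrode is a manufacturer geometry
   (contact count and center-to-center pitches g₁…gₙ₋₁) plus a trajectory:
   the deepest contact center **t** and a unit direction **d** toward the
   entry. Contact k sits at **t** + **d**·Σᵢ₍ᵢ₌₁₎^(k−1) gᵢ. Explicit
   per-contact coordinates are accepted as an alternative input.
2. **Contact window.** Each contact is represented on the 1 mm atlas grid by
   a 2×2×1-voxel window centred on its continuous voxel coordinate (the two
   bracketing voxels per in-plane axis, the nearest plane on the third),
   matching the physical contact footprint.
3. **Tissue class.** Against a Harvard-Oxford-style parcellation split into
   GM and WM label sets, a window touching only GM is *gray matter*, only WM
   *white matter*, both *gray–white boundary*, neither *CSF*
   (extra-parenchymal).
4. **Tract crossing.** A probabilistic tract atlas stores per voxel the
   fraction p ∈ [0, 1] of a reference cohort whose tract occupies that voxel.
   A contact's crossing probability is max p over its window, and a tract
   counts as crossed at chance level or above, p ≥ 0.5 (threshold,
   comparison mode and mean aggregation are configurable).
5. **Cohort statistics.** Per-patient tissue and per-tract contact counts
   aggregate into cohort tables: mean ± SD contacts per patient and tract,
   the percentage of patients with ≥ 1 contact in each tract (the probability
   that a prospective implantation samples the tract), hemispheric splits,
   and multi-tract overlap censuses with or without commissural fibers.
6. **Stimulation planning.** For a chosen tract, contacts overlapping it plus
   their same-electrode neighbours are listed with distances to the tract —
   the candidate montage for stimulation-mapping protocols.

## Worked example

Published-style count arithmetic (the aggregation layer works directly from
counts, e.g. when checking a printed table):

```python
>>> from seegwm.tissue import census_from_counts
>>> census = census_from_counts(gm=1473, boundary=2554, wm=1826, csf=519)
>>> print(census.to_frame().to_string(index=False))
           class    n   pct
              GM 1473 25.17
  GM_WM_BOUNDARY 2554 43.64
              WM 1826 31.20
             CSF  519  8.15
intraparenchymal 5853 91.85
```

Of 6372 contacts, 5853 (91.85%, ≈ 92%) are intraparenchymal; among those,
25.17% sit in gray matter, 43.64% at the gray–white boundary and 31.20% in
white matter — per-class shares use intraparenchymal contacts as the
denominator, the intraparenchymal share uses all contacts.

End-to-end on a synthetic phantom from the shell:

```console
$ seegwm simulate --out demo --patients 5 --seed 7
simulated 5 patients, 45 electrodes, 307 contacts -> demo
demo/run.yaml
$ seegwm -v run --config demo/run.yaml
INFO seegwm: load: 45 electrodes, 3 tracts
INFO seegwm: mask: 307 contact windows
INFO seegwm: classify: 292 intraparenchymal of 307
INFO seegwm: cross: 11 crossed of 921 (contact, tract) pairs
INFO seegwm: report: wrote 6 artifacts to demo/results
```

`simulate` writes a 128³ phantom (tissue atlas + three tube-tract atlases as
NIfTI), the electrode trajectory TSV, the tract manifest, analytic
ground-truth tables and a ready `run.yaml`. `run` produces `contacts.csv`,
`tissue_census.csv`, `crossings.csv`, `cohort_tract_table.csv`, `overlap.csv`
and a provenance `manifest.json`. Here 292 of 307 simulated contacts are
intraparenchymal (the phantom's thin gray shell makes white matter dominate),
and 11 (contact, tract) pairs cross a tract at the p ≥ 0.5 rule — every one
of them agreeing with the phantom's closed-form distance oracle.
`seegwm report` rebuilds the summary tables from cached outputs and
`seegwm plan-stim --tract <name>` emits the stimulation candidate list.

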