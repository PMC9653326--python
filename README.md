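# disconnectome

Decode group-level task-fMRI activation maps with stroke-derived
white-matter disconnection components.

## The problem

A group activation map tells you *where* the cortex responds to a task;
it does not tell you *which white-matter circuitry* feeds those regions,
nor what damage would disrupt the function. Lesion-network ("disconnectome")
decoding bridges that gap: the disconnection probability maps of a large
stroke cohort are compressed into a principal-component basis, and a
group activation map is then expressed as a linear combination of those
components. The component loadings localise the critical white matter,
and correlating each individual patient's disconnection profile with
the activation profile identifies the *typical lesion* — the damage
pattern most likely to disrupt the decoded network.

This package implements that pipeline end to end for researchers in
lesion-symptom mapping and network neuroscience, together with a
synthetic-brain generator, so that every stage is testable against known
ground truth without access to patient data.

## The method

Given per-patient binary lesion masks and a tract probability atlas, a
lesion's **disconnection map** assigns each voxel the probability that
its white matter is disconnected (max over the tracts the lesion hits).
The stages are:

1. **Components** — PCA of the patients × voxels disconnection matrix
   (voxelwise mean removed, no variance scaling). The retained number K
   is the smallest with cumulative explained variance > 99%.
2. **Group t-map** — voxelwise one-sample t = m̄/(s/√n) across the n
   subject contrast maps, thresholded at the Bonferroni-corrected
   one-sided level p < α/n_voxels, keeping positive t only.
3. **Decoding** — OLS of the activation's atlas region profile on the K
   component region profiles; loadings are standardized coefficients
   β*ₖ = βₖ·σ(xₖ)/σ(y), with R² the variance explained.
4. **Voxel mapping** — at each voxel, the K component values are
   regressed on the K loadings; the slope t-map (df = K−2) is corrected
   family-wise by the max-|t| permutation null obtained by permuting the
   loading vector's entries (exact enumeration when K! is small).
   Replication between independent component sets is the Pearson r of
   the two unthresholded t-maps.
5. **Typical lesion** — Pearson correlation of each patient's
   disconnection region profile with the activation profile; "pure
   lesions" are patients with r > 0.5 (large effect), and the top
   patient's mask is exported as the typical lesion.

## Worked example

```python
import numpy as np
import disconnectome as dc

grid = dc.make_grid(24)
tracts = dc.simulate_tracts(grid, n_tracts=8, seed=1)
lesions = dc.simulate_lesions(grid, n_patients=200, seed=2)
disc = dc.batch_disconnect(lesions, tracts)
comps = dc.fit_components(disc, variance_threshold=0.99)
print(f"{comps.n_components} components explain "
      f"{100 * comps.cum_var[-1]:.1f}% of the disconnection variance")

atlas = dc.simulate_atlas(grid, n_regions=120, seed=3)

# group fMRI sample whose true activation is carried by one tract
reading_tract = tracts.tracts[0]
subjects = dc.simulate_subject_maps_from_field(
    grid.with_data(5.0 * reading_tract.data), n_subjects=48,
    noise_sd=0.5, seed=4)

tmap = dc.group_tmap(subjects)
activation = dc.threshold_bonferroni(tmap)
print(f"{int((activation.data != 0).sum())} of {tmap.n_mask_voxels} "
      f"voxels survive Bonferroni")

fmri = dc.region_profile(activation, atlas, "fmri")
profiles = [dc.region_profile(m, atlas) for m in comps.maps]
loadings = dc.decode_profile(fmri, profiles)
print(f"components explain {100 * loadings.r_squared:.1f}% "
      f"of the activation profile")

result = dc.permutation_fwe(comps.maps, loadings, n_perm=499, seed=6)
n_sig = int(result.sig_mask.data.sum())
on_tract = int((result.sig_mask.data * (reading_tract.data > 0.5)).sum())
print(f"{n_sig} white-matter voxels significant at FWE alpha=0.05, "
      f"{on_tract} on the generating tract's core")

disc_profiles = [dc.region_profile(d.probmap, atlas, d.patient_id)
                 for d in disc]
report = dc.pure_lesion_analysis(disc_profiles, fmri,
                                 patient_ids=[d.patient_id for d in disc],
                                 lesions=lesions)
print(f"pure lesions (r > 0.5): {report.pure_fraction:.2f}% of cohort; "
      f"typical lesion {report.top_patient.patient_id} "
      f"explains {100 * report.top_patient.r_squared:.1f}% "
      f"of the activation profile")
```

prints

```
10 components explain 99.0% of the disconnection variance
1409 of 13824 voxels survive Bonferroni
components explain 99.8% of the activation profile
137 white-matter voxels significant at FWE alpha=0.05, 46 on the generating tract's core
pure lesions (r > 0.5): 30.17% of cohort; typical lesion P0025 explains 99.8% of the activation profile
```

The significant white matter concentrates on the tract that generated
the activation (46 of its core voxels), no voxel outside the tract
system is flagged, and the typical lesion is the patient whose
disconnection best mirrors the activation pattern. The pure-lesion rate
is far higher than in a real stroke population because the synthetic
cohort has only eight tracts to hit.

The same pipeline is available from the shell:

```bash
disconnectome simulate --out study --seed 1
disconnectome disconnect --tracts study/tracts --lesions study/lesions --out disc
disconnectome components --disconnect disc --out comp \
    --atlas study/atlas.nii.gz --atlas-names study/atlas.tsv
disconnectome group-tmap --subjects study/subjects --out tmap
disconnectome profile --map tmap/tmap_thresholded.nii.gz \
    --atlas study/atlas.nii.gz --atlas-names study/atlas.tsv \
    --out fmri_profile.tsv
disconnectome decode --fmri-profile fmri_profile.tsv \
    --component-profiles comp/component_profiles.tsv --out loadings.tsv
disconnectome voxmap --components comp/components.nii.gz \
    --loadings loadings.tsv --out voxmap
disconnectome typical-lesion --disconnect disc --lesions study/lesions \
    --fmri-profile fmri_profile.tsv --atlas study/atlas.nii.gz \
    --atlas-names study/atlas.tsv --out typical
```

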