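# phasevasc

Simulation and quantification chain for **propagation-based (in-line) X-ray
phase-contrast CT of tumor neovascularization**. The package reproduces, as
tested reusable code, the workflow used to characterize microvasculature in
unstained liver-tumor specimens at a synchrotron imaging beamline: a synthetic
specimen generator stands in for the animal samples, a Fresnel near-field
forward model produces edge-enhanced projections, filtered back projection
reconstructs them, and threshold-based 3D analysis extracts vascular density,
vessel calibers and their week-by-week trajectory during tumor growth.

## Who this is for

Researchers developing or validating phase-contrast CT analysis — segmentation
thresholds, contrast metrics, artifact handling — who need ground-truth-known
specimens, and anyone who wants a compact, fully scripted model of why
object-to-detector distance, beam energy, ring artifacts and suture inclusions
matter for vessel quantification.

## The model in brief

A monochromatic plane wave (energy 8–72.5 keV) crosses the specimen under the
projection approximation, accumulating a phase shift from the refractive-index
decrement δ and attenuation from the absorption index β
(n = 1 − δ + iβ). Free-space propagation over the object-to-detector
distance *z* is applied in Fourier space with the paraxial Fresnel transfer
function H(f) = exp(−iπλz|f|²); the detected intensity |w|² shows the
bright/dark fringe pair at every interface that makes unstained vessels
visible. At z = 0 the model reduces exactly to conventional absorption
imaging. Slices are reconstructed with parallel-beam FBP (Ram-Lak default)
directly from the edge-enhanced intensity, without phase retrieval — exactly
as beamline slice-reconstruction software does.

Two contrast statistics quantify the images:

- **edge contrast** across a vessel wall, C = (I_max − I_min)/(I_max + I_min),
  read from a line profile crossing the wall;
- an **overlapping local-contrast map**, the windowed coefficient of variation
  C(x,y) = sqrt(⟨I²⟩_W − ⟨I⟩_W²)/⟨I⟩_W.

3D quantification extracts vessels by thresholding inside a tumor outline,
then reports tumor volume, vascular volume, vascular density
(= 100 · vascular/tumor volume), the smallest vessel diameter (medial-axis
local thickness, per-component median), and a caliber histogram. A
week-series driver aggregates replicates (mean ± SD per week) and fits
ordinary-least-squares trends of each metric on week.

## Worked example

`examples/04_quantify_specimen.py` pushes one week-2 specimen (96³ voxels at
9 µm) through the whole chain — simulate 400 noisy projections at 15 keV and
1 m, reconstruct, segment, measure:

```
metric                      recovered ground truth
tumor volume (mm^3)            0.0969       0.0969
vascular volume (mm^3)        0.00377      0.00416
vascular density (%)            3.890        4.292
min vessel diameter (um)          9.0         18.0

density recovery error: -9.3 % relative
```

The tumor volume matches exactly (the outline is given, as in the manual
workflow); the density is recovered to within ten percent from the noisy,
fringe-dominated reconstruction; the thinnest extracted structure sits at the
single-voxel resolution floor.

`examples/02_edge_enhancement_sweep.py` shows why the beamline operates at
1 m rather than in contact, and why softer beams give more contrast:

```
edge contrast C across the vessel wall
energy       0.05 m     1.0 m     3.0 m
  12 keV    0.0694    0.5118    0.7911
  15 keV    0.0419    0.3824    0.6943
  20 keV    0.0165    0.2406    0.5551
```

The other examples cover phantom construction (`01`), ring artifacts and the
threshold confound (`03`), the staged four-week pipeline with CSV outputs
(`05`), and transmittance-threshold suture correction (`06`). A thin CLI
(`phasevasc simulate|reconstruct|contrast|quantify|report|run-all`) wraps the
same library calls for shell use.

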