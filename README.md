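# strainpet

Regional lung-strain and macrophage-PET mapping for paired-inflation
CT / PET studies of ventilator-induced lung injury (VILI), with
iso-gravitational profile statistics and cross-modal mutual information.

Mechanically ventilated lungs deform inhomogeneously: strain concentrates
in the gravitationally dependent (dorsal, in supine position) regions,
where atelectasis collects — and so do activated pro-inflammatory
macrophages, visible with somatostatin-receptor PET tracers. `strainpet`
turns co-registered volumetric images into the quantities that describe
this topography:

* **CT aeration** — per-voxel gas and nongaseous content from Hounsfield
  units: `V_vox,gas = V_vox · (−HU/1000)`;
* **Field of strain** — the voxel-associated normal strain between a
  reference (ZEEP/FRC) and an inflated state,
  `VoStrain = (1/3)(V₁ − V_FRC)/V_FRC`, with a 0.01%-of-voxel-volume gas
  floor over atelectatic voxels;
* **SUVR** — voxel activity divided by the mean concentration of a
  blood-pool (left-ventricle) reference ROI;
* **Iso-gravitational profiles** — 100-layer ventral→dorsal summaries of
  any map, their central-quartile (layers 25–75) OLS regressions, and the
  F / Z / Wilcoxon machinery to compare conditions;
* **Linear mutual information** — the Gaussian-approximation mutual
  information between the strain and SUVR maps, normalized to [0, 1] via
  `lmi = √(1 − e^(−2I))` (equal to |Pearson r| for scalar intensities);
* **Synthetic phantoms** — supine-lung phantoms with a gravitational
  aeration gradient, dependent atelectasis, paired inflation, a
  strain-coupled PET signal and tunable noise, so the full pipeline is
  testable without animal data.

It is primarily a Python library (see `examples/`), with a thin
`strainpet` CLI (`phantom | aeration | strain | suvr | profiles | lmi |
run`) for shell use. Volumes are NIfTI (via nibabel); tables are CSV;
reports are JSON.

## Worked example

The demo study pushes a 7-vs-3 phantom cohort (injured vs healthy-like)
through every stage at two transverse levels:

```sh
python examples/06_full_study.py
```

prints (abridged):

```
para_diaphragmatic:
  VoStrain slice mean: injured 104.4 vs healthy 0.33 (rank-sum p = 0.0167)
  SUVR slice mean:     injured 0.92 vs healthy 0.52 (rank-sum p = 0.0167)
  vostrain gravitational regression lines differ: F = 4320.7, p = 5.31e-87
  suvr gravitational regression lines differ: F = 57089.3, p = 4.93e-135
  SUVR vs nongaseous slope: Z = 56.3, p = 0

LMI (strain vs SUVR): injured 0.653 ± 0.013, healthy 0.035 ± 0.016,
rank-sum p = 5.2e-05
```

Reading the numbers: injured phantoms carry a far higher slice-mean
VoStrain (the mean is dominated by floored strains over the deep dorsal
atelectasis) and a higher SUVR; their strain and SUVR rise toward the
dependent lung along statistically different regression lines; SUVR
grows faster per unit of nongaseous tissue (so tracer uptake is not just
passively carried by blood/tissue volume); and the two modalities share
much more linear information when the strain–macrophage coupling is
strong. The same orderings — not the same magnitudes — are what the
corresponding in-vivo analysis reports.

The other examples are single-capability walkthroughs: phantom anatomy
(`01`), aeration + strain (`02`), SUVR (`03`), profiles and the F test
(`04`), LMI vs coupling strength (`05`).

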