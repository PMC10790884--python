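# occupet

`occupet` is a Python pipeline for quantifying neuroreceptor occupancy from
baseline/blocking dynamic PET studies, with regions of interest derived from
resting-state fMRI. It was built around the design of a 5-HT2A receptor
occupancy study (a selective inverse-agonist radioligand, a cerebellum
reference region, and a psychoactive drug as the blocking agent), but the
stages are generic:

1. **Parcellation** — spatially constrained spectral clustering
   (normalized-cut) of the across-subject, Fisher-z-averaged voxel
   correlation graph from preprocessed rs-fMRI, giving K functionally
   homogeneous ROIs (K = 200 in the study design).
2. **TAC extraction** — per-ROI time-activity curves from 4D dynamic PET as
   unweighted voxel means, plus the reference-region TAC.
3. **Kinetic modeling** — the simplified reference tissue model (SRTM),

       C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a·t)](t),
       k2 = R1·k2REF,  k2a = k2/(1 + BP_ND),

   fitted simultaneously to all ROI TACs of a scan with one shared
   ("coupled") reference efflux rate k2REF, yielding per-ROI R1 and BP_ND.
4. **Occupancy** — percent occupancy per ROI,

       Occ(%) = 100·(BP_ND^baseline − BP_ND^blocking) / BP_ND^baseline,

   with discard rules (baseline BP_ND < 0.2, DVR < 1.2, occupancy outside
   [0, 100]%) and refitting of the remaining ROIs until stable.
5. **Summary** — study-level statistics over per-ROI mean baseline BP_ND and
   occupancy, including a top-k ranking.

A synthetic-data module generates every input with known ground truth
(reference curves, TACs, baseline/blocking pairs with a planted occupancy
field, 4D phantoms, and rs-fMRI with planted parcel structure), so the whole
pipeline is testable without any scan data. The package also ships a
transcription of the study's published per-ROI table (137 ROIs × 4 subjects,
baseline BP_ND and occupancy) as a validation fixture.

## Worked example

Summarize the packaged per-ROI table:

```sh
$ occupet summarize --fixture table1 --top 7
n_retained      : 137
mean BP_ND      : 1.44 (SD 0.33)
mean occupancy  : 39.5% (SD 10.9%)
occupancy range : 19.84 - 74.72%
top ROIs by mean occupancy:
  l angular gyrus                   74.72%
  l intraparietal sulcus            70.97%
  r angular gyrus                   70.48%
  superior parietal gyrus           68.51%
  l precentral gyrus                68.39%
  r intraparietal sulcus            65.93%
  sgACC                             63.12%
```

Mean baseline binding potential across the 137 retained ROIs is 1.44 (about
1.4 available-receptor units relative to the reference region), mean
occupancy by the blocking drug is 39.5%, and the regions with the greatest
occupancy (63–75%) include the bilateral angular gyri, bilateral
intraparietal sulci and subgenual anterior cingulate.

The same stages run on synthetic data with known truth:

```sh
$ occupet simulate study --seed 1 --n-rois 6 --noise-cv 0.03 --out study
$ occupet fit-srtm --tacs study/tacs_baseline.tsv --reference-row reference \
      --frames frames.yaml --out fit_base.tsv
fitted 6 ROIs, shared k2REF = 0.1460 /min -> fit_base.tsv
$ occupet fit-srtm --tacs study/tacs_blocking.tsv --reference-row reference \
      --frames frames.yaml --out fit_block.tsv
$ occupet occupancy --baseline fit_base.tsv --blocking fit_block.tsv --out occ.tsv
6 retained, 0 discarded -> occ.tsv
```

Here `frames.yaml` holds the 30-frame schedule
(`framing: [[4, 15], [4, 30], [3, 60], [2, 120], [5, 240], [12, 300]]`,
90 min total). The fitted shared k2REF of 0.1460 /min recovers the
generator's 0.14 /min to within the noise; `study/ledger.tsv` holds the
planted per-ROI truth for comparison. The same flow works from images:
`occupet parcellate` builds a label volume from rs-fMRI NIfTIs and
`occupet extract-tacs` produces the TAC table from a 4D PET NIfTI.

From Python, the equivalent calls are `simulate_study`, `fit_srtm_coupled`,
`filter_refit_loop` and `summarize` (see docstrings).

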