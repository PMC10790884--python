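# Methods

## The model

The simplified reference tissue model (SRTM) describes a target region's
tracer concentration C_T(t) in terms of a reference region essentially
devoid of the target receptor (here, cerebellum). With R1 the
target/reference delivery ratio, k2REF the reference efflux rate and BP_ND
the non-displaceable binding potential, the one-tissue reduction gives

    dC_T/dt = R1·dC_R/dt + k2·C_R − k2a·C_T,
    k2 = R1·k2REF,  k2a = k2/(1 + BP_ND),

whose solution is the convolution form implemented in `srtm_forward`:

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·∫₀ᵗ C_R(s)·e^(−k2a(t−s)) ds.

DVR = BP_ND + 1. Occupancy compares BP_ND between a baseline scan and a
scan after the blocking drug: Occ(%) = 100·(BP_base − BP_block)/BP_base,
interpreted as the fraction of receptors occupied by the drug.

Assumptions inherited from SRTM: the reference region is receptor-free and
shares the non-displaceable distribution volume with the targets; target
kinetics are well approximated by one tissue compartment; TACs are decay
corrected; scans are motion-corrected and co-registered upstream. Nothing in
the package corrects for partial volume.

## Numerical treatment

* **Time axis.** Seconds internally everywhere; rate constants cross the API
  in per-minute units (the PET convention), converted in exactly one place.
* **Convolution.** The forward model is evaluated on a uniform fine grid
  (default 1 s) with a recursion that is exact for the trapezoid rule:
  y[i] = a·y[i−1] + Δt/2·(f[i] + a·f[i−1]), a = e^(−k2a·Δt). This is O(n),
  stable for any k2a·t (no positive exponentials), and agnostic to the
  reference shape. A grid-refinement test (10× finer) bounds the
  discretization error below 0.01% on frame averages, and an independent ODE
  integration of the SRTM system agrees within 0.1% at all frame midpoints.
* **Frame averaging.** PET frames measure interval-averaged activity, so
  model curves are integrated over each frame (trapezoid on the fine grid)
  rather than sampled at midpoints; exact for piecewise-linear curves.
* **Dense reference reconstruction.** The measured reference TAC consists of
  frame averages. Plain midpoint interpolation of those values biases the
  convolution wherever the curve bends; the reconstruction therefore refines
  the midpoint knot values by fixed-point iteration (8 sweeps) until the
  interpolant's own frame averages reproduce the measured values, anchored
  at C_R(0) = 0.
* **Coupled fitting.** The joint objective Σ_ROI Σ_f w_f·(TAC − model)² over
  {R1_i, BP_i} and one shared k2REF is solved by nested profiling: a bounded
  scalar minimization over k2REF ∈ [0.01, 1.0] /min (tolerance 1e−6); inside
  it, each ROI's 2-parameter weighted NLLS, itself profiled over k2a with a
  closed-form weighted linear solve for R1 (the model is linear in R1 given
  k2a and k2REF). Bounds R1 ∈ (0.1, 3), BP_ND ∈ (−0.5, 10) define the k2a
  search interval; R1 is clipped to its bounds. The scheme is deterministic,
  its profile structure matches the coupling contract exactly, and on
  noiseless data it recovers parameters to ~1e−5 relative. Negative fitted
  BP_ND is reported as-is; the filter stage handles it.
* **Weights.** Default `duration` scheme: w_f = duration_f / max duration.
  Longer frames accumulate more counts, so their measured concentration has
  lower variance; with the generator's noise model (below) these weights are
  inverse-variance optimal. `uniform` is available.
* **Filters.** Strict inequalities exactly as stated (BP < 0.2, DVR < 1.2,
  Occ < 0% or > 100%); boundary values are retained. The reason reported is
  the first failing rule in that order. DVR is derived as BP_ND + 1, which
  makes the BP and DVR rules coincide; both are kept as named rules for
  configurations where the thresholds are moved independently. Filters are
  evaluated on the scan pair being fitted; the refit loop drops discarded
  ROIs, refits both scans (each with its own coupled k2REF), and repeats
  until the retained set is stable (at most 5 passes).
* **Summary statistics.** Per-ROI means are taken over subjects first; the
  study mean and sample SD (n − 1) are computed over per-ROI means —
  "average across ROIs" — as are min/max and the top-k ranking. Rounding
  happens only at report time.

## Parcellation

Edges are restricted to 26-connected in-mask voxel neighbours and weighted
by Pearson correlation; edges below the threshold (default r = 0.5) are
dropped. A dense all-pairs correlation matrix over a full gray-matter mask
is computationally infeasible and the spatial constraint is what yields
contiguous parcels. Subject graphs are averaged in Fisher-z space
(correlations clipped to ±(1 − 1e−7)) and mapped back with tanh; negative
group weights are clipped to 0, as the normalized cut requires nonnegative
affinities. Clustering embeds the voxels with the leading K eigenvectors of
D^{−1/2} W D^{−1/2}, row-normalizes, and runs k-means with 10 seeded
restarts (lowest inertia wins). If thresholding disconnects the graph, K is
apportioned across components by size (largest remainder, at least 1 each)
and each component is clustered separately — with strongly separated
planted parcels this reduces to one label per component. Empty clusters
(k-means relocates centroids, so they are rare) are repaired by splitting
the largest cluster in the embedding.

## The synthetic generator

`simulate_study` draws per-ROI R1 ~ U(0.7, 1.3) and baseline BP_ND ~
U(0.2, 4) (typical cortical ranges for a high-affinity antagonist tracer),
shares R1 and k2REF = 0.14 /min across the scan pair, and derives blocking
BP from the planted occupancy field via BP_block = BP_base·(1 − Occ/100),
which holds exactly in the ledger. The reference curve is a gamma variate
A·t^α·e^(−t/β) (α = 1, β = 300 s), peaking at 5 min with >80% washout by
90 min, shaped like a cerebellum TAC. The default schedule is the 30-frame,
90-min protocol (4×15, 4×30, 3×60, 2×120, 5×240, 12×300 s).

Frame noise is zero-mean Gaussian with SD = cv·peak/√(duration_f/max
duration): variance inversely proportional to frame duration, a simple
proxy for count statistics that ignores decay, randoms and scatter. The
reference TAC's noise is scaled by an additional 1/√10 by default because
the cerebellum reference region is roughly an order of magnitude larger
than one of 200 parcels and its voxel-averaged TAC is correspondingly less
noisy. This matters: feeding the fit a reference as noisy as a single small
ROI produces the classic errors-in-variables bias of reference-tissue
models (several percent upward in BP_ND at 5% peak noise). The scale is a
parameter (`reference_noise_scale`), so the biased regime remains
reachable for study.

`simulate_rsfmri` gives each parcel's voxels a shared latent series mixed
as √b·g + √(w−b)·z_parcel + √(1−w)·ε, so the expected within-parcel
correlation is w and the between-parcel correlation is b. Defaults: 180
timepoints (a ~7.5-min run at TR ≈ 2.5 s), w = 0.8, b = 0. What the
generator does **not** emulate: autocorrelated BOLD noise, motion,
physiological confounds, spatially varying SNR, partial-volume mixing at
parcel borders, or PET resolution effects — so passing recovery tests show
correctness of the algorithms under clean, well-specified conditions, not
robustness to real acquisition artifacts.

## Problem sizes and determinism

Desk-scale defaults keep every stage fast: 8-ROI kinetic studies (a coupled
fit takes ~0.2 s), 50-replicate noise studies, 512-voxel parcellations at
K = 8, and a single 4096-voxel run at the study's K = 200. All stochastic
draws flow from explicit seeds (NumPy `default_rng`); fits are
deterministic by construction (nested bounded scalar minimization, no
random restarts outside seeded k-means).

## Known limitations

* The per-subject filter/refit is applied to the scan pair being analyzed;
  multi-subject retention reporting (a ROI retained only if retained in all
  subjects) is a thin aggregation left to the caller.
* The parcellation's permutation equivariance holds up to label renaming
  and is only guaranteed when the clustering solution is stable (well
  separated parcels); near-degenerate eigenvalue problems may break ties
  differently under reordering.
* SRTM itself biases BP_ND when target kinetics are distinctly
  two-compartment; no such data is generated here.
* The published per-ROI table retains one region ("l putamen", mean
  baseline BP 0.14) that the stated discard rules would remove; the fixture
  is shipped as printed and the loader does not force it through the
  filters.
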