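# Methods

This note records the models implemented in `emfit`, the conventions and
defaults chosen where several are in circulation, and the limits of what
the synthetic test bed can demonstrate.

## Simulated density

Each heavy atom contributes the kernel
`g_n(r) = exp(-(3 / 2 sigma^2) |r - r_n|^2)`; the value of voxel (i,j,k)
is the exact integral of `sum_n g_n` over the voxel volume. Because the
kernel is separable, the integral is a product of three 1-D
error-function differences, and its derivative with respect to an atom
coordinate is a difference of the kernel evaluated at the two opposing
voxel faces. We use the exact integral rather than center-point sampling
because the downstream bias energy needs a gradient that is consistent
with the energy to machine precision, and because at coarse grids
(voxel ≈ sigma/2) point sampling misallocates a few percent of mass.

Conventions that differ between packages, fixed here:

- **sigma is the stated map resolution, verbatim.** No `r/2` or
  FWHM-to-sigma conversion is applied. Users comparing against tools
  that use another convention must rescale sigma themselves.
- **Grid origin is the world coordinate of the center of voxel (0,0,0)**;
  voxel (i,j,k) spans `origin + (i-1/2 .. i+1/2) * spacing` per axis.
- Kernel contributions are truncated beyond `truncation_radius * sigma`
  (default 4 sigma, where the kernel has decayed to exp(-24) ≈ 4e-11);
  with the default margin the total simulated mass matches the
  closed form `N (2 pi sigma^2 / 3)^{3/2}` to well under 0.1%.
- Auto-generated grids use voxel size sigma/3 (the usual
  one-third-of-resolution sampling) and pad the model bounding box by
  the truncation radius.
- Experimental maps are used as-is: no low-pass filtering or
  normalization before CCC, which is scale-invariant anyway.

CCC is the non-centered form `sum(ab) / sqrt(sum(a^2) sum(b^2))`. The
centered (Pearson) form appears only in the CC validation metrics, where
the source definitions are centered.

## Rigid docking

Rotations are enumerated on a z-y-z Euler lattice (default step 20°;
polar rows keep a single gamma since alpha and gamma are degenerate
there). For each rotation the centered model is simulated on a grid with
the experimental spacing and the correlation *numerator* is computed for
every integer voxel shift by FFT. Peaks (greedy non-maximum suppression,
default minimum separation 2 voxels) are pooled over all rotations; the
top K (default 20) are rescored with the exact CCC, which removes the
approximation that `sum(rho_sim^2)` is shift-invariant. Finally the best
few placements (default 3) are polished off-lattice by Powell search
over a local rotation-vector and translation increment, directly
maximizing the exact CCC — the same lattice-then-refine strategy
classical FFT docking programs use. The input pose itself is always
scored as a candidate, so the returned best placement can never be worse
than the starting pose. The whole search is deterministic.

## Flexible fitting

Objective: `E = E_restraint + E_EM` with `E_EM = N k (1 - CCC)`.

The structural term is a Cα structure-based (Gō-like) potential built
from the *starting* pose:

- harmonic pseudo-bonds between consecutive Cα of each chain,
  `kb = 10` (reduced units), targets = initial lengths;
- flat-bottom harmonic contacts (`kc = 0.2`, half-width `delta = 0.5 Å`)
  between Cα pairs at least 3 residues apart (or on different chains)
  within `contact_cutoff = 8 Å` initially, targets = initial distances.

This realizes "maximize CCC without losing the starting structure's
residue–residue contacts" with a potential that is cheap, differentiable
and seedable. It is *not* an all-atom force field: side chains,
electrostatics and stereochemistry beyond the Cα trace are out of scope,
and fits of all-atom models should be finished with a dedicated
real-space refinement tool. `k` (default 1.0) is the single bias knob;
force-field-engine-specific weighting schemes of external MD codes are
deliberately not emulated.

Two optimizers:

- **gradient descent** (default): steepest descent with Armijo
  backtracking; the total energy is monotonically non-increasing by
  construction and the trajectory is fully deterministic. Line-search
  trials evaluate energies only; the exact gradient is computed once per
  accepted step from cached erf factors.
- **langevin**: BAOAB discretization, fixed timestep (default 0.02),
  friction 5, reduced temperature 0.1, seeded noise — bit-reproducible
  per seed. Useful to escape shallow local minima; not monotone.

Convergence: stop when the CCC changed by less than `1e-6` over the last
50 steps, or at `max_steps` (default 2000). Every step emits a record
(step, E_restraint, E_EM, CCC); `E_EM = N k (1 - CCC)` holds for each
record by construction.

## Map–model metrics

- **CCmask**: centered Pearson over voxels within `mask_radius`
  (default 3 Å) of any atom. The mask is a union of fixed-radius
  spheres, not per-element atomic radii — a documented simplification;
  with Cα-only models a per-element mask would be spurious precision.
- **CCvolume**: Pearson over the v highest-valued voxels of the *model*
  map, v = mask size (compares molecular envelopes).
- **CCpeaks**: Pearson over the union of the v highest voxels of model
  and experimental maps (strongest features of both).
- **CCbox**: Pearson over the whole grid; crop the map first for a local
  box measure.
- **SMOC**: per residue, non-centered Manders overlap over voxels within
  `radius` (default 3 Å) of the atoms of a `window`-residue segment
  (default 11, odd; chains shorter than the window use the whole chain).
  The centered/non-centered split between the CC metrics and SMOC is
  deliberate: each follows its source definition.

All five metrics equal 1 identically when the experimental map is the
model's own simulated map.

## Profiles, alignment, Z-scores

Profiles are L×20 log-odds matrices versus a uniform background. The
pseudocount (default 1) acts on relative frequencies,
`f_a = (count_a / n + pc) / (1 + 20 pc)`, so duplicated sequences do not
change a profile. Building profiles from external search pipelines is
out of scope — any aligned FASTA works.

The match score of two columns is their Pearson correlation, so any
column representation with per-column variance is usable. Alignment is
affine-gap Gotoh; a gap run of length g costs
`open + extend * (g - 1)` (defaults 1.0 / 0.1 on the correlation scale;
these are package defaults, not values inherited from any particular
tool). Two modes:

- **glocal** (default): the path must reach a sequence start on the left
  and a sequence end on the right; the overhang of the other sequence is
  free, everything in between is paid. This suits template detection
  where the query region should be covered.
- **local**: Smith–Waterman, the single best contiguous region.

Traceback ties break deterministically (match, then gap-in-template,
then gap-in-query). Raw scores are calibrated per library by
least-squares regression of S on `log(Lq * Lt)`; the Z-score is the
standardized residual (denominator n-2; a constant model with a warning
when all length products coincide). The Z-score is invariant under
affine rescaling of all library scores. Queries longer than a chosen
fragment length can be split into overlapping windows (last window
anchored at the sequence end, so coverage is complete).

## Candidate selection and assembly

Score tables are pandas DataFrames keyed by `model_id`; docking failures
are kept as flagged rows rather than dropped. Filters are explicit
`(column, comparator, threshold)` conjunctions — the practice of
selecting "models above CCC and secondary-structure-similarity and
quality-score thresholds" made mechanical; external quality scores are
pass-through columns, never recomputed here. Secondary structure for the
model side of the similarity filter is assigned geometrically from Cα
distances (helix: d(i,i+3) in 4.2–5.8 Å and d(i,i+4) in 4.9–6.9 Å;
strand: d(i,i+2) in 6.4–7.7 Å; else coil), in the spirit of P-SEA;
the prediction side is supplied by the user. Assembly applies the
placements, relabels chains uniquely (up to 62), and reports
inter-component Cα pairs closer than `clash_cutoff` (default 3 Å).

Map segmentation for per-subunit work is a zone (spheres around an
anchor model) or an index-box crop — a scriptable proxy for the manual
map splitting done interactively in visualization tools.

## Synthetic test bed

The fixture generator produces ideal Cα traces (3.8 Å spacing; helices
with 1.5 Å rise and 100° twist), four topologies (single helix,
asymmetric three-helix bundle, exact C2 dimer, two-domain hinge),
hinge/jitter/rigid perturbations, profile-sampled MSAs (uniform
substitution model), and white-Gaussian-noise maps. Everything is
deterministic per seed.

What this emulates: the geometry of docking and fitting problems at
sigma ≥ 4 Å, where side-chain detail is unresolved and a Cα trace
carries the signal. What it does not: real experimental maps (correlated
noise, B-factor falloff, masking artifacts, heterogeneity), real
sequence evolution (position-dependent substitution), or all-atom
stereochemistry. Passing tests therefore demonstrate correctness of the
algorithms and their implementations, not end-to-end accuracy on
experimental data.

Problem sizes used in the tests and the acceptance script (30–60 residue
fixtures, 16³ oracle grids, 30°–90° angular steps, a few hundred
minimizer steps) were chosen as the smallest sizes at which each
property is non-trivially exercised.

## Numerical and degenerate-input policy

- Rotation matrices are validated orthonormal with det +1 (tol 1e-8).
- Zero-variance profile columns, all-zero maps, constant map regions,
  coincident bonded atoms, and collinear superposition point sets raise
  typed errors instead of returning NaN.
- Translation-scan ties break by smallest shift norm, then
  lexicographically; alignment traceback ties by the fixed state order.
- TM-score uses the standard fragment-seeded iterative-Kabsch heuristic;
  it is exact for identical and rigidly moved structures (asserted in
  tests) and a lower bound otherwise. d0 follows the usual
  `1.24 (L-15)^{1/3} - 1.8` with L ≥ 16 required.
- PDB dialect: first altloc kept, hydrogens dropped on read (the density
  model counts heavy atoms), insertion codes ignored, HETATM kept but
  flagged; coordinates outside the fixed-column range (−999.999 to
  9999.999 Å) refuse to write.

## Known limitations

- The Cα potential cannot detect or repair side-chain clashes; the
  assembly clash report is Cα-distance-based only.
- The Euler-lattice rotation enumeration is denser near the poles;
  coverage (every rotation within `step * sqrt(3)` of a lattice point)
  is verified by test rather than by construction.
- SMOC windows clip at chain termini, so terminal residues are scored on
  asymmetric segments.
- `cc_volume`/`cc_peaks` regions are defined by voxel count equal to the
  mask size; when the grid is smaller than the mask the region clips
  with a warning.
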