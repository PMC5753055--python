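# Methods

## The model

Each residue's backbone is described by (φ, ψ, ω, χ1) in degrees, wrapped to
(−180°, +180°]. The conformational model is a per-residue two-component
mixture over ψ:

    ψᵢ ~ wᵦᵢ · N_wrap(μ_β, σ_β) + (1 − wᵦᵢ) · N_wrap(μ_α, σ_α)

with β centre μ_β = +140°, α centre μ_α = −30° (the centres of the two
Ramachandran ψ peaks for these peptides), and a single Gaussian for φ
centred at −135° (the midpoint of the extended −160°…−110° range). ω is
fixed trans (180°); χ1 defaults to a point mass at +60° (the gauche+
rotamer found dominant for the CF₃-threonines). Draws are independent
across frames and residues, so the ensemble factorises over residues and
the product rule P = ∏ p_β is exact for the generator, not an
approximation. Real trajectories have inter-residue coupling and temporal
autocorrelation; the generator deliberately has neither (see Limitations).

Wrapped-Gaussian sampling is a plain Gaussian draw wrapped into
(−180°, 180°]; for σ ≤ 60° the wrapped density is indistinguishable from
re-summing images to double precision, and the analytic window mass used as
ground truth (`mixture_window_mass`) sums ±5 images of the unwrapped CDF.

### Parameters that matter

| parameter | default | unit | why |
|---|---|---|---|
| wᵦ per residue | system-specific | – | the quantity under study; pipeline defaults use the tabulated per-residue β probabilities of the eight systems so synthetic runs echo the published contrast |
| σ_α, σ_β | 15 | deg | typical width of a single Ramachandran basin at room temperature; narrow enough that < 0.5 % of β mass leaks outside [90°, 180°] |
| φ centre / σ | −135 / 15 | deg | keeps φ inside the extended range that produces large ³J couplings |
| β window | [90°, 180°] | deg | stated β basin; closed on both ends, boundary counts inward |
| α window | [−70°, +40°] | deg | stated α region |
| Karplus (A, B, C, phase) | 6.51, −1.76, 1.60, −60° | Hz, deg | standard HN–Hα parameterisation; selectable in `config/karplus.yaml` because the original analysis does not state its set |
| coil ³J means | Ala 6.1, Leu 7.0, Val 7.5 | Hz | the coil-library reference values used for the extension comparison |
| temp.-coefficient thresholds | −4.5 / −6.0 | ppb/K | protected vs exposed amide; strict inequalities, exact boundary → "intermediate" |
| χ1 thresholds | 5 / 10 | Hz | conventional gauche/anti cutoffs for ³J(Hα–Hβ); configurable |
| cluster cutoff | 0.2 | nm | the conventional gromos-clustering threshold for small peptides |
| periodicity margin | 1.0 | ppb/K | a residue is flagged only when less negative than both neighbours by more than this |

## Randomness and determinism

One `numpy` Generator seeded per ensemble. The stream is consumed
residue-major: for each residue, basin indicators (n uniforms), then the β
draws, the α draws, φ, and χ1, each as one vector over frames. Identical
(spec, model, n_frames, seed) give bit-identical arrays; the pipeline
derives per-system seeds as `seed + system_index`. Coordinate building and
clustering are fully deterministic; the clustering tie-break (equal
neighbour counts) goes to the lowest frame index, which cluster membership
can depend on.

## Coordinate building

Chain extension places each atom from a bond length, bond angle and torsion
(NeRF), vectorised over frames. The atom set per residue is N, H, CA, HA,
CB, C, O, plus a C-terminal ester oxygen OS and methyl carbon CM, and a
two-atom N-terminal cap (residue id 0): for Boc peptides the carbamate O–C,
for free amines a virtual reference frame. The cap exists so that φ and ω
of residue 1 are defined and every backbone torsion round-trips exactly; ψ
of the last residue uses OS as the following carbonyl substituent, so all
five residues have ψ. Side chains stop at Cβ: χ1 is carried in the dihedral
tables but not realised in 3D, and re-measuring dihedrals from coordinates
returns NaN for χ1. Bond lengths/angles are standard idealised peptide
values recorded in `BackboneGeometry` defaults.

PDB output rounds coordinates to the format's three decimals before
writing, and reading restores exactly those decimals, so a write→read
round-trip deviates by at most 0.0005 Å.

## Numerical and procedural choices

- **Basin probability** counts frames inside the stated closed windows
  rather than fitting and integrating peak shapes: deterministic,
  matches the stated basin bounds, no fit instabilities. The window bounds
  are configuration, so a peak-area convention can be approximated by
  widening them.
- **Ensemble-averaged couplings** are the mean of J(φ) over frames, never
  J of the mean φ — couplings average linearly under fast exchange.
- **Kabsch superposition** uses an SVD with a determinant sign correction
  (proper rotations only), batched over all model pairs so the full
  pairwise matrix is one vectorised call; RMSD is computed in Å and
  reported in nm. Collinear selections are rejected.
- **Clustering** subsamples the ensemble (default 120 frames) before the
  O(n²) RMSD matrix; cluster *populations* at that size are qualitative.
  The RMSD atom set defaults to backbone heavy atoms (N, CA, C, O) and is
  configurable.
- **Temperature coefficients** use ordinary least squares on δ(T);
  diagnostics (point count, RMS residual) ride along.
- **CSD exclusions**: terminal residues ("terminal") and residues without
  a coil reference ("no-reference", the CF₃-threonines) are marked, never
  silently dropped; summaries operate on the included values only.
- **Degenerate inputs**: empty ensembles, <2 temperatures, out-of-range
  probabilities, non-dividing histogram bin widths and mismatched
  model atom counts are rejected with specific messages.

## What the synthetic generator does and does not show

The generator reproduces the *statistical structure* of the analysis — basin
occupancies, their products, the monotone link from β weight to end-to-end
distance and to mean ³J — so tests that pass demonstrate the correctness of
the measurement machinery (windows, products, Karplus averaging, RMSD,
clustering) and the recoverability of basin weights at realistic noise. It
does not emulate force-field energetics, inter-residue correlations,
solvent effects or kinetics, so agreement here says nothing about whether a
particular force field would reproduce the experimental propensities; the
distance-distribution and cluster-population *shapes* of real trajectories
are outside its reach, and are checked only as orderings (the
(2*S*,3*S*)-CF₃-Thr systems most extended).

## Problem sizes

Default pipeline runs use 20,000 frames per system (parameter-recovery
tests 50,000), where the Monte-Carlo standard error of a basin probability
is ≤ 0.004, comfortably inside the ±0.01 recovery tolerance; clustering
runs on a 120-frame subsample (7,140 pairwise superpositions per system).
A full eight-system run completes in a few seconds.

## Known limitations

- Basin weights are treated as independent per residue; cooperative
  (zipper-like) extension cannot be represented.
- The Karplus parameter set and the random-coil shift compilation are
  choices, shipped as config; CSD and coupling *rules* are independent of
  those choices, but absolute back-calculated values are not.
- χ1 classification is a threshold call, not a rotamer-population fit.
- The gromos clustering is order-deterministic but cutoff-sensitive near
  cluster boundaries; populations should be compared across runs only at
  identical subsampling.
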