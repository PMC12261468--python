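# Methods

`holoflow` implements, at desk scale, the generative machinery used by
flow-matching docking models that transport an unbound (apo) protein-ligand
state to a bound (holo) one: structured priors, conditional flow matching
(CFM) with an unbalanced apo-holo coupling, a variance-diminishing ODE
sampler, and confidence/affinity ranking heads. This note records the model,
its assumptions, the numerical choices, and what the synthetic world does
and does not establish.

## State and notation

A complex state is the stacked heavy-atom coordinate matrix `x in R^(N x 3)`
(Angstroms), `N = N_P + N_L` protein plus ligand atoms, carried by
`ComplexStructure` together with the residue-level Ca trace (length `S_P`)
and the ligand bond graph. Flow time `t` runs from 0 (prior) to 1 (holo).

## Priors (t = 0)

**Ligand — harmonic prior.** Initial ligand conformations are drawn from a
Gaussian whose precision matrix is the bond graph's Laplacian `L = D - A`:
`rho_0(x) ∝ exp(-1/2 x^T L x)` applied per coordinate axis. `L` is PSD with
one zero eigenvalue (rigid translation) per connected fragment, so the
density is improper; we sample only the positive modes with per-axis
coefficient variance `1/lambda` and pin each fragment's centroid to a
configurable center. Default center: the protein's heavy-atom centroid
(the sampler must not presume knowledge of the binding site; where a
pocket hint exists it can be supplied). Bonded atoms thereby start close
together — the biophysical constraint the prior encodes.

**Protein — noised apo structure.** The t=0 protein is a user-supplied apo
structure plus i.i.d. Gaussian noise, sigma = 1e-4 A per axis during
training (applied to the apo and holo protein coordinates and the holo
ligand coordinates), off at inference. The noise regularizes against
coordinate round-off, not a conformational ensemble. Producing the apo
structure itself (a folding model in the full-scale setting) is out of
scope: any structure can be supplied.

## Conditional flow matching

Paths are linear (CondOT): `x_t = (1-t) x0 + t x1`, `t ~ U(0,1)`. The field
`v(x_t, t)` is an **endpoint predictor** — it regresses `x1` directly, not a
velocity — under the loss

    L = mean over atoms of || v(x_t, t) - x1 ||^2,

i.e. the squared Euclidean deviation summed over the 3 coordinates of an
atom and averaged over atoms (a uniform 1 A offset on every atom gives
exactly 1.0; size-independent scale). The loss is deliberately
frame-dependent; the test suite pins this contract down.

**Unbalanced coupling.** Prior and data samples are paired independently,
then pairs whose apo and holo *protein* structures are too dissimilar are
rejected: after a ligand-proximity-weighted Ca superposition, a pair is
accepted iff `TM >= 0.7` and `RMSD < 5 A` (strict at the RMSD bound:
a pair sitting exactly at 5 A is rejected), plus configurable length
bounds (defaults `10 <= S_P <= 2000`, `1 <= N_L <= 200`; the full-scale
curation pipelines apply similar but unspecified length rules, so these
are config, not doctrine).

**Alignment details.** Superposition is computed on Ca correspondences
only; heavy atoms inherit the rigid transform. Residue weights are
`w_i ∝ exp(-d_i / 4 A)` with `d_i` the minimum distance from residue i's
Ca to any holo-ligand heavy atom — an exponential kernel concentrating the
fit on the pocket. The functional form and the Ca-level granularity are
design choices (the upstream description says only "weighted"); the kernel
scale is configurable. TM-score uses the standard
`d0(L) = 1.24 (L-15)^(1/3) - 1.8`, floored at 0.5 A, normalized by the
holo chain length; it is evaluated after the ligand-weighted alignment by
default, with a `tm_optimal` flag for an iterative TM-oriented
superposition (fixed-point reweighting by `1/(1+(d_i/d0)^2)`).

## VD-ODE sampler

On the uniform grid `t = n/i`, `s = (n+1)/i` (default `i = 40` steps,
`eta = 1.0`):

    x_{n+1} = clamp((1-s)/(1-t) * eta) * x_n
            + clamp((1 - (1-s)/(1-t)) * eta) * v(x_n, t)

with each scalar coefficient clamped into `[1e-6, 1 - 1e-6]`. The clamp is
applied to the coefficients, not the coordinates (the upstream notation is
ambiguous; bounding the blend weights matches the stated intent that both
terms stay bounded). The `t = 1` singularity is never evaluated: the last
step uses `t = (i-1)/i`, where the state coefficient clamps up from 0 to
1e-6. For `eta = 1` the unclamped coefficients sum to one, and with a
perfect oracle field the iteration reproduces the CondOT path exactly up
to clamp error (< 1e-4 A over 40 steps).

A plain Euler baseline integrates the induced velocity
`(v(x,t) - x)/(1-t)` with step `1/i`. For `eta = 1` this is algebraically
the same recursion as the VD-ODE *except* for the clamp, so the
variance-diminishing property is verified with common random numbers: the
same noisy field evaluations drive both solvers, and the final-state
variance under the VD-ODE is strictly (if slightly, at eta = 1) below the
Euler baseline's. Larger damping appears for eta < 1, where the VD-ODE
geometrically suppresses early field noise while Euler does not.

## Toy endpoint field

The trainable field is the minimal architecture that exercises the
training and sampling contracts: a one-pass equivariant message model.
Per-atom update = learned linear combination of geometric direction
channels — fragment-centroid-to-pocket pull, contraction toward the own
(fragment) centroid, pull toward a burial-weighted protein centroid
("pocket proxy"), and radial-basis-weighted interface messages — each
modulated by a polynomial time embedding (default degree 5). All channels
are coordinate differences, so predictions are translation-invariant and
rotation-equivariant, and both protein and ligand atoms are updated (the
protein is not frozen). Because the weights enter linearly the CondOT
objective is least-squares; we optimize with Adam (lr 0.05, weight decay
1e-3) to retain a training curve. The weight decay matters: the channels
are partially collinear and the penalty keeps the fit near the
minimum-norm solution, which extrapolates sanely off the training path.

With prior and holo poses drawn from the *same* harmonic covariance, even
the Bayes-optimal endpoint predictor can only reach ~75% of the initial
loss on shape modes (the posterior-variance floor of matching Gaussians);
meaningful transport requires the data distribution to be sharper than the
prior, which is also the physically correct statement — crystal poses are
specific, ordered conformations. The synthetic world encodes this as a
bound-state compactness factor (below).

## Confidence and affinity heads

Both heads are ridge regressions over rigid-motion-invariant interface
descriptors (contact counts per ligand atom at 2.5/3.5/4.5/6 A, clash
count < 2 A, mean and min interface distance, ligand radius of gyration,
bond-length mean/variance). The confidence head is trained against
negative ligand RMSD to the true pose of deliberately corrupted poses; the
affinity head against pK-scale affinities (-log10 molar, the PDBBind
convention; mean-square loss). Samples are rank-ordered by confidence
(stable descending sort, ties by sample index).

## Synthetic world

`synthetic` generates fully reproducible toy systems:

- **Protein**: compact self-avoiding bead chain, 3.8 A Ca steps, one
  pseudo side-chain atom per residue (so `N_P = 2 S_P` and the Ca vs
  heavy-atom distinction is exercised).
- **Binding rule**: the holo ligand sits at the protein's most buried
  point — the burial-weighted centroid — making the apo-to-holo map
  learnable from coordinates alone.
- **Holo pose**: harmonic blob scaled by a compactness factor 0.5 about
  its center (bound poses are ordered/compact relative to the diffuse
  prior). Multi-fragment ligands get per-fragment centers jittered by
  1.5 A around the pocket.
- **Deformation modes**: `rigid_ligand_shift` (ligand translated by
  exactly the requested scale; protein fixed), `pocket_hinge` (C-terminal
  half rotated about a mid-chain hinge) and `global_deform` (smooth
  low-frequency chain field), the latter two rescaled so the apo-holo Ca
  RMSD equals the requested scale exactly.
- **Affinity**: `pK = 0.1 * (protein-ligand atom pairs < 4.5 A) + N(0, 0.3)`
  — a contact-driven toy binding free energy on the pK scale.

`make_pair_with_similarity` constructs apo/holo pairs whose *measured*
(TM, RMSD) — under the coupling filter's own alignment — hit requested
targets, via nested bisection over a two-parameter deformation family
(overall scale vs the fraction of moving residues, recruited
far-from-ligand first so the pocket deforms last). Boundary cases can be
placed on a chosen side of a threshold, which is how the strict RMSD
rejection rule is tested at exactly 5 A.

What the toys do **not** emulate: real protein folds, chemically valid
ligand geometry, sequence mismatches between apo and holo, or any of the
large-scale benchmark distributions. A green transport test establishes
that the machinery — priors, coupling, training, sampling, ranking —
composes correctly and transports toward the data distribution; it says
nothing about docking accuracy on real complexes.

## Numerical choices and degenerate inputs

- Laplacian null-space threshold 1e-8 (eigenvalues below it are treated as
  translations); non-PSD precision matrices are rejected.
- Kabsch uses the SVD closed form with the determinant sign correction;
  (near-)collinear or coincident point sets emit a degeneracy warning and
  return a best-effort transform.
- RMSD and TM-score are reported over all points, unweighted, regardless
  of the alignment weights, so down-weighted residues still count toward
  the similarity verdict.
- Randomness flows from one run-level seed through named substreams
  (CRC-32 of the stream name spawned off a `SeedSequence`), making every
  pipeline stage bit-reproducible.
- Fields returning non-finite coordinates abort integration with the
  offending step named; non-finite training losses abort training.

## Known limitations

- The toy field is linear-in-weights; it cannot memorize per-system holo
  shapes and therefore bounds transport at the in-span posterior mean.
- Ligand RMSD is computed without symmetry correction (graph automorphisms
  of the ligand are ignored).
- Apo/holo pairs must be residue-matched; no sequence alignment is
  performed.
- The `eta = 1` variance reduction relative to Euler is real but small by
  construction (the two recursions differ only in the clamp); the
  qualitative variance-limiting behaviour of the sampler is the design
  point, not a large effect size at eta = 1.
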