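# Methods

## The model

`porethread` treats the substrate polypeptide inside a AAA+ channel as a
*symmetrized* extended strand: a two-residue dihedral repeat
(φ₁, ψ₁, φ₂, ψ₂), peptide bond fixed trans (ω = 180°), repeated over the
resolved length (13 residues by default).  The assumption is that at
modest local resolution the tubular substrate density constrains only a
small number of backbone degrees of freedom; four torsions capture the
dipeptide periodicity that the pore-loop spiral imposes while making
overfitting impossible.  Chains are built by sequential
internal-coordinate placement (NeRF): each atom is positioned from the
previous three by bond length, bond angle, and torsion, with the first
residue in a canonical frame.  Covalent geometry uses standard idealized
values (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, Cα–Cβ
1.521 Å; N–Cα–C 111.2°, Cα–C–N 116.2°, C–N–Cα 121.7°; Cβ placed by the
L-chirality improper C–N–Cα–Cβ = −122.6°).  Any consistent idealized set
preserves the repeat analysis; these constants live in
`GeometryParams` and round-trip exactly: a built chain re-measures its
generating torsions to better than 10⁻⁴ degrees.

## Repeat recovery from density

The repeat is recovered by maximizing real-space correlation between a
poly-Ala chain built at candidate torsions and the map, sampled at 2°
over the generalized β region (φ ∈ [−180°, −30°], ψ ∈ [60°, 180°]).
A full 4-D exhaustive scan at 2° (~2 × 10⁷ points) is infeasible, so
the search proceeds in three deterministic stages:

1. **Symmetric initialization** — scan the single-residue diagonal
   (φ, ψ, φ, ψ).  The best symmetric helix is a robust ridge point of
   the landscape.
2. **Coordinate descent** — alternate exhaustive 2-D scans of the
   (φ₁, ψ₁) and (φ₂, ψ₂) planes until neither improves.
3. **Joint local polish** — the two pairs compensate strongly (a
   symmetric average fits almost as well as the true asymmetric repeat,
   and the true repeat differs from the ridge in *both* planes), so the
   descent fixpoint is refined by exhaustive scans of the joint 4-D
   neighborhood (±10° per axis on the same grid) iterated to a fixpoint.

Each candidate chain is placed in the map by superimposing its Cα trace
onto the current anchor chain (Kabsch), where the anchor is the current
best chain rigid-body fitted to the density (coarse axis/centroid
pre-alignment, rotation-about-axis and axial-shift scan, then
Nelder–Mead polish of the six rigid parameters on the correlation).
Correlations are evaluated over the fixed set of voxels above 5% of the
map maximum, so scores are comparable across candidates.  Ties break
toward the candidate closest to the search start.  On a noiseless map
simulated from a chain whose repeat lies on the grid, the procedure
returns that repeat exactly (correlation ≈ 1.0) in under a minute on
one CPU; when the map is simulated from the start repeat itself, the
start is returned with zero improvement steps.

## Density simulation and scoring

Simulated density places one isotropic Gaussian per atom with the
nominal resolution treated as FWHM (σ = resolution/2.3548, truncated at
4σ) and amplitude proportional to atomic number.  The real-space
correlation of a model is the Pearson correlation between its simulated
density and the target map over voxels within 3 Å of any model atom.
Maps are float32 on cubic-voxel orthogonal grids; MRC/CCP4 I/O via
gemmi round-trips values bit-exactly, with the origin carried in the
ORIGIN header words in Å.  Default simulation resolution mirrors the
source structure (2.9 Å); scoring accepts its own resolution parameter
and should match the map being scored.

## Threading and the surrogate energy

Candidate windows are placed on the *fixed* shared backbone.  Side
chains come from ideal residue templates (heavy atoms of the chemical
component dictionary, via biotite), anchored exactly at the model Cβ
with the Cβ–Cα bond direction aligned and the spin chosen to match the
amide N — side-chain internal geometry therefore stays rigidly
template-ideal (bond lengths reproduce template values to 10⁻⁶ Å).
χ₁/χ₂ are sampled on the staggered grid {−60°, 60°, 180°} (≤ 9
combinations; further χ kept at template values, Pro ring fixed) and
the lowest-clash combination wins, ties to the first in grid order.

The per-model energy is a documented surrogate, not a physical force
field:

    total = e_density + e_clash + e_ref
    e_density = −w_d · cc                      (w_d = 10)
    e_clash   = w_c · Σ max(0, r_i + r_j − d)²  (w_c = 1, radii × 0.8)
    e_ref     = Σ ref(aa)                       (ref(Ala) ≡ 0)

Clash pairs count side-chain atoms against other residues and fixed
context atoms only; backbone–backbone terms are constant across
sequences and excluded.  All inference is relative — windows are ranked
by `total − total(poly-Ala)` and profiles are averages — so the
absolute scale is irrelevant; what matters is that filling observed
density lowers the energy and steric overlap raises it.  Reference
weights default to zero; `calibrate_reference_weights` sets
ref(aa) = total(poly-Ala) − mean(single-aa null totals), which anchors
the calibrated null profile's alanine row at exactly zero.

Refinement runs five independent trajectories of greedy (temperature-0
Metropolis) stochastic moves: Gaussian χ perturbations (σ = 10°) and
per-residue backbone jitter bounded at 0.2 Å from the shared backbone;
only the peptide moves.  Trajectories score against a fixed mask for
speed; the winner is re-scored on its own mask and the input model is
kept unless the refined one is strictly better, so refinement never
worsens the reported energy.  Everything is reproducible from a single
seed (per-window streams are spawned deterministically).

## Profiles, null background, logos

The threaded profile cell (position, aa) is the mean total energy of
all windows carrying `aa` at that position; first and last window
positions are excluded (11 analyzed positions for k = 13), since
terminal residues are only partially enclosed by the channel.  The
null-background scan builds all-Ala windows with one substituted
position — (k−2) × 20 identities × rings, i.e. 440 models for k = 13
and two rings — and reports each model's energy minus the all-model
mean.  Cells never observed are missing, not zero.  Logo conversion is
p(aa | position) ∝ exp(−E/kT) over the observed identities, kT = 1
energy unit by default (the conversion temperature is a presentation
choice; it rescales contrast, not ordering).

## Synthetic scenes

`make_channel_scene` emulates the features of a substrate-bound channel
that this analysis relies on: an extended strand at the selected repeat
(−92°, 118°, −102°, 110°), a ground-truth sequence alternating bulky
hydrophobics (F/Y/W/L/I) at the pocket-aligned even positions with
small residues (A/S/T/V) elsewhere, pocket pseudo-atom triplets on an
exact spiral around the strand axis (rise 6.5 Å, rotation 60° per
contact, radius 7 Å — the pore-loop staircase geometry), simulated
density at 2.9 Å, and optional i.i.d. Gaussian voxel noise
(SNR defined as σ of supra-threshold signal voxels over noise σ).  The
truth peptide is threaded with the pocket atoms as clash context,
exactly as candidates are threaded later, so recovery experiments are
self-consistent.  Scenes are bit-reproducible from their seed.

What the scenes deliberately do **not** emulate: experimental noise
correlations and B-factor falloff, solvent/envelope effects, pore-loop
flexibility (pocket atoms are rigid context; a config hook is reserved),
partial occupancy from mixed substrate registers, and any map-to-model
scale miscalibration.  Passing recovery tests therefore demonstrates the
inference logic (ranking relative to poly-Ala, per-position averaging,
null-background normalization) under controlled conditions — not that
the surrogate energy reproduces a physical force field on experimental
maps.

Decoy isoform sets embed the truth window exactly once in random
polar/charged background sequences with hydrophobic decoy patches; with
casein-like precursor lengths (214, 222, 224, 190) they reproduce the
802-window count.

## Spiral geometry

Contact spirals are measured from one anchor atom per protomer (default
Cα; side-chain atoms selectable).  The axis is a least-squares *helix*
fit: chord bisectors at interior anchors are radial for an ideal helix,
so the axis direction is their null-space vector and the axis position
the least-squares circle centre in the perpendicular plane.  (A straight
line fit is biased for wide spirals, where in-plane spread dominates.)
Rise and signed rotation are reported per consecutive protomer pair;
collinear anchor stacks (zero spiral radius) have no defined azimuth and
raise an error.  Constructed spirals are recovered to well within
0.05 Å / 0.5°, and the measurement is invariant under rigid-body motion
of the whole model.  Per-protomer marker distances
(`protomer_expansion`) take a residue pair and report the atom–atom
distance in each chain.

## Problem sizes and determinism

Default analysis scale mirrors the study design: k = 13 windows, 2°
grid, five refinement trajectories, two rings.  The test suite and the
acceptance script run reduced problem sizes chosen as the smallest that
still exercise each property — 9-residue scenes with ~40 decoy windows
for ranking experiments, 10 seeds for the noisy-recovery average,
refinement disabled where only relative scores of fixed models are
compared.  Every stochastic component (scene generation, decoy
sequences, refinement moves) flows from explicit integer seeds, and
pipeline manifests record seed, package versions, and SHA-256 digests
of all outputs.

## Known limitations

* The surrogate energy has no electrostatics, solvation, or backbone
  remodelling beyond bounded jitter; absolute energies are meaningless
  off-scale and only within-run rankings are interpretable.
* The strand register and direction inside the tube are input
  conventions, not inferred (no de novo tracing).
* χ sampling is coarse (staggered grid, first two χ); long side chains
  keep template values for distal torsions unless refined.
* The grid search assumes the map contains a single tubular strand
  region; multi-strand maps need masking upstream.
* Deposited-map validation (which experimental peptide fits best) is
  out of scope here; it requires the original maps and force field.
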