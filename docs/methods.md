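# Methods

This note records the models, conventions and numerical choices behind
`sfcollapse`, and what the synthetic-data tests do and do not establish.

## Collapse reaction coordinate

The conductive↔collapsed transition of a selectivity filter (SF) is
described by a single collective coordinate built from two reference
conformations A (conductive) and B (collapsed). After superposing B onto
A on the coordinate's atom selection, the coordinate is the normalized
flattened difference vector **u** = (B − A)/|B − A| ∈ ℝ³ᴺ. For a data set
of exactly two structures, mean-centering leaves a rank-one covariance
whose only non-degenerate eigenvector is the (B − A) direction, so this
explicit difference *is* the first principal component of the pair; we
implement the difference directly because it is numerically exact and
carries no eigen-solver sign ambiguity (the sign is fixed so that the
collapsed reference maps to +1). An eigen-decomposition route exists only
as an independent oracle in the tests.

A frame x is projected as s = [(x − A)·**u**]/|B − A| after rigid-body
superposition of the frame onto A *on the coordinate selection itself*
(the SF backbone). Aligning on the measured atoms matches the way the
reference endpoints are defined; an alternative alignment selection is a
constructor argument for users who prefer whole-pore alignment. s is
dimensionless (0 = conductive, 1 = collapsed, excursions outside [0, 1]
meaningful); the displacement in Å (s·span) is reported alongside because
either scale is common in figures.

Endpoint collapse is the arithmetic mean of s over frames with
t ≥ burn-in; the burn-in defaults to 40 ns, the time scale on which the
collapse transition completes in the underlying simulations. Ensemble
traces match runs to a common grid by nearest frame time (no smoothing or
interpolation of single-run data) and report SEM = sd/√n with the sample
standard deviation across runs (n ≥ 2 required).

**Default selection.** Which atoms constitute "the SF backbone" is not
uniquely determined by convention; the default is N, CA, C, O of the five
filter residues (624–628) per chain and is exposed as a parameter rather
than hard-coded.

## RMSF

Fluctuations are measured about the trajectory mean after a two-pass
superposition: frames are fitted to frame 0 on the alignment selection,
the mean structure of the fitted frames is formed, and the original
frames are refitted onto that mean before deviations are accumulated
(rmsf_i = √⟨|r_i − ⟨r_i⟩|²⟩). Aligning to the mean rather than to an
arbitrary frame removes the reference-frame bias of one-pass RMSF; this
is standard practice. No mass weighting is applied — the headline
analysis concerns carbonyl oxygens only, and weighting would be a no-op
there. Aggregation over the four subunits is an arithmetic mean;
per-(chain, residue) values are retained. Atoms whose coordinates are
bitwise constant across frames report exactly zero.

For iid isotropic Gaussian noise of standard deviation σ per coordinate,
E[RMSF] → σ√3; the suite checks this closed form at σ = 0.5 Å with 10⁴
frames (2% tolerance), with alignment atoms left noise-free so the rigid
fit does not absorb part of the noise.

## Hydrogen-bond criteria

The underlying analyses report H-bond counts without publishing a
geometric criterion, so the criterion here is a documented default, not a
reconstruction: donor–acceptor distance ≤ 3.5 Å, plus (with explicit
hydrogens) a hydrogen deviation from the D→A line ≤ 30°, or (heavy-atom
mode, the default for the idealized models) the requirement that every
covalent neighbour of the donor lies behind it (antecedent–D···A angle
≥ 90°), which suppresses geometrically impossible approaches. Covalent
(< 1.8 Å) and same-residue geminal pairs (< 2.8 Å, e.g. the two amide
heteroatoms of an asparagine side chain) are never counted. Donor and
acceptor atom-name tables follow standard protein chemistry (backbone O
is acceptor-only, backbone N donor-only, hydroxyl O both).

The focal residue's side chain is counted whether it acts as donor or
acceptor (an amide group is both). "Neighboring subunit" means any chain
other than the focal one — with four-fold symmetric geometries the
distinction from ring-adjacency never arises in practice. Raw integer
counts per frame are the primary output; rolling-mean smoothing is
presentation-layer only.

## Pocket volume

Accessibility is probe-center accessibility: a grid point is accessible
iff its distance to every heavy atom is ≥ vdW(atom) + probe radius. This
is the simplest defensible reading of "solvent accessibility for a
water-sized molecule", and it has an exact analytic test case (a
spherical shell of atoms encloses a probe-accessible ball whose radius is
known in closed form). Defaults: probe 1.4 Å, grid spacing 0.5 Å,
Bondi-style vdW radii shipped as data; unknown elements raise rather than
defaulting. The region is a sphere (default 18 Å radius around the S620
position, matching the receptor-region convention of the docking
analyses this mirrors). The grid is anchored at the region center, which
makes volumes exactly translation-reproducible; rotations move atoms
relative to the grid and change volumes within roughly one grid cell, as
expected for any voxel method. Connected components use 26-neighbor
connectivity; the open/closed threshold for time series is a parameter
(suggested default: half the open-state reference volume — no published
number exists).

## Distance scan

The scan label d is the *target* Cβ–Cβ separation of the S620/N629 pair
(the restraint target of the original simulations); the realized mean
distance is recomputed from the trajectories and reported alongside,
since the two are silently interchanged in figure axes. The endpoint
collapse vs d line is fitted by ordinary least squares over a declared
window, default 5–11 Å: beyond ~11 Å the SF backbone is stretched and the
relation leaves the linear regime, so 12 Å is excluded by default. The
fit is a diagnostic summary of near-linearity, not a mechanistic model.
Reports are deterministic given the manifest (fixed float formatting, no
timestamps in tables), so reruns are byte-identical.

## Electrophysiology fits

Boltzmann forms: activation f(V) = 1/(1 + exp((V½ − V)/k)) with k > 0
(current increases with depolarization); steady-state inactivation uses
the descending branch 1/(1 + exp((V − V½)/k)), again with k reported
positive. The exact algebraic convention is a package decision — sign
conventions differ across the literature — and is fixed by the biology.
Initialization is deterministic: V½ from the half-maximum crossing of the
linearly interpolated data, k from the 25–75% span divided by 2·ln 3;
Levenberg–Marquardt refines. Data with amplitude span < 0.1 raise
immediately; data that converge but fit poorly (R² < 0.9, e.g. biphasic
conductance–voltage relations) set a lack-of-fit flag rather than being
reported silently. The "open fit" mode freezes k, for curves shifted so
far that only a few points span the transition. Deactivation is
A·exp(−t/τ) + C with A > 0, τ > 0 bounds; non-decaying traces are
rejected. The steady-state inactivation measure is the ratio of the
current remaining 100 ms after pulse onset to the instantaneous current;
the instantaneous amplitude is the onset sample when one exists,
otherwise a linear extrapolation of the first five post-onset samples
(synthetic traces are capacitive-transient-free, so no further
correction is modeled).

## Synthetic data: what it emulates, what it does not

The generators produce an idealized four-chain SF stand-in (backbone
N/CA/C/O of residues 624–628, Ser-620 and Asn-629 side-chain stand-ins)
with exact four-fold symmetry; the collapsed reference pinches the
central carbonyl oxygens radially inward so the coordinate span is known
in closed form (δ·√8 for a δ Å pinch of 8 atoms). Trajectories follow
programmed collapse paths with iid Gaussian positional noise; toggle
trajectories place the Asn donor 2.9 Å from either its own chain's S620
hydroxyl or the next chain's G628 carbonyl according to a seeded
Bernoulli sequence; cavities are atom shells with analytically known
accessible volume; recordings are exact model curves plus optional
Gaussian noise. Every generator emits a ground-truth sidecar, and all
recovery tests read truth only from sidecars.

Default study conditions mirror the scenario the package targets: scan
labels d = 5…10 Å with programmed plateau s(d) = (10 − d)/5 (conductive
at 10 Å, collapsed at 5 Å), 4 runs per d, positional noise σ = 0.3 Å,
burn-in 40 ns; activation V½ = −28.5 mV, k = 7.41 mV; deactivation
τ = 73.2 ms; steady-state inactivation V½ = −18.8 mV with slope 7.0 mV
(a typical value; the slope is not separately constrained) and a 50 ms
inactivation time constant for the ratio trace (chosen so the 100-ms
ratio has the closed form e⁻²).

Because the geometry is idealized and the noise is iid Gaussian, passing
tests demonstrate the correctness of the *analysis* code — projections,
fluctuation statistics, bond classification, volumes, fits — under known
ground truth. They do not validate force fields, sampling, or the
structural realism of any particular channel model, and real trajectories
add correlated noise, anharmonic motions and hydrogen-bond dynamics that
these generators deliberately omit.

## Problem sizes

The packaged test and acceptance workloads use desk-scale sizes chosen to
keep statistical targets meaningful: 10⁴ frames for the RMSF closed form,
2 000 frames for the toggle recovery, 60-frame/1-ns-spaced scan runs
(20 post-burn-in frames per run, 4 runs per d), 100 random 30-atom frames
for oracle equivalence, and ~1 200-atom shells on 0.5/0.25 Å grids for
the cavity benchmarks.

## Known limitations

- PDB support is deliberately narrow (fixed-column ATOM records, no
  insertion codes, HETATM ignored); mmCIF and binary trajectory formats
  are out of scope — convert externally.
- H-bond detection is geometric only; no energetic model, no
  water-mediated bridges.
- Pocket volume is probe-center accessible volume, not a molecular
  surface; absolute values depend on the convention and should be
  compared within one convention only.
- The two-structure coordinate assumes the endpoints bracket the motion
  of interest; it is not a free-energy or committor coordinate.
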