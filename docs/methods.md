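# Methods

This note records the models, conventions and numerical choices behind
`idenet`, and what its synthetic validation does and does not demonstrate.

## Units and containers

Lengths are nm (PDB Å divided by 10 on read), energies kJ mol⁻¹, spring
constants kJ mol⁻¹ nm⁻², times ps, temperatures K. The Boltzmann constant is
fixed at k_B = 0.008314462 kJ mol⁻¹ K⁻¹. A `Structure` is an ordered list of
labelled beads (1-based residue index, chain id, position); an `Ensemble` is
a frame stack over one topology. Residue numbering is taken from the input
as-is — if a study renumbers a truncated construct, that mapping is the
user's responsibility and the tool never renumbers.

## Superposition and deviation measures

Rigid-body fitting is least-squares (Kabsch) via
`scipy.spatial.transform.Rotation.align_vectors`, which returns a proper
rotation (det = +1); reflections can never be introduced, so chirality is
preserved. Fits are defined on a selection (typically a rigid core region)
and applied to all beads. Fewer than 3 selected beads, or a collinear
selection, is an error. RMSF is measured about the mean of the fitted
frames. Histograms are left-closed/right-open with the minimum value
anchored to a bin edge; an on-edge global maximum falls into the last
occupied bin rather than opening an empty one; densities are normalised so
Σ density · bin width = 1.

## Pair statistics

The scalar covariance cov_ij = ⟨(r_i − ⟨r_i⟩)·(r_j − ⟨r_j⟩)⟩ uses
population (1/F) normalisation and two-pass (mean, then deviation)
accumulation; computing it requires fitting every frame to a reference first
to remove global translation/rotation. That same fitting suppresses genuine
co-movement of rigid-core beads, which is why the distance statistics
d̄_ij = ⟨|r_i − r_j|⟩ and Var(d_ij) are computed **without** any fitting
(distances are rigid-motion invariant) and are kept as an independent
bonding criterion. Correlations of zero-variance (frozen) beads are
undefined and stored as NaN; they simply fail any correlation threshold
rather than raising, so the variance branch can still bond such pairs.
Averaging over equivalent units (e.g. the two chains of a homodimer) acts on
the statistics matrices after index remapping, never on coordinates — an
averaged structure can place beads in unphysical positions, an averaged
covariance cannot.

The default fitting selection for covariances is configurable and defaults
to all beads unless a core selection is passed; analyses that care should
pass the core region explicitly.

## Network construction

`build_elnedyn` is the plain cutoff network (single conformation, uniform
K); `select_iden_bonds` applies the fluctuation gates described in the
README, with the cutoff acting on the ensemble-**mean** distance.
`c_min` and `v_max` are deliberately required arguments with no defaults
(`SUGGESTED_CORR_MIN = 0.5`, `SUGGESTED_VAR_MAX = 0.01 nm²` are module
constants): the gate values are study choices and should appear in every
analysis record rather than being inherited silently. Sequence separation is
measured in residue-index units within a chain; inter-chain pairs are never
bonded — networks support one protein unit, they must not stitch an
assembly together, or assembly/disassembly and mechanical failure modes
would be eliminated by construction. Initial constants use
K_ij = K₀·Var_min/Var(d_ij) (stiffest bond = K₀ exactly, K_ij·Var_ij
constant); zero-variance bonds receive exactly K₀. Cutoff-network rest
lengths come from the input conformation; gated-network rest lengths from
the ensemble-mean distances.

## Harmonic engine

The anisotropic-network Hessian carries one K·êê^T super-element per bond
at the reference geometry. The equilibrium covariance is C = k_BT·H⁺ with
the pseudo-inverse taken over the rigid-body null space; the expected
zero-mode count is derived from the geometry's rank (6 in general, 5 for a
collinear dumbbell) and any extra zero mode is an error that names the
disconnected component when there is one. The per-pair distance variance
Var(d_ij) ≈ ê·(C_ii + C_jj − C_ij − C_ji)·ê is first order in
fluctuation/|r₀|; the validation below quantifies the error of that
linearisation. For strained configurations (energy minima under external
load) the exact bond Hessian including the transverse K(d−r₀)/d·(1−êê^T)
term is used instead.

The Langevin engine is overdamped (positions only, unit mass) in the
successive-noise-averaging (Leimkuhler–Matthews) form,
x ← x + F·dt/γ + √(2k_BT·dt/γ)·(ξ_n + ξ_{n+1})/2, chosen because its
configurational sampling error is O(dt²) — the plain Euler–Maruyama update
inflates each mode variance by λdt/2γ, which is measurable at usable time
steps. Stability is enforced through the Gershgorin bound λ_max ≤ 2·max_i
Σ_b K_ib with a factor-2 margin. Divergence (|x| > 10⁴ nm) aborts with
advice to reduce dt.

Three objects satisfy the fluctuation-evaluator contract (network → per-bond
Var(d)): the analytic evaluator, the Langevin evaluator (optional
common-random-numbers variance reduction across refinement iterations, off
by default), and an external-ensemble adapter. The last is how the
refinement loop couples to a real CG engine: export the network as a bonded
include file, simulate externally, read the trajectory back.

## Refinement

Both update rules are clamped to [K_min, K_max] (defaults 1.0 and twice the
largest initial constant) because the additive rule can overshoot
catastrophically when a noisy evaluation returns a tiny Var_current, and a
multiplicative step on a noisy ratio can do the same. Convergence is
declared on the *relative change* of the metric (mean |Var_current −
Var_target| over bonds) over one iteration falling below `rel_tol`
(default 10⁻²), or on the metric being numerically zero; an absolute
threshold would need a system-dependent scale. If every bond sits at a clamp
for two consecutive iterations a "stalled" warning is emitted. The bond set
is immutable during refinement — selection precedes iteration.

The direct rule is implemented as K′ = K·(Var_current/Var_target)^γ with
γ = 1 by default. This power-law form is this package's reading of "direct
scaling": it is the unique one-parameter multiplicative rule that is
dimensionless, fixes the matched point, and solves an isolated harmonic bond
(Var = k_BT/K) in a single γ = 1 step. On coupled networks it converges in
tens of iterations in our experiments, consistently faster than the additive
rule at α = 0.05.

## Orientation maps

Internal axes are guide vectors from a subunit's centre of mass to the
centres of mass of fixed residue clusters. Two presets are provided
(`METHODS_CLUSTERS`, the default: X 69–71+92+122–124, Y 19–21+136,
Z 55–57+137–139; and `FIGURE_CLUSTERS`: same X, Y 20–21+134–135,
Z 56–58+99–100) because the two published lists for this protein disagree;
neither is silently preferred beyond the documented default. Gyration-tensor
eigenvectors are deliberately not used: the two smaller eigenvalues are
nearly degenerate and their eigenvectors swap identity between frames.
Axis pairs deviating more than 25° from orthogonality trigger a warning, not
an error. Per frame, the whole dimer is fitted to a shared reference on
subunit 1's core, the chosen axis pair (M1, M2) is rotated rigidly so M1
lies along a global direction (+z by default, +x available), and the
projection p of M2 on the normal plane, scaled by M2's guide length, is
recorded — so |p| = L·sin θ with θ the M1–M2 angle, computed in atan2 form
for conditioning at θ ≈ 0. If M1 is antiparallel to the target the rotation
axis is an arbitrary perpendicular (the documented tie-break). Density maps
are normalised occupancy histograms over [−r, r]², r the longest guide
length observed.

## Indentation

The wall potential is U(h) = ε[(2/5)(σ/h)¹⁰ − (σ/h)⁴] truncated at its
minimum h = σ and shifted by +3ε/5, so U(σ) = U′(σ) = 0 and the wall is
purely repulsive with cutoff σ. Defaults ε = 1 kJ mol⁻¹, σ = 0.5 nm are
explicit configuration, not claims about any published setup. Internally the
potential continues linearly below h = σ/4 so that minimiser line searches
and rare noise kicks that probe behind the wall stay finite; equilibrium
states never live in that region. Walls are infinite planes normal to one
axis and act on the beads only (there is no solvent in this engine, so
"semi-permeable" is purely documentation). Schedules are inclusive
arithmetic sequences; per step the walls are held while the system runs a
fixed time of overdamped dynamics continuing from the previous step, and the
load on one wall is reported as the whole-step mean ± SD (running-average
reporting over 10/50 samples is available; an `equilibration_fraction`
discards the post-move transient for quasi-static estimates). The analytic
cross-check computes −dF/dL by linear response around an energy minimum:
the bond Hessian plus wall curvatures on the contact beads, solved against
the wall-displacement forcing with a least-squares pseudo-inverse (the
in-plane translations and the rotation about the compression axis remain
zero modes and are orthogonal to the forcing).

In a purely harmonic network the only irreversibility available is
transient lag, so hysteresis vanishes in the slow-compression limit;
genuinely irreversible (bond-breaking / bead-rearrangement) behaviour
requires anharmonic add-ons or an external engine through the evaluator
route.

## Synthetic validation systems and their limits

`make_truth_system` builds a densely bonded compact core (log-uniform
constants, default 50–500 kJ mol⁻¹ nm⁻²) with an optional pendant tail whose
beads hug the core surface in the reference conformation but are tied only
softly (default 2–10 kJ mol⁻¹ nm⁻²) to their three nearest
sequence-eligible predecessors — rigid attachment (exactly 6 zero modes is
verified) with fluctuations that dwarf the core's. That geometry is exactly
the failure mode of snapshot-cutoff bonding: close in the reference, weakly
correlated and widely fluctuating in the ensemble. `make_toy_capsid` is a
Fibonacci-lattice spherical shell with neighbour bonds; `make_dimer_fixture`
is two rigid 150-bead subunits (with valid guide-cluster residues) whose
relative orientation rotates per frame about a fixed axis by angles drawn
with variance k_BT/k_hinge, or by a prescribed series. All generators are
deterministic under their seed.

Validation scales were chosen to keep every check closed-form or
Monte-Carlo-cheap on one CPU: 20-bead truth networks, 42-bead shells,
5·10⁴-sample Gaussian draws, ~10⁶-step Langevin runs. Two regimes are used
deliberately: a moderate-stiffness network (K 50–500, T = 300 K) for
refinement recovery, where the analytic evaluator is self-consistent
regardless of linearisation error; and a stiff network (K 3000–12000,
T = 50–150 K) for sampler-vs-analytic closure, because the linearised
Var(d) is only accurate when fluctuations are well below bond lengths — at
K ~ 100 and T = 300 K the d²-Jacobian correction to a bond-length variance
is already ~15%, which the tests exhibit rather than hide (the dumbbell
sampler test checks against the exact radial Boltzmann quadrature, not the
linearised value). Monte-Carlo comparisons use blocked standard errors
(maximum over 10- and 20-block estimates, conservative against residual
autocorrelation).

What passing these tests shows: the statistics are exact, the engine
closures are mutually consistent, the refinement loop recovers known
heterogeneous stiffness essentially exactly under its own evaluator, the
gates prune constructed tails, and the indentation engine agrees with
independent linear response. What it does not show: fidelity to any real
protein's fluctuation spectrum — the synthetic ensembles are Gaussian by
construction, with none of the anharmonicity, multi-well kinetics, solvent
effects or sampling-convergence issues of real (atomistic) reference
trajectories, and no claim is made about published simulation values that
require hundreds of ns of MD on real systems.

## Known limitations

* The analytic evaluator requires a connected, rigid network over the whole
  topology; a gated network that (correctly) leaves a tail unbonded cannot
  be refined standalone — in the intended workflow those beads are carried
  by the base CG force field, i.e. by the Langevin engine with add-on
  potentials or by an external engine.
* The overdamped integrator has no inertia; only configurational statistics
  are meaningful, time scales are diffusive.
* PDB support covers CA-bead ATOM/MODEL records; alternate locations and
  insertion codes are passed through, not interpreted.
* Wall indentation supports flat plates only (no tip geometry).
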