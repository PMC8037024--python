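# Methods

## Fiber-lattice model of the ECM

Collagen-dominated ECM is modeled as a 2D triangular lattice with unit
nearest-neighbor spacing.  Site (a, b) sits at a·(1,0) + b·(1/2, √3/2);
the periodic box is the parallelogram spanned by nx·(1,0) and
ny·(1/2, √3/2).  Three straight fibers cross at every site.  Disorder is
quenched and two-fold:

* **Dilution** — each of the 3·nx·ny candidate bonds is kept with
  probability `pbond` (a proxy for collagen density).
* **Phantomization** — with probability `pphan` a site loses one
  cross-link: one of its three fibers, chosen uniformly, detaches and its
  two bond-ends move onto a phantom node co-located with the site.  The
  detached fiber keeps its own bending continuity through the phantom
  node but exerts no force on the crossing fibers.  Phantomization is
  applied on the full lattice first, independently of dilution, and
  conserves the bond count.

Counting bonds at the primary (cross-linked) node of each original site
gives the mean connectivity z = pbond·(6(1−pphan) + 4pphan); this
per-site primary-node convention is the only one that reproduces that
expression exactly, since phantom crossings contribute no cross-link.

Randomness uses common random numbers: one uniform per site for the
split decision, one per site for the fiber choice, one per candidate
bond for dilution, drawn in a fixed order independent of the probability
values.  Networks built from the same seed at different `pphan` (e.g.
different LOXL2 levels) therefore differ only where the probabilities
say they must, which makes paired stiffness comparisons and ratio maps
clean.

An open modeling choice: whether a site whose bonds are already diluted
can still be phantomized is not constrained by the connectivity law; we
phantomize independently of dilution, which is what makes the law exact.

## Elasticity and relaxation

The energy is E = Σ ½k(l_ij − 1)² over bonds plus Σ ½κθ²_ijk over bend
triples (consecutive colinear bonds of one fiber sharing a node), with
θ the signed deviation from colinearity computed from minimum-image
displacement vectors.  Defaults: k = 1, κ/k = 10⁻⁴ (thin-fiber limit);
both are exposed.  Shear strain enters only through the Lees–Edwards
image shift (the second box vector gains γ·h·x̂, h the box height), so
node coordinates stay in the unsheared frame and the area per period is
constant.

Relaxation minimizes E over free node positions with analytic gradients:
a short L-BFGS warm-up followed by damped Newton iterations on the exact
sparse Hessian (Levenberg regularization, Armijo backtracking),
converging on the **maximum per-node residual force** (default 10⁻⁸)
rather than energy change, which floppy modes render meaningless.  The
Newton stage is essential at κ/k ≈ 10⁻⁶: the soft-mode spectrum makes
quasi-Newton methods stall orders of magnitude above the true minimum.

Two numerical hazards of lattices of initially *straight* fibers are
handled explicitly:

* The affinely sheared configuration is always a stationary point
  (stretch relief by transverse buckling is second order), so an
  unperturbed minimization would sit on that saddle and report the
  affine modulus.  The initial guess is therefore perturbed by a small
  deterministic random displacement (amplitude ~0.3·√γ, capped at 0.03),
  and after convergence the state is kicked twice (5·10⁻³, 10⁻³) and
  re-relaxed, keeping the lowest-energy result.
* A fiber line that survives dilution around the periodic box is
  topologically taut under Lees–Edwards shear and contributes O(k·L/A)
  to G however floppy the rest of the network is.  On a 30-cell box at
  pbond = 0.9 about four such lines survive per realization, masking the
  floppy regime; at pbond = 0.8 the expected count is ~0.1.  The
  isostatic-sweep study condition is therefore pbond = 0.8, with pphan
  in [0.25, 0.75] spanning z in [3.6, 4.4] around the isostatic point.

G(γ) = (1/A)·d²E/dγ² is evaluated by a 3-point central difference of the
relaxed energy (δγ = 10⁻³ by default, 10⁻² in the floppy sweep where the
energies would otherwise sit at the convergence floor); each stencil
point is relaxed independently from the affinely sheared central
minimum.  A 5-point stencil is available near the numerical floor.

Bead microrheology uses fixed boundaries (a periodic network would
translate freely): the rim one lattice spacing wide is pinned, nodes
within the bead radius co-move rigidly with the bead (two extra degrees
of freedom), and a harmonic trap of stiffness k_trap drags the bead by
d_trap along ±x and ±y in turn.  The compliance is
J = ¼ Σ d_bead / [k_trap (d_trap − d_bead)] with displacements projected
on the pull axis.  Defaults: bead radius 1.2, k_trap = 1, d_trap = 0.02
(verified to be in the linear regime); probes are restricted to an inner
region (default 25% margin) to avoid rim artifacts.

## LOXL2 field

A spherical tumor of radius R holds its interior LOXL2 level at the
plateau c₀ = αρ/λ; outside, the steady diffusion–decay profile is
c(r) = c₀ (R/r) e^(−(r−R)/d) with d = √(D/λ).  This is the exact
solution of the exterior 3D problem with the plateau clamped at the
tumor boundary; it is *not* the flux-continuous solution of the
full-space source problem (the model neglects diffusive depletion of
the interior), and the test oracle solves the exterior Dirichlet problem
accordingly.  The field is spherically symmetric but evaluated on the
2D lattice plane through the tumor center.  Cross-linking maps
concentration to local phantomization as pphan(c) = pphan⁰/(1+(c/c_LP⁰)²).
Defaults used in the spatial studies — R = 10, λ = 0.1 h⁻¹, D = 40
(d = 20 lattice units), pphan⁰ = 0.8, c_LP⁰ set per study — are
illustrative; the spatial predictions are qualitative (a stiffened halo
extending ~d beyond the tumor boundary).

## Gene circuit

The core is the published microRNA-based ternary EMT switch: miR-200⊣ZEB
with ZEB self-activation and miR-34⊣SNAIL with the external signal I
activating SNAIL transcription.  MicroRNA action enters through binomial
binding-site occupancy M_i(u) with per-occupancy translation weights l_i,
active mRNA degradation γm_i, and microRNA co-degradation γu_i (6 sites
on ZEB mRNA, 2 on SNAIL mRNA).  All constants are the published defaults
(molecules and hours) and every one is overridable.  With these values
the baseline diagram has folds at I ≈ 42.4k, 51.6k, 58.5k, 65.1k
molecules: epithelial-only below 42.4k, a tristable E/hybrid/M window at
51.6k–58.5k, mesenchymal-only above 65.1k.

The extension adds dc/dt = g_LOXL/(1 + K_ZL/Z) − k_LOXL·c (Michaelis–
Menten activation of LOXL2 by ZEB, Hill order 1) and a mechanosensing
input I_ECM = g_ECM/(1 + (K_LE/c)^n_LE) added to I (additive coupling
into SNAIL only; multiplicative coupling was rejected because the total
EMT-inducing signal is the natural observable along migration paths).
The feedback constants are not fixed by data and were chosen once on
scale arguments: k_LOXL = 0.1 h⁻¹ (protein-like turnover) and
g_LOXL = 10⁴ h⁻¹ give a saturating LOXL2 level of 10⁵ molecules;
K_ZL = 2.2·10⁵ (the ZEB scale of the core model) separates the
epithelial (c* ≈ 4·10³) and mesenchymal (c* ≈ 7·10⁴) LOXL2 outputs by
~20×; g_ECM = 10⁵ makes a saturated mechanosensing signal comparable to
the full multistable range of I; n_LE = 4 encodes the sharp, switch-like
stiffness onset at the isostatic point (a high-order Hill); K_LE is the
swept control parameter (default 5·10⁴).  Only the ratio K_LE/c matters.

Steady states are found by multistart damped-Newton root finding (hybrid
Powell) from a 25-point grid spanning epithelial-like to mesenchymal-like
corners, deduplicated at 10⁻⁵ relative distance; stability is judged by
the Jacobian spectrum (max Re λ < −10⁻⁹).  Branches are traced by
pseudo-arclength continuation in scaled variables (each component divided
by its characteristic concentration; I divided by 10⁴) with adaptive
step, and a dense multistart I-sweep is retained as an independent check
of branch topology.  Saddle-nodes are located from tangent sign changes,
local extrema of I along the polyline, and stability flips, then refined
by Newton on the extended fold system [f = 0, Jv = 0, |v|² = 1]; refined
fold positions are reproducible to ~10⁻⁵ relative.  The strongest wiring
check is exact: at K_LE = 0 the system is the baseline translated by
−g_ECM in I, and at K_LE → ∞ it is the baseline itself.

## Migration

Cells leave the tumor edge r₀ = R radially at constant speed v through
the static field; the few migrating cells do not remodel the ECM, so the
feedback is severed and the LOXL2 level entering I_ECM is the local
field value c(r₀+vt) (the cell-intrinsic LOXL2 equation is not
integrated).  The core ODEs with I_tot(t) are integrated with LSODA.
MET is scored where ZEB mRNA first falls below 10% of its tumor-edge
value (the drop is a fold-crossing collapse, so the result is
insensitive to the exact fraction).  v is quoted in lattice lengths per
hour; the examples sweep v between 0.01 (quasi-static: the MET radius
converges to where I_tot(r) crosses the mesenchymal fold) and 0.2
(dynamical lag delays MET outward, never inward).

## What the synthetic conditions do and do not show

All inputs are generated; there is no external data.  The lattice
studies use 14–30-cell boxes — big enough to bracket the isostatic point
within ±0.15 in z but with finite-size rounding of the transition and
realization-to-realization scatter (hence medians over seeds).  The
circuit parametrization reproduces the topology of the published core
model, not fitted cancer data, so circuit results are structural
(ordering and movement of folds, hysteresis, monotonicities), not
digit-level predictions; the same holds for the spatial maps and MET
distances, which depend on the illustrative field defaults.  Real
collagen is 3D, viscoelastic, and remodeled by cells — none of which is
represented; the model's claim is that the isostatic-point mechanism
couples cross-linking to stiffness, and stiffness to cell state, in the
direction and order observed.

## Numerical defaults

| quantity | default | note |
|---|---|---|
| κ/k | 10⁻⁴ (10⁻⁶ in floppy sweeps) | thin-fiber bending |
| force tolerance | 10⁻⁸ k | max per-node force |
| δγ | 10⁻³ (10⁻² floppy sweep) | FD stencil |
| saddle kicks | 5·10⁻³, 10⁻³ | deterministic RNG |
| root dedup | 10⁻⁵ relative | steady states |
| stability threshold | Re λ < −10⁻⁹ | Jacobian |
| continuation step | 0.05 initial, ≤0.1 | scaled arclength |
| MET drop criterion | 10% of initial ZEB mRNA | insensitive |
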