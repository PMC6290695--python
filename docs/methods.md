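# Methods

`isrsim` couples three submodels into a two-dimensional, longitudinal-section
simulation of in-stent restenosis (ISR), and wraps the coupled simulator in a
quasi-Monte Carlo uncertainty-quantification (UQ) and Sobol
sensitivity-analysis (SA) layer.  This note records the model equations and
assumptions, the parameters that matter, the numerical choices, and the known
limitations — in particular what the desk-scale configuration used by the
test suite can and cannot show.

## Tissue mechanics

Smooth muscle cells (SMC), internal elastic lamina elements (IEL) and stent
strut elements are off-lattice soft discs.  For centre distance `d` and
contact distance `r_a + r_b` the pair force magnitude (positive = repulsive)
is

* Hertzian contact with an adhesive offset for overlapping discs
  (`delta = r_a + r_b - d > 0`):  `F = k_h delta^1.5 - a_c k_h`;
* a Hookean tether representing the extracellular matrix for separations
  `s = d - (r_a + r_b)` inside the tether range:  `F = -k_t s`;
* zero beyond the tether range.

An isolated pair therefore has the closed-form equilibrium overlap
`a_c^(2/3)` mm, which the test suite checks to 1e-8 mm.  The wall relaxes by
overdamped position updates (`dx = gain * F`, gain halved on residual growth,
per-step displacement capped at a fraction of the smallest radius) until the
largest residual force is below `equilibration_tolerance`; non-convergence is
flagged, not fatal.  Neighbour search uses a k-d tree with a safety margin so
the cached pair list is exact between refreshes; results are identical to an
all-pairs search (tested).

Boundary conditions: cells in the first and last columns are constrained
horizontally; the outermost SMC row of each wall rests on an elastic
foundation (a spring to its as-built position) standing in for the
surrounding tissue, which the model does not represent as agents.  Without
this support, growth pressure extrudes the wall out of the domain.

Stent deployment moves the square strut(s) outward in equal increments; after
each increment the struts are held fixed, forces are equilibrated, and
overloaded elements are removed, repeating relaxation and removal until the
configuration is stable for that strut position.  Removal criteria:

* SMC: contact stress (sum of touching-pair force magnitudes) above a
  threshold;
* IEL: contact stress, or chain strain (relative extension of the link to a
  chain neighbour), or bodily displacement from the as-built position above a
  displacement threshold.  The displacement criterion captures membrane tear
  under deformation that pure link strain misses: once a chain link breaks,
  the freed elements can rotate without stretching any link.  When an IEL
  element is removed its chain neighbours are re-linked across the gap with
  added rest lengths, so the surviving lamina still behaves as a membrane.
  The displacement criterion defaults to infinity (off) and is enabled in the
  calibrated presets.

Thresholds are calibrated once per preset so that the nominal 110 um
deployment ruptures the lamina near the strut without destroying the media;
deeper deployment never removes fewer elements (tested at 0, 0.07 and
0.13 mm).

## Growth dynamics

Stenting injury activates the SMCs beneath the longitudinal window of every
torn lamina element; activated cells (and their descendants) are synthetic —
they traverse the cell cycle and divide.  Cycle durations are drawn per cell
from Normal(32 h, 2 h) truncated to positive values; all cells start their
cycle simultaneously at the end of deployment.  A dividing cell places its
daughter one radius away at a uniformly random angle; a bounded local
relaxation (free zone around the daughters, fixed ring outside) resolves the
overlaps.

Two inhibition pathways stop growth:

* **Contact inhibition** — a cell with at least `contact_neighbor_limit`
  touching neighbours (contact slack `neighbor_tolerance`) is quiescent.
* **NO inhibition** — a cell covered by functional endothelium whose wall
  shear stress (WSS) is at or above `wss_no_threshold` is quiescent.  The
  threshold defaults to 85% of the unobstructed plane-Poiseuille wall stress,
  so covered cells in an open lumen are inhibited, and the WSS only rises as
  the lumen narrows at constant flux.  The endothelium is implicit — a
  coverage attribute of the SMCs, never revoked; because it is an attribute
  of the cell, its NO exposure persists when later growth buries the cell
  (the engine retains each covered cell's last known WSS).

Re-endothelialization follows a prescribed coverage schedule c(t): Scenario 1
rises to 59% in 3 days and then linearly to 1 at the uncertain total recovery
time T (15–23 days); Scenario 2 is linear from 0 to 1 at T.  Each uncovered
lumen-exposed cell becomes covered per step with probability
`p = max(0, (c(t+dt) - c(t)) / (1 - c(t)))` (p = 1 once c = 1), a thinning
process whose expected realized coverage of an always-exposed cohort tracks
c(t) exactly (verified by Monte Carlo against the binomial standard error).
"Lumen-exposed" is geometric: the cell's disc lies within one lattice spacing
plus one radius of its column's open lumen band and no lamina element sits
laterally between the cell and the lumen.

## Hemodynamics

After every growth step the agents are rasterized onto a uniform lattice
(node solid iff its centre is inside a disc).  The open lumen is the
mid-channel fluid run of each column, after a 3x3 morphological closing that
seals sub-node slits between touching discs.  Steady flow at constant flux
(the flux of the unobstructed vessel at the configured mean velocity) is
solved either by

* the reference D2Q9 BGK lattice Boltzmann solver — half-way bounce-back
  walls, an equilibrium parabolic-velocity inlet at the local density, an
  equilibrium pressure outlet anchored at rho = 1, initialized from a
  per-column Poiseuille guess; converged when the relative velocity change
  per check interval falls below 1e-6; or
* the quasi-1D lubrication mode — each column carries the plane-Poiseuille
  profile of its local gap at the target flux.  Exact for a straight channel
  and ~1000x cheaper; used for campaign-scale runs.

WSS is extracted at solid/fluid interfaces with the wall half a spacing from
the first fluid node and the two-point one-sided difference
`(9 u1 - u2)/(3 dx)` (exact for a parabola).  In a 50-node channel the LBM
profile matches plane Poiseuille within 2% and the developed-region wall
stress matches `6 mu U / H` (11.52 Pa at the reference parameters) within 5%;
the few columns next to the open ends carry local boundary-condition
artifacts and are excluded from that comparison.  Mass flux (the conserved
quantity of the weakly compressible scheme) matches between inlet and outlet
to 0.1%.

## Outputs

The lumen's mean width w (fluid nodes per column x spacing, averaged) is
reduced to the area of a circle of diameter w; the neointimal area is the
post-stenting baseline circle area minus that, floored at zero.  Restenosis
is declared when the final neointimal area exceeds half the original
(pre-stenting) lumen area — for a 1 mm vessel, about 0.39 mm^2.  If the
lumen closes, the run terminates with metrics held at their last values and
restenosis set.  Boolean lattice snapshots are stored weekly and at the final
time for the spatial products.

## UQ and sensitivity analysis

The simulator is a stochastic black box f(xi, x): x = (flow velocity in
0.432–0.528 m/s, deployment depth in 0.09–0.13 mm, regeneration time in
15–23 days), all uniform; xi = the run seed.  A campaign evaluates f on the
Saltelli design of M(2n+2) runs built from a single 2n-dimensional plain
Sobol' sequence (all-zeros point skipped), column-split into the A block and
its complement; per-run seeds are a splitmix64 hash of (seed root, block,
input index, row).  Estimators:

* coefficient of variation `CV = sd / |mean| * 100%`;
* aleatory variance `Var^T_xi = (1/2M) sum_j (f(x^j, xi^j) -
  f(x^j, xi^{j+M}))^2`, whose square root bounds the mean conditional
  aleatory SD from above (Jensen's inequality; equality for input-independent
  noise, verified against a nested double-loop Monte Carlo);
* first-order indices from `Var_{x_i} = (1/M) sum_j (f_A^j - f0)(f_FOi^j -
  f0)` with f0 the A-block mean, normalized by the A-block variance.
  Negative estimates are reported raw, never clamped;
* total indices from `Var^T_{xi,x_i} = (1/2M) sum_j (f_A^j - f_TOi^j)^2`;
  the TO block redraws the seed together with column i, so total indices
  include all interactions with the model's stochasticity.

Error bars come from a bootstrap (default K = 10,000) that resamples design
rows with replacement, keeping every block's row j together so the paired
estimators remain valid.  All estimators apply unchanged to scalars, to each
time point of the area series, and sitewise to lattice presence indicators
(the spatial variance/FOSI/TSI maps; sites with zero A-block variance are
masked).  Estimator correctness is validated against closed forms (additive
models, the Ishigami function) and against brute-force double-loop Monte
Carlo.

## The desk-scale configuration

`presets.porcine_default` is the full study geometry: a 1.5 mm section with a
1 mm lumen, five SMC layers per wall (cell radius 15 um), a 90 um square
strut per wall deployed 110 um, Re = 120 flow (mean 0.48 m/s, viscosity
4 mPa s, density 1000 kg/m^3) solved with the LBM, 30 days at 1 h steps.

`presets.coarse_demo` is the configuration the test campaigns run: a 0.8 mm
section, 0.7 mm lumen, three 20-um-radius SMC layers per wall, an 80 um
strut, 26 days at 4 h steps, lubrication flow on a 20 um lattice.  26 days
was chosen so the horizon spans the whole regeneration-time range (15–23
days): the run must outlast full endothelial recovery for the
regeneration-time input to express its effect, exactly as the full study's
horizon does.  A single run takes about two seconds, so the 5 x 64-run
acceptance campaign fits in minutes.

What the scaled configuration preserves: localized lamina rupture around the
strut, injury-driven activation, an oval neointima around the strut,
monotone growth that saturates as the endothelium completes, a strong and
monotone regeneration-time effect, a weak flow-velocity effect, coherent
aleatory/epistemic variance decomposition, and restenosis probabilities of
the right order.

What it does not preserve, and why passing tests do not certify it for real
data: with a lumen surface of only ~10 cells, the model's intrinsic noise
(cycle draws, division angles, coverage realization) contributes between
half and four fifths of the output variance — far above the 15–35% of the
full-scale study —
so sensitivity-index estimates at M = 8 are individually very noisy (the
acceptance check therefore asks only for a majority verdict over five
campaign seeds).  For the same reason the *shape* of the recovery schedule
(Scenario 1 vs Scenario 2) does not separate significantly at this scale:
growth is contact/mechanics-limited until coverage completes, so the
scenarios differ mainly through their common hard stop at T.  Demonstrating
the scenario contrast requires the full-scale configuration and
campaign-scale sampling.

## Numerical and design choices

* Time step 1 h (full) / 4 h (scaled); flow recomputed every step.
* Lattice spacing 10 um (full) / 20 um (scaled); width quantization is one
  node per column, and the area series is non-decreasing up to one lattice
  quantum.
* Deployment in 10 (full) / 5 (scaled) equal increments.
* Contact-inhibition neighbour limit 6 at 10% slack (full geometry default);
  the scaled preset uses limit 5 at 25% slack, calibrated once so that
  interior cells of the coarser packing are recognized as surrounded.
* Daughters are born uncovered; coverage is never inherited.
* The A/A' seed pairs, FO and TO blocks each use disjoint seed streams; any
  two distinct (block, i, j) triples get independent seeds by construction.
* Degenerate inputs: coincident agent centres raise an error; a fully
  occluded lumen raises a closure error inside the solver and ends the run
  gracefully in the engine; zero-variance outputs flag CV and all indices as
  undefined (NaN) rather than raising.

## Known limitations

* Two-dimensional longitudinal section; no curvature, no 3D effects.
* Steady flow only; no pulsatility or WSS reversal.
* Bare metal stent: the drug-elution pathway is a no-op.
* The adventitia is represented only as an elastic foundation.
* Mechanical parameters are in arbitrary consistent force units, calibrated
  for behaviour (rupture localization, wall integrity), not against measured
  wall properties.
* Desk-scale campaigns are qualitative echoes of the full study: headline
  numbers (mean areas, SDs, index values) are not expected to reproduce the
  full-scale campaign's values.
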