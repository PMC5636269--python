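# Model and methods

`tmesim` is a hybrid multiscale model of the tumour microenvironment: a 3D
on-lattice agent-based model (ABM) of cancer cells and CD8+ T cells with
PD1/PDL1 checkpoint interactions, coupled to a continuum IL-2
reaction-diffusion field, with downstream analytics for spatial
immuno-architecture, a rim-PDL1 response biomarker, simulated anti-PDL1
therapy, and LHS/PRCC global sensitivity analysis.  It is deliberately
phenomenological: it is not calibrated to a particular cancer type, and its
purpose is to generate and analyse qualitative behaviour — emergent spatial
patterns, treatment-response contrasts, monotone parameter effects — not
patient-level predictions.

## Lattice and agents

The domain is a cubic lattice of `N^3` voxels of 10 um (default `N = 100`,
a 1 mm^3 tissue block).  A T cell occupies one voxel (~10 um diameter), a
cancer cell an axis-aligned 2x2x2 block (~20 um).  Adjacency between agents
is the Moore (26-neighbour) relation between any voxel of one agent and any
voxel of the other; Moore adjacency was chosen over 6-connectivity for
isotropy of contact interactions.  Every voxel holds at most one agent.

Time advances in steps of `dt = 0.25 h`.  Each step executes a fixed
sub-phase order — recruitment, IL-2 secretion/diffusion/decay, contact
actions, divisions, migrations, deaths and clearance — with the agents
inside each sub-phase processed in a freshly shuffled uniform order, so no
agent is favoured by storage order.  All per-event probabilities are per
contact step; halving `dt` therefore changes per-hour hazards, and the
shipped defaults are stated at `dt = 0.25 h`.

### Cell states and rules

Cancer cells are `PDL1-`, `PDL1+` or `DEAD`; T cells are `EFFECTOR`,
`CYTOTOXIC` or `SUPPRESSED` (codes 1-6 in snapshots, 0 = empty).

- An effector T cell adjacent to a living cancer cell becomes cytotoxic
  deterministically (activation on first antigen encounter; no probability
  is attached because recognition of cognate antigen is assumed).
- A cytotoxic T cell makes one kill attempt per step against one uniformly
  chosen adjacent living cancer cell: success probability `p_kill_neg`
  against PDL1- targets, `p_kill_pos <= p_kill_neg` against PDL1+ targets.
  A successful kill marks the target `DEAD` (the block persists for
  `dead_clearance_time_h`, default 24 h, before its voxels free up).
- A PDL1- cancer cell surviving a kill attempt upregulates PDL1 with
  probability `p_pdl1_induction` — the inflammatory-microenvironment route
  to adaptive immune resistance.  PDL1+ is irreversible.  A config switch
  (`induction_on_contact`) instead conditions induction on mere contact.
- A cytotoxic T cell adjacent to a living PDL1+ cancer cell is suppressed
  with probability `p_supp` per step, independently of its kill draw.
  Suppressed cells never kill, divide or secrete; they still migrate and
  age out.
- Except for suppressed T cells and dead cells, agents divide once their
  cycle cooldown (`cancer_cycle_time_h`, `t_cell_cycle_time_h`) elapses and
  a free adjacent site exists (a free voxel for T cells; a free,
  non-overlapping, touching 2x2x2 block for cancer cells, chosen uniformly
  among free candidates).  Contact inhibition is implicit: fully enclosed
  cells cannot divide; a blocked attempt is retried after
  `division_retry_h` (default 1 h) rather than every step, which matters
  only for performance in crowded tumours.  T-cell division additionally
  requires local IL-2 at the cell's voxel to reach
  `il2_division_threshold`, and a T cell dies after
  `max_t_cell_divisions` divisions (replicative exhaustion) or at
  `t_cell_lifespan_h` (default 7 days).
- All living cells random-walk: each step an agent attempts
  `speed * dt / voxel` moves to uniformly drawn Moore-adjacent sites;
  a blocked move is forfeited.  The fractional part of the move budget is
  resolved stochastically, so the expected displacement rate equals the
  configured speed.
- Living cancer cells additionally carry a small spontaneous death hazard
  (`spontaneous_death_rate_h`, tumour turnover/necrosis).  This is not a
  cosmetic addition: dead cancer cells of any cause feed the antigen
  signal that drives recruitment, and without a non-immune death channel
  the immune response could never start from the tumour-only initial
  state.

### Recruitment and vasculature

Effector T cells enter at vasculature entry points.  Entry voxels are drawn
once per run: a voxel at depth `d` (Euclidean distance to the nearest
lattice face) is an entry point with probability
`base_entry_density * exp(-lambda_vasc * d)`; `lambda_vasc` spans
near-uniform (1/3200 um^-1) to boundary-only (1/25 um^-1) vascular
architectures.  Depth is measured from the static lattice boundary, not the
moving tumour surface.

The recruitment rate collapses lymph-node priming and trafficking into

    rate = r_base * k_a * (k_i * D) / (1 + k_i * D)   [arrivals / h]

where `D` is the cumulative number of dead cancer cells.  `k_a`
(mutational burden) acts as a capacity — more neoantigen clones mean
proportionally more recruitable specificities — while `k_i` (antigen
strength) is an affinity setting how small a dead-cell signal already
saturates the response.  Arrivals per step are Poisson with mean
`rate * dt`, drawn by inverse CDF from a dedicated uniform stream (which
makes cumulative arrivals pathwise monotone in the rate under a shared
seed, a property the tests exercise); each arrival lands on a uniformly
chosen unoccupied entry voxel, and arrivals finding no free entry voxel are
forfeited and logged.

### IL-2 field

Cytotoxic T cells secrete IL-2 (`secretion_rate_h` units/h into their
voxel); the field diffuses, decays and gates T-cell division.  The PDE
`dc/dt = D lap(c) - k c + sources` is integrated with an
alternating-direction-explicit (ADE) scheme: per substep one ascending and
one descending Saul'yev sweep are computed from the same state and
averaged.  Both sweeps are written in flux form — each interior face flux
appears once, implicitly for the already-visited side and explicitly for
the not-yet-visited side — so each sweep conserves total mass to machine
precision, and zero-flux boundaries are imposed by dropping boundary-face
fluxes.  Decay is applied as an exact `exp(-k dt)` factor per substep and
sources are added before diffusion (operator splitting: sources, then
transport).

Numerical behaviour: the scheme is von Neumann stable at any diffusion
number `alpha = D dt_pde / dx^2`, but it is positivity-preserving only for
modest `alpha`; `CytokineField.step` therefore refines the substep to keep
`alpha <= 1.8`, and the ABM coupling path floors rare negative ripples at
zero (the clipped mass is tracked and is orders of magnitude below total
mass).  The default parameterization is `D = 10 um^2/s` (hindered
interstitial diffusion of a 15 kDa cytokine), decay half-life 1 h, and ten
substeps per ABM step (`alpha = 0.9`).  Scaled scenario runs use an
effective `D = 0.1 um^2/s` with one substep per ABM step: what matters for
the division gate is the quasi-steady niche length `sqrt(D/k)` (~25-30 um,
matching the short range over which strongly consumed cytokines act), and
the slow-diffusion/slow-decay parameterization reproduces that length at a
hundredth of the PDE cost; the price is an hour-scale (instead of
minute-scale) equilibration lag, immaterial against 8-12 h T-cell cycle
times.

### Treatment

Anti-PDL1 blockade multiplies the suppression probability by
`(1 - m_supp)` from `start_day` on (`m_supp = 0.8`: an 80% reduction;
incomplete blocking stands in for redundant ligands such as PDL2).  Kill
probabilities against PDL1+ cells are not modified — the drug acts only on
the suppression channel.  Treated/untreated comparisons are run as coupled
pairs: one simulation advances to the treatment day and is then branched,
both arms inheriting identical RNG streams, so pre-treatment trajectories
are shared exactly.

## Spatial analysis

From a voxel snapshot, `L_raw = 1` wherever a cancer cell of any state sits
(a config switch excludes dead cells).  `L_smooth` applies an unweighted
3x3x3 moving average over the zero-padded volume with threshold 0.5;
since 27-voxel box sums are integers, the threshold is implemented as an
exact integer comparison (sum >= 14; the tie 13.5 is unattainable, making
the strict/non-strict choice observationally irrelevant).  Note the
zero-padding erodes structures touching the lattice faces — including the
corner voxels of an all-occupied lattice — which is a property of the
formula, not an artefact.

The tumour region is the complement of the face-connected background:
6-connected flood fill of `L_smooth = 0` voxels seeded from all lattice
faces; sealed cavities therefore count as tumour.  Three cross sections are
taken through `floor(N/2)` perpendicular to each axis.  Per section, the
distance map assigns each in-tumour pixel its Euclidean distance to the
nearest out-of-tumour pixel centre within that section (2D, centre-to-centre
convention; distances in um).  The rim at depth `t` is the set of in-tumour
pixels with distance <= t; rims nest monotonically, and because the minimum
in-tumour distance is one voxel, thresholds below 10 um select nothing.

## Biomarker and ROC

The rim-PDL1 score of a section is the fraction of living cancer cells in
the rim that are PDL1+; dead cells are excluded from numerator and
denominator.  A multi-voxel cancer cell intersecting the rim counts once
(agent counting, using the snapshot's id grid); voxel-weighted counting is
available as a switch.  A tumour's score is the mean over the (up to three)
sections with a non-empty rim; a tumour whose rims hold no living cancer
cell is flagged undefined and excluded from ROC analysis.  Outcome labels
come from the shrinkage ratio, the post/pre-treatment total living cancer
count ratio (1 equilibrium, 0 elimination, > 1 progression); the responder
cutoff (default: ratio < 1) is config-exposed.  ROC curves are standard
empirical curves with ties grouped and trapezoidal AUC; cohorts must
contain both outcome classes.

## Sensitivity analysis

`SensitivityDesign` draws a Latin hypercube sample (one point per
equal-probability stratum per parameter, independent column permutations,
uniform marginals on documented ranges), simulates each combination with
`n_replicates` seeds, averages replicate outputs (pooling is available),
and computes PRCC per parameter and output.  PRCC is the partial
correlation of rank-transformed columns, implemented in Schur-complement
form so it stays defined when the output is perfectly rank-correlated with
one parameter (the residual-free case yields 0 for the remaining
parameters); significance uses the t statistic with `n - 2 - (k - 1)`
degrees of freedom and the deliberately extreme flag threshold
`alpha = 1e-9` alongside raw p-values.  Failed replicates exclude their
sample and are logged in the provenance table.

## Calibrated defaults and scaled study conditions

No published per-event parameter table exists for this class of model at
this resolution, so every rate and probability is config-exposed with a
documented default, and the defaults were calibrated once so the model
reproduces the expected qualitative biology on the scaled lattice:

- baseline (k_a = 20, k_i = 0.1): T-cell arrival once the tumour is a few
  hundred cells (~day 10), slow-down of cancer growth, emergence of a
  PDL1+ front under immune attack, progression without treatment;
- treatment from day 20 (m_supp = 0.8): decline or elimination for
  high-burden tumours, continued growth at low burden, with the
  low-antigen-strength response weaker and later than the
  high-antigen-strength one.

The calibrated regime makes suppression the binding constraint untreated
(a cytotoxic cell near the PDL1+ front survives ~1.3 h) and lets blockade
lift it (5x longer engagement, above the IL-2-gated division threshold, so
the cytotoxic front sustains itself).  The separation between burden levels
comes from the recruitment capacity `r_base * k_a` interacting with the
nonlinear IL-2 division gate: twice the arrivals is the difference between
a self-sustaining and a collapsing cytotoxic front.

Scaled study conditions used by the tests and the acceptance script: a
50-voxel (0.5 mm) lattice for treatment scenarios (40-voxel for the
vasculature sweep), 35-day horizon with treatment at day 20, ten seeds per
condition.  These sizes were chosen as the smallest at which the quadrant
contrast and the rim-score geometry are cleanly expressed.

Two notes on emergent growth behaviour that shape the checks:

- Exponential law and crowding.  A tumour grown from one seeded cell is a
  compact ball, and its interior becomes contact-inhibited once the ball is
  a few hundred cells — at a few percent *global* occupancy, far below any
  fixed occupancy fraction.  The immune-free count therefore tracks
  `2^(t/c)` only over the pre-crowding range; the engine logs blocked
  division attempts, and the growth check uses the first blocked attempt as
  the crowding onset (through ~day 9 at a 24 h cycle, a 256-fold count
  range), verifying sub-exponential growth afterwards.
- Sensitivity screening conditions.  PRCC screens are run under conditions
  where the parameter can act: growth parameters (cycle time, cancer
  motility) immune-free with a pre-crowding readout; immune parameters
  (kill probability, T-cell motility) with an intensified recruitment
  setting (`r_base = 0.15`, spontaneous death 0.001/h, `p_kill_pos` fixed
  at 0.02 below the sampled `p_kill_neg` floor so every sampled
  combination is admissible) and a day-14 readout.  At the shipped default
  recruitment, killing barely begins by mid-run and its PRCC is
  indistinguishable from noise in small designs.

## What the synthetic data does and does not show

All inputs are generated by the simulator itself (plus hand-built phantom
volumes for the spatial pipeline), so passing tests demonstrate internal
consistency and the model's emergent qualitative behaviour — not agreement
with any patient dataset.  Real tumours differ in ways the model explicitly
omits: off-lattice mechanics and cell deformation, stromal and myeloid
populations, Tregs, nutrient/oxygen fields, dynamic vasculature and
perfusion, mechanistic receptor-ligand kinetics and PK/PD of the antibody.
The shrinkage-ratio endpoint is a cell-count ratio, not a RECIST-style
radiological response.

## Known limitations and numerical notes

- Determinism: identical seeds give bit-identical trajectories (a fixed
  per-subsystem stream layout; kernels consume pre-drawn uniforms).
  Changing the number of agents changes downstream draws, so parameter
  changes decorrelate trajectories quickly — coupled comparisons are exact
  only for shared prefixes (as in the paired-treatment design) or for the
  dedicated recruitment-count stream.
- The treated <= untreated suppression-count property holds pathwise only
  until trajectories diverge; over whole runs it holds in distribution and
  is tested over a set of seeds.
- Early stochastic extinction: a slow-starting tumour can be eliminated by
  the first T-cell wave before building a PDL1+ shield (~5-10% of seeds at
  high antigen strength).  Such runs are excluded from cohort outcome
  labelling (no pre-treatment tumour to score).
- At high occupancy the lattice cap (N/2 per edge for 2x2x2 cells)
  compresses count differences; scaled runs keep untreated endpoints below
  saturation by using a 40 h cancer cycle.
- The ADE solver trades grid-scale transient accuracy for stability at
  large substeps; its accuracy envelope is validated against a fine-step
  FTCS oracle in the tests.
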