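# Methods

`drgstim` simulates extracellular electrical stimulation of a dorsal root
ganglion (DRG): how epineural surface macroelectrodes and penetrating
microelectrodes recruit pseudounipolar sensory afferents. This note
documents the model, its assumptions, the parameters that matter, and the
choices made where the underlying literature leaves the design open.

## Volume conductor

The quasi-static potential obeys ∇·(σ∇φ) = 0 with a conductivity tensor σ
that is diagonal in the anatomical frame. The DRG is a prolate spheroid
(semi-major 3.7 mm along the longitudinal x-axis, semi-minor 1.5 mm) with
longitudinal/transverse conductivities 0.6 / 0.083 S/m; the dorsal and
peripheral roots are 0.75 mm-radius cylinders of the same tensor, wrapped
(with the spheroid) in a 20 µm epineurium (0.6 S/m); concentric cylinders
of intraforaminal tissue (3.25 mm, 0.25 S/m) and bone (17.2 mm, 0.02 S/m)
surround the structure, and the outer faces of the solved box are held at
0 V (the distant saline return).

The solver is a cell-centered finite-difference scheme with harmonic-mean
face conductances and conjugate-gradient iteration (Jacobi preconditioner,
relative tolerance 1e-8). The platinum contact is modelled as an
equipotential Dirichlet patch; the solution is rescaled so the net contact
current is exactly 1 mA, giving a transfer field in V/mA that is exactly
linear in the stimulus current. Fields are solved in two levels: a global
grid at 100 µm (box ±8 mm × ±5.2 mm², boundary inside the bone annulus)
and a locally refined 50 µm box around the contact whose boundary values
come from the global solution; the refined solution superposes a
contact-at-1-V solve and a boundary-driven solve, scaled to 1 mA net
current. The refinement matters most for the penetrating tip, whose 22.5
µm × 50 µm exposed contact is far below the global grid scale. Truncating
the bone annulus at the box boundary lowers the absolute potential scale
slightly; electrode *contrasts*, which all conclusions rest on, are
insensitive to this.

Solver accuracy is validated against an exact bounded-domain closed form:
the alternating method-of-images lattice sum for a point source in a
grounded box, coordinate-rescaled for anisotropy. Agreement is ~2% in the
band between 5 voxel lengths and a third of the box. The free-space 1/(4πσr)
law cannot hold literally near a grounded boundary (the image correction
is O(r/R)); it is verified on potential *differences*, which cancel the
boundary offset.

## Neuron models

Axons follow the MRG double-cable formulation: explicit node / MYSA /
FLUT / 6×STIN internodal segmentation, a periaxonal space under the myelin
with its own axial conductance, and myelin admittance scaled per lamella
(0.001 S/cm² and 0.1 µF/cm² per lamella membrane). Geometry at arbitrary
caliber comes from monotone cubic (PCHIP) fits through the nine published
MRG diameters, linear in diameter outside the tabulated range; the fits
reproduce every table knot to machine precision and stay within 10% of a
piecewise-linear interpolant.

Nodal membranes carry fast and persistent sodium (m³h and p³ gating), slow
potassium (s), fast potassium (n⁴, the sensory modification), and leak
(raised to 8 mS/cm², reversal −90 mV). The slow-potassium β rate uses
A = 0.06, which shortens the afterhyperpolarization to sensory values.
Internodal axolemma carries fast/slow potassium, leak and a small HCN
conductance. Rate constants are the published 36 °C MRG set plus a
Schwarz-type fast-potassium gate; the HCN gate is a generic slow
hyperpolarization-activated channel (half-activation −94 mV, τ = 100 ms,
E_h = −45 mV) — its role here is a weak inward conductance stabilizing the
internodal resting potential.

A pseudounipolar neuron is a tree rooted at the soma: soma (node-like,
diameter = length = 2.78 × fiber diameter, 300 channels/µm² of sodium
against the nodal 2000), a three-part unmyelinated AIS (6 µm proximal at
1000 ch/µm², 194 µm intermediate at 600, 1 µm distal heminode at 2000), a
stem axon of four internodal regions whose myelin ramps linearly from a
third of to the full lamella count, a t-junction node, and 50-node
peripheral and dorsal axon branches (dorsal caliber = 0.87 × peripheral).
The stem path including the AIS is exactly 784 µm for every cell size.
Axons of passage are unbranched 100-node chains.

### Unprinted constants and calibration

Several constants are not published anywhere in the source chain:
internodal potassium/leak magnitudes, the AIS/stem caliber, and the
soma/AIS leak reversal. These were calibrated once against the published
single-neuron validation table (the same quantities the acceptance suite
checks): FLUT/STIN leak 0.0005 S/cm², soma and AIS leak reversal −80 mV,
stem and AIS caliber 0.7 × the node-diameter fit. With that calibration
the model reproduces, at the protocol step of 5 µs: somatic AP amplitude
116.8/116.6 mV (printed 118.62/118.86), somatic AHP 3.5/3.4 mV (3.48/3.36),
axonal AP amplitude 104.3/104.3 mV (102.59/103.71), conduction velocity
33.8/84.2 m/s (33.09/81.95) for the 7.3/16.0 µm cells, and a CV–diameter
slope of 5.68 m/s/µm over 6–20 µm (R² = 0.998). The printed slope of 5.29
is lower than the slope implied by the two printed CVs themselves
((81.95−33.09)/8.7 = 5.62), so we report the computed value without
further adjustment.

The printed AP duration (0.71 ms for both cells) matches the base-to-base
width of our somatic spike — the interval the trace spends more than 1 mV
above rest — not its half-width (~0.26 ms); base-to-base is therefore the
default duration convention, with half-width available.

### Integration

Backward-Euler stepping at the 5 µs protocol step with Rush–Larsen
exponential gate updates (rates pre-tabulated on a 0.05 mV grid). Each
step solves the double-cable system exactly by Hines elimination on the
compartment tree with 2×2 blocks (intracellular and periaxonal
potentials); bare compartments (nodes, soma, AIS) have the periaxonal
potential clamped to the imposed extracellular value. The imposed
extracellular potential is applied at *every* compartment; a nodes-only
switch exists but raises axonal relative to AIS excitability and is not
the default. The resting state solves gate steady states at −80 mV and
relaxes for 20 ms (25 µs steps) before the 10 ms protocol window; resting
drift is below 0.1 mV over 10 ms for all calibers. Halving the step to
2.5 µs changes AP amplitudes by <2%; conduction velocity rises by ~4%
(propagation is the step-size-sensitive quantity), so CV values are
defined at the 5 µs protocol step.

## Populations

Fiber diameters are drawn from a lognormal distribution truncated to
[6, 20] µm (only Aα/Aβ calibers are modelled); the default shape
(µ = 2.26, σ = 0.25 in log-space) puts the mode near 9 µm. The Aα/Aβ
boundary defaults to 12 µm and only affects the per-type recruitment
curves, which are directional.

Three packing schemes: *realistic* (90% of somata in the outer annulus — a
cross-sectional angle uniform in (−30°, 210°), a longitudinal position
within ±2 mm, and a radial position beyond 2/3 (angles 30–150°) or 4/5
(otherwise) of the local DRG radius; 10% anywhere; somata oriented
outward with stems inward ±10°), *random* (volume-uniform somata,
isotropic stems), and *axon-only* (uniform axons of passage). Axon shafts
run parallel to the long axis from the t-junction. Placement is
rejection-sampled against soma–soma and soma–axon clearance (1 µm); the
number of passage axons in neuron-containing models defaults to 0.25 per
neuron, on the argument that each pseudounipolar cell already contributes
two shafts to the interior. Near the spheroid boundary the
rejection-on-out-of-volume rule necessarily depletes the random model's
soma density (stems must fit), so volume-uniformity holds — and is tested
— in the interior where every orientation is feasible.

The axon-only subsampling regions mirror the electrode geometries: a
800 µm-radius core for the penetrating electrode and the dorsal band above
537 µm for the epineural electrode (equal cross-sectional areas within
3%). The published approximate counts for the two regions (~7700 and
~6400) are mutually inconsistent under uniform placement — they imply
different total population sizes — so the generator is validated on
proportional scaling of both counts rather than the absolute pair.

## Stimulation and analysis

The protocol pulse is biphasic, charge-balanced and cathodic-leading:
80 µs at −A then 160 µs at +A/2, onset 1 ms into a 10 ms window; the
sampled net charge is exactly zero. Activation requires a propagating
spike: a 0 mV upward crossing plus at least five consecutive spiking nodes
of Ranvier along one axon branch. The initiation site is the earliest
crossing (ties: largest dV/dt, then lowest index) mapped to {AIS, stem,
t-junction, pseudounipolar axon, axon of passage}; somatic crossings are
never first in practice and would be surfaced as a diagnostic only.
Thresholds come from a bisection with geometric midpoints to a 1% bracket,
with the bracket established by a descending scan so that block at extreme
amplitudes cannot masquerade as activation failure; population sweeps are
ordered by electrode distance and warm-started. Fiber calibers are
quantized to 0.1 µm in population sweeps to cache compartment models and
resting states.

The similarity between two five-category initiation-site count vectors is
the coefficient of determination about the identity line,
S = 1 − Σ(N₂ᵢ−N₁ᵢ)²/Σ(N₂ᵢ−mean N₂)², which is 1 for identical vectors and
can be negative for divergent ones (an OLS-R² mode exists for comparison).
Recruitment curves accumulate activated cells on a 1 µA grid above the
electrode threshold; the dynamic-range slope is the least-squares slope
over the 10–90% span of the final count.

## Desk-scale study conditions

The full-size study (10 000–20 000 cells, 100 subsamples of 2500) is
represented at desk scale: 500 neurons per model, 20 subsamples of 250,
first-20 site vectors, and a 150-cell subset for the electrode-shift
comparison. At this scale the package reproduces: an epineural/penetrating
electrode-threshold ratio of ~10–17× (published ~10×), a wider epineural
than penetrating dynamic range in the realistic model, penetrating-
electrode similarity between random and realistic models above 0.8 with
epineural similarity strongly divergent (published 0.934 vs −0.633), Aα/Aβ
recruitment curves that overlap at all amplitudes, and shift stability —
epineural site patterns similar at all four electrode positions while the
laterally shifted penetrating electrode diverges sharply.

## Known limitations

* **AIS-dominant epineural initiation is not reproduced.** In the source
  model the first cells recruited by the epineural electrode in the
  realistic DRG mostly initiate at the AIS. In this implementation the
  unmyelinated AIS, built strictly from the printed channel densities and
  geometry with standard MRG conventions, has an extracellular threshold
  ~5–8× that of a myelinated axon at comparable distance, so low-threshold
  epineural recruitment is dominated by axons. Every calibration that
  closes the gap (raising the AIS resting potential or caliber) pushes
  several validation-table metrics outside their bands; we chose the
  validation table. The directional contrasts (epineural recruits more
  AIS than penetrating; penetrating recruitment is t-junction/axon
  dominated; somata never initiate) are reproduced.
* Absolute population thresholds are several-fold higher than the
  published ones at matched electrode for the same reason; electrode
  ratios and orderings are preserved.
* Straight axon trajectories and in-plane stems; no glomerular winding, no
  stem wrapping of the soma, no Aδ/C fibers, no frequency-dependent tissue
  properties, no electrode–electrolyte interface.
* The synthetic populations idealize real DRG tissue (hard-sphere somata,
  parallel shafts, no somatotopy); passing the population tests shows the
  pipeline reproduces the published model-level contrasts at reduced
  scale, not that it predicts any particular animal's anatomy.
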