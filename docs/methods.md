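# Methods

`skingetsim` simulates gene electrotransfer (GET) to skin: it predicts which
tissue volume a pulse-delivery protocol electroporates reversibly (the
useful regime, where plasmid DNA can enter surviving cells) and
irreversibly (collateral damage), and compares electrode-commutation
protocols on those two competing criteria.

## The tissue model

The skin is modelled as eight plane-parallel layers — stratum corneum,
epidermis, papillary dermis, upper vessel plexus, supply layer, deeper
vessel plexus, hypodermis, muscle — totalling 27.35 mm.  Each layer carries
a diagonal conductivity tensor σ0 = (σx, σy, σz); the stratum corneum is
strongly anisotropic (σz ≈ 2.2·10⁻⁴ S/m, fifty-fold smaller than lateral)
and is the dominant barrier to current entering the skin.  Each layer has a
reversible-electroporation (RE) threshold and an irreversible (IRE)
threshold, in V/cm converted internally to V/m, and a maximal conductivity
increase (100× for the stratum corneum, 3.5× for the soft-tissue layers,
2.5× for muscle).

Electroporation feeds back on the field: the conductivity scaling factor is
a sigmoid of the local field magnitude,

    f(E) = 1 + (f_max − 1) · g(t),   t = (E − E_re) / (E_ire − E_re),

with g an endpoint-normalised logistic of steepness k (default 10), t
clamped to [0, 1].  f equals 1 exactly at and below the RE threshold and
f_max exactly at and above the IRE threshold, with f = (1 + f_max)/2 at the
band midpoint.  The normalisation (rather than a raw logistic) was chosen
so that the baseline and saturation values are exact, which the raw
logistic misses by ~0.5 % at k = 10; the steepness and centering within the
RE→IRE band are modelling choices, not published values.

Muscle is fibered (fibers along the axis of its largest conductivity
component, y): its RE threshold is 80 V/cm for fields parallel to the
fibers and 200 V/cm perpendicular, interpolated elliptically,
E_th(θ)⁻² = (cos θ/E_par)² + (sin θ/E_perp)² — the simplest smooth rule
honouring both endpoints.  Its IRE threshold (800 V/cm) is
direction-independent.  The conductivity increase is applied as an
isotropic scaling of the (possibly anisotropic) σ0 tensor, since a single
maximal increase per layer is specified.

## Electrode arrays and protocols

Three applicators are modelled as disc-shaped surface contacts:

- **hex6** — six rod electrodes on a regular hexagon, opposite-centre
  distance 9 mm (circumradius 4.5 mm), contact radius 1.0 mm.  The radius is
  the unique value consistent with both published spacings: a 4.5 mm
  hexagon side minus two 1.0 mm radii leaves the stated 2.5 mm adjacent
  edge-to-edge gap.
- **hex7** — hex6 plus a central electrode.
- **mea6** — six pins at 3.5 mm centre-to-centre spacing (read as
  centre-to-centre), default pin radius 0.35 mm, both configurable.

Protocols are ordered anode/cathode activation steps, each immediately
followed by its polarity reversal:

- **classical** (hex7): all twelve adjacent pairs — six rim–rim, six
  rim–centre — ×2 polarities = 24 steps.
- **alternative** (hex6): the six rim pairs ×2 polarities, then pulses
  between two opposite *pairs* of electrodes — a pair of adjacent rim
  electrodes energised together against the diametrically opposite pair —
  three such oppositions ×2 polarities, 18 steps in total.  An alternative
  reading (single-electrode diagonals, also 6 steps) is available via
  `diagonal_mode="single"`; it was rejected as the default because it fails
  to compensate for the missing central electrode — in simulation it yields
  a *smaller* reversibly electroporated volume than the classical protocol,
  the opposite of the protocol's design intent, while the pair-versus-pair
  reading enlarges it.
- **mea_lv** (mea6): the six rim pairs ×2 polarities, 12 steps.

Default pulse trains: hex protocols 560 V, 4 × 100 µs pulses per burst at
5 kHz, bursts at 50 Hz; MEA low-voltage 60 V, one 150 ms pulse per step at
2.82 Hz.  Trains can be validated against the pulse generator's envelope
(80–600 V, 10–1000 µs, 0.1–5000 Hz, bounds inclusive); the MEA train
deliberately fails it, as it targets a different generator.  All steps of
both hex protocols use the same 560 V in simulation; whether the classical
protocol's reference simulations used a different amplitude is unpublished,
so equal amplitude (the device's output) is the default assumption.

Step ordering follows rim pairs clockwise with immediate polarity reversal,
then the cross-array steps.  In the stationary-sequential model the final
envelope is insensitive to step order (tested); ordering is preserved for
protocol export.

The skin-contact detector is a three-way impedance classifier with
configurable bounds (defaults 100 Ω and 10 kΩ — plumbing values, not
published).

## Field solver

Each step solves the stationary current-conservation equation
∇·(σ(E)∇φ) = 0 with Dirichlet potentials on the active contact discs
(amplitude on anodes, 0 on cathodes) and zero normal current elsewhere.
The lateral extent (default 30 mm) is chosen so the insulating boundary has
negligible influence on the metrics.

Discretisation is cell-centred finite volume on a structured grid: uniform
x/y, z graded so every layer interface is a grid line and the 20 µm stratum
corneum keeps ≥ 2 cells.  Face conductances use distance-weighted harmonic
averaging, which keeps the normal current density continuous across layer
interfaces and reproduces the 1D series-resistance solution exactly on
layered slabs (validated to < 1 % against closed forms; parallel-plate
fields to < 0.1 %).  Cell fields are recovered from face current densities
(E = J/σ per cell), not from potential differences, for the same reason.

The within-step nonlinearity is a damped Picard fixed point: solve → recover
|E| → σ from the sigmoid evaluated at max(envelope, |E|) → re-solve, with
mixing parameter 0.5 on the conductivity factor, until the maximum change
of |E| falls below 10⁻³ of its peak (≤ 50 iterations).  Cells sitting on
the steep part of the sigmoid can lock into a period-2 limit cycle under
fixed mixing; when the residual stalls the mixing parameter is halved
(floor 0.05), which restores contraction.  Non-convergence is flagged on
the solution, not raised.

Linear systems are solved by conjugate gradients preconditioned with a
z-line block-Jacobi preconditioner (one tridiagonal block per vertical cell
column, solved by a batched Thomas algorithm).  Cells are much thinner than
they are wide, so vertical coupling dominates the stencil by orders of
magnitude — including the extreme stratum-corneum contrast — and the
remaining lateral problem is mild.  Solves are warm-started across Picard
iterations; relative tolerance 10⁻⁹ keeps electrode-current imbalance
below 10⁻⁸.

**Sequential electroporation memory.**  The protocol is modelled
stationarily and sequentially: after each step the per-voxel *field
envelope* absorbs the converged |E| (a running maximum, with the field
direction at the maximum retained for muscle's directional threshold), and
the conductivity everywhere is recomputed from the envelope.  A region
permeabilised by any pulse therefore stays conductive for all later
pulses.  A step that exactly reverses the previous step's polarity is
reproduced analytically: for any fixed σ, φ' = U − φ solves the reversed
problem, so |E| is identical and the envelope cannot change; this exact
shortcut halves the number of nonlinear solves and is verified against the
full solve in the tests.

## Volume metrics

A voxel is IRE when its envelope reaches the layer's IRE threshold, and RE
when the envelope lies between the (direction-dependent, for muscle) RE
threshold and the IRE threshold.  The reported RE volume excludes IRE
voxels by default — the two quantities are competing design criteria — with
an inclusive variant available (`inclusive_re=True`); which definition the
reference comparison used is unpublished, so both are provided.  Volumes
are sums of voxel volumes; the RE depth is the largest voxel-centre depth
of any RE voxel.  Protocol comparisons report
100·(RE_alt − RE_cls)/RE_cls and 100·(IRE_cls − IRE_alt)/IRE_cls with the
classical protocol as baseline.  Horizontal field slices (e.g. 2 mm below
the surface, in the hypodermis where the immune cells targeted by GET
reside) and vertical mid-plane slices, optionally log-transformed, support
visual inspection.

## Grid presets and problem sizes

| preset  | lateral cells | z cells | total cells | use |
|---------|--------------|---------|-------------|-----|
| tiny    | 21 × 21      | 16      | ~7 k        | smoke tests only |
| coarse  | 33 × 33      | 30      | ~33 k       | quick runs, examples |
| default | 51 × 51      | 41      | ~107 k      | reported volume metrics |
| fine    | 69 × 69      | 55      | ~262 k      | resolution checks |

The default preset resolves the 1 mm contact discs by ~9 cells and is the
scale at which the protocol-comparison percentages are evaluated; a paired
classical+alternative run takes a few minutes on one CPU.  The tiny preset
is below the resolution at which the RE-volume comparison is meaningful
(the sign of the few-percent difference is not resolved there); the coarse
preset resolves the direction but not the percentages.

At the default preset the simulated alternative protocol yields ~10 %
larger RE volume and ~16 % smaller IRE volume than the classical protocol
(recomputed by `scripts/acceptance.py`), with the irreversible damage most
concentrated — as a fraction of each layer's volume — in the stratum
corneum within one contact radius of the electrodes.  The unpublished
degrees of freedom (mesh, domain extent, contact radius, classical-protocol
amplitude, RE-volume definition) make exact reproduction of reference
percentages impossible in principle; the directional result is robust
across resolutions from coarse upward.

## Fluorescence quantification

Transfection images are quantified as in the standard FIJI workflow: pixels
strictly above a fixed threshold form the transfected area; the integrated
density is area × mean supra-threshold intensity (zero area ⇒ zero mean by
convention).  The threshold is a user input applied identically to all
images of a comparison; its published value is not stated, so none is
hard-coded.  Multi-channel images default to the green (EGFP) channel.  The
synthetic generator (Gaussian blobs plus folded-normal background noise,
fully seeded) emulates a single bright expression region over detector
noise; it does not emulate autofluorescence gradients, fur artefacts, or
vignetting, so passing tests demonstrate the arithmetic of the metrics, not
robustness to real-world image defects.

## Known limitations

- Stationary model: no µs-scale membrane charging, no Joule heating, no
  electrochemistry, no pore dynamics.
- Electrodes are flat surface discs; rod penetration into a gel layer is
  not modelled (an optional gel layer can be added to the stack by config).
- Layers are laterally homogeneous slabs of infinite extent within the
  domain; no appendages (follicles, glands) that locally short the stratum
  corneum.
- The voxel→layer map uses voxel centres; sub-voxel threshold crossings are
  not interpolated, so volumes carry O(voxel) quantisation, visible as ties
  in the maximal-RE-depth metric at coarse resolutions.
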