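# Methods

## Model overview

`angiosprout` simulates sprouting angiogenesis from cultured endothelial-cell
aggregates on a 2-D lattice.  Each lattice site holds at most one
endothelial-cell (EC) agent; each agent integrates a deterministic ODE model
of its own signaling state, and agents interact through two channels:
juxtacrine Dll4-Notch1 ligand exchange with their Moore (8-site) neighbors,
and uptake/secretion of diffusible molecules — extracellular VEGF-A, soluble
VEGFR1 (sVEGFR1), and the sVEGFR1·VEGF complex — represented as lattice
fields of particle counts per site.

The tip/stalk decision is emergent.  VEGF-A activates VEGFR2; active VEGFR2
drives `dll4` transcription; Dll4 presented to a neighbor releases that
neighbor's Notch intracellular domain (NICD), which activates `VEGFR1`
transcription and represses `VEGFR2` transcription.  This closes the
classical lateral-inhibition loop: a cell that gets ahead suppresses the
same fate in its neighbors.  Two refinements known to matter for the
sharpness of the switch are included: cis-inhibition (Dll4 binding Notch1 on
the same cell into an inert complex, rate `kc`) and transcriptional
auto-activation of `notch1`.

A cell becomes a **tip cell** when all three hold strictly:
`vegfr2_mRNA > vegfr1_mRNA`, `filopodia > A*`, and `dll4_mRNA > D*`.
Tip cells chemotax up the VEGF-A gradient; the vacated site is refilled by a
copy of a random non-tip neighbor (stalk proliferation), which keeps every
sprout 8-connected to its aggregate of origin.

## Intracellular signaling

The single-cell network is loaded from a model description
(`models/intracellular.yaml`, also exportable/importable as SBML Level 3)
with 21 species — 14 integrated per cell plus 7 boundary species
(extracellular VEGF, neighbor Dll4, extracellular sVEGFR1 and its VEGF
complex, the culture-medium reservoir, and source/sink pseudo-species) — and
43 parameters.  Transcription follows Hill laws

    v = V_max * (1/a + (1 - 1/a) * mod^h / (mod^h + M0^h))

with fold change `a`, half-activation amount `M0`, and exponent `h = 2`
throughout; repression uses the mirrored decreasing form (same basal and
maximal bounds), and when a transcript has two regulators (NICD and notch1
auto-activation on `notch1_mRNA`) their fractional activities multiply.
All other reactions — translation, degradation, Dll4-Notch1 binding in cis
and trans, VEGF association/dissociation of mVEGFR1/sVEGFR1/VEGFR2, and
sVEGFR1 export — are mass action.  VEGFR2 bound to VEGF converts to
VEGFR2-active on dissociation; VEGFR2-active relaxes back to the free
receptor pool at `k_act_decay` (first-order), which keeps receptor mass
bounded.  The sVEGFR1·VEGF complex can dissociate and release VEGF in active
form.  The cis complex is inert and only degrades.

Amounts are particle numbers per cell; per-cell VEGF input is the total VEGF
within the cell's sensing window, so receptor binding competes directly with
the local field content.

### Numerics

The per-cell ODE advances by forward Euler.  Two guards make the explicit
scheme safe with counts:

* **Sub-stepping** — a candidate step that would change any variable above
  a floor of 1 particle by more than 25% is halved, down to at most 2^-14 of
  the outer step; successful sub-steps re-double.
* **Extent clipping** — if a step would drive a variable negative, the
  extents of reactions consuming it are scaled so consumption never exceeds
  availability, then the step is applied and clamped at zero.

The integrator also tracks exchange fluxes (net VEGF uptake, neighbor Dll4
consumed by trans binding, sVEGFR1 exported) so the engine can book them
against the fields and neighbors conservatively.  Euler trajectories
converge at first order to stiff reference integrations on fixed test
systems (see the test suite), and a coarse-step trajectory agrees with a
100x-finer one to within a few percent per variable.

## Extracellular fields

Fields evolve by an explicit 5-point diffusion stencil with Dirichlet
boundaries, sub-stepped so the stencil weight `D*dt/dx^2` stays at or below
0.25.  The boundary value is the medium VEGF reference for VEGF-A (the rim
abuts bulk medium) and 0 for sVEGFR1 and its complex.  Within one outer step
the field update order is fixed: diffuse, react (sVEGFR1·VEGF binding),
degrade, replenish.  VEGF replenishment relaxes each site toward a constant
medium reference (the culture medium is effectively renewed), with a signed
flux so sites above the reference lose molecules.

Defaults (config values; sites are 10 um): VEGF `D` = 50 sites^2/h, sVEGFR1
and complex `D` = 25 sites^2/h, degradation 0.02/0.1/0.2 per h, reference
44 particles/site, influx 0.03/h.  The slow influx is what lets the growing
network deplete its surroundings: membrane-bound VEGFR1 and secreted sVEGFR1
carve VEGF-poor corridors around existing cells, which both throttles total
sprouting and pushes tips outward, away from the network.

## Agents and scheduling

One outer step (default 0.5 h) updates the fields, then visits every agent
in a fresh uniformly random permutation.  Each agent, in order: integrates
its signaling using the current VEGF window total and neighbor Dll4 (each
neighbor's ligand divided by that neighbor's occupied-contact count);
applies its exchange fluxes to the world; updates filopodia (extend at 0.4
sites/h while VEGFR2-active exceeds its setpoint of 130, retract at 0.2
sites/h otherwise, clipped to [0, 4]); re-evaluates its phenotype; and, if a
tip, attempts a move with probability `1 - exp(-move_rate*dt)`
(`move_rate` = 0.45/h).  Because agents read the world as already modified
by earlier agents in the permutation, information propagates within a step
and the permutation order is itself a noise source.  A single seeded PCG64
stream drives sampling, permutations, and movement, so a run is
bit-reproducible from `(config, seed)`.

Movement: the tip's target is the gradient direction (slope averaged over
the sensing radius, distance-normalized, ties broken uniformly; a flat
neighborhood gives a uniformly random direction) with a `p_dev` = 0.3 chance
of deviating 45 degrees clockwise and the same counter-clockwise.  A move
into an occupied site or off the grid simply fails — a tip meeting another
sprout stalls against it; no explicit fusion event is modeled.  The stalk
copy placed into the vacated site inherits the parent's instantaneous
signaling state but draws fresh per-cell parameters.

## Per-cell parameter sampling

Cellular heterogeneity comes from per-cell sampling of three parameter
groups: transcription `V_max` ("tc"), translation rates ("tl"), and the NICD
degradation rate ("nicd_deg").  Each sampled parameter is drawn from a
log-normal law moment-matched so the distribution's mean is the configured
mean and its SD is `(SD/mean) * mean`; the packaged calibration uses
SD/mean = 0.55 for all three groups.  Entity-specific constants (binding
affinities, fold inductions, `M0` values) are never sampled.  Sensitivity
sweeps pin the swept parameter to one value for every cell (exempting it
from sampling), reproducing the distinction between varying a parameter's
magnitude and varying its cell-to-cell spread.

## Initial conditions and scenarios

Runs start from two filled discs of radius 4 at 1/4 and 3/4 of the grid
width (mimicking two plated embryoid bodies) on a 100x100-site lattice
(1x1 mm at 10 um/site); a single central aggregate is a config option.  The
initial cell state is the quiescent, stalk-like base state of the
calibration: NICD high (400), `VEGFR1` mRNA high, `VEGFR2` mRNA low — cells
must *escape* basal lateral inhibition, via sampled-parameter heterogeneity
and asynchronous-update noise, before they can sprout.  The default
simulated time is 199 h with snapshots at 60, 90, 120, 192, and 199 h.

The `vegfr1_ko` scenario sets the mean of `vmax_tc_vegfr1` to zero for all
cells: no membrane or soluble VEGFR1 is produced, the `vegfr2_mRNA >
vegfr1_mRNA` tip criterion is trivially satisfied once transcripts decay,
and no VEGF-depleting corridors form — the knockout overgrows.

## Calibration

The calibration was built in three stages, mirroring how such models are
usually parameterized when no single-cell rate measurements exist: (1) the
single-cell system was tuned to show distinct tip-like (high VEGFR2, high
Dll4) and stalk-like (high VEGFR1, repressed VEGFR2) steady states under
constant inputs; (2) the two-cell and ring systems were tuned until the
symmetric state is linearly unstable, so a 1% perturbation resolves into
alternating fates; (3) the behavior, medium, and transport parameters were
tuned at the full-lattice level against the study-level outputs (relative
vessel area of wild-type and VEGFR1-knockout cultures, and the shape of the
parameter-sensitivity and heterogeneity responses).  All rates lie in
ranges typical for mammalian transcription/translation/degradation
kinetics (minutes-to-hours timescales) and VEGF receptor biology (VEGFR1
binds VEGF with higher affinity than VEGFR2; decoy binding is
non-signaling).

Under this calibration, five-replicate means land near 14-19% relative
vessel area for wild type (observed mean 17.2% in embryoid-body cultures),
45-57% for the VEGFR1 knockout (observed 55.1%), and 45-52% for the
zero-VEGFR1-transcription sweep endpoint at 192 h.

### Known limitation: branch-point density

Skeleton-based branch analysis (binary closing with a 3x3 element,
skeletonization, junction pixels merged into 8-connected clusters counted
once, length as 1 per orthogonal and sqrt(2) per diagonal skeleton
adjacency, calibrated by `dx`) yields 4-5.5 branch points per mm vessel
length for wild-type networks under any setting of this calibration that
keeps the vessel area in its observed range — junctions every ~200 um
rather than the ~100 um reported for embryoid-body cultures.  This appears
structural: sprouts are one site wide (the copy-on-move rule cannot thicken
or remodel them), side branches shorter than the closing scale are erased
by the smoothing, and merged junction clusters at the aggregates count
once.  The branch-density metric should therefore be read as a relative
measure between conditions (it does track the vessel-area trends), not as
an absolute match to image-analysis pipelines.

## Scaled-down experiment sizes

The packaged experiment drivers default to the full protocol (20 replicates)
but every driver takes replicate counts and lattice sizes as arguments.  The
shipped test suite and the reproduction script use 5 replicates at the
default 100x100 lattice for the scenario comparison, and 60x60 or 48x48
lattices with 2 replicates per point for sweep-shape and heterogeneity
checks.  These sizes were chosen as the smallest at which the qualitative
patterns are stable across seeds; absolute areas on the small lattices run
slightly higher than on the default lattice because the seeded aggregates
occupy a larger fraction of the arena.

## What the fixtures do and do not show

The ring fixtures (`two_cell`, `ring_n`) couple static cells through the
Dll4-sharing rule under clamped VEGF — they isolate the lateral-inhibition
circuit from movement, transport, and heterogeneity, and are the right
object for patterning and knockout-of-`kt` tests.  They do not exercise
VEGF competition or the asynchronous scheduler.  The synthetic vessel masks
used by the metrics tests are built junction-by-junction, so junction counts
are known by construction; they validate the skeleton pipeline, not the
biology of branching.
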