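# Methods

## Scope and units

`memassoc` analyses ensembles of coarse-grained protein/bilayer
trajectories and generates synthetic ensembles to validate that analysis.
Internally all lengths are nm (native to GRO) and all times ns; `t=`
tokens in GRO titles are picoseconds and converted on read.  Literature
thresholds quoted in ångström are stored in nm (6 Å → 0.6 nm); reports can
print both.  Only orthorhombic boxes are supported: the systems this
pipeline targets are rectangular, and triclinic input is rejected rather
than silently truncated.

## Contact and event definitions

A snapshot is a **contact** when the minimum protein–membrane bead
distance is *strictly* below the threshold (default 0.6 nm); a snapshot at
exactly 0.6 nm is not a contact.  The membrane selection for this global
criterion is all lipid beads by default (`contact_lipid_beads="head"`
restricts it to head-group beads).  An **insertion event** is the first
run of `insertion_run_length` (default 3) successive snapshots with the
anchor residue in membrane contact.  The event time is reported as the
*first* snapshot of the qualifying run; the phrase "the first time the
interaction was observed in N successive snapshots" can also be read as
the run's last snapshot, so `insertion_report="run_end"` is available.
Anchor contact for insertion is evaluated against **all** lipid beads; the
head-group restriction applies only to residue contact probabilities,
where it is explicit in the definition.

Trajectories are classified `inserted` (insertion event present) >
`contact_only` (≥ 1 contact) > `no_contact`.

## Snapshot bookkeeping

Analysis snapshots are the frames nearest to `interval, 2·interval, …` up
to the final frame time.  The grid starts at `t = interval`: the t = 0
initial structure is not an analysis snapshot, so a 1-μs trajectory at a
2-ns interval yields exactly 500 snapshots, not 501.  Ties between equally
near frames resolve to the earlier frame; a source frame is never selected
twice; requesting an interval finer than the native spacing is an error
(no upsampling).

## Ensemble curves

`cumulative_contact(t)` is the fraction of trajectories with any contact
at a snapshot ≤ t.  The **subtotal** at t is the fraction with a contact
in the half-open trailing window (t − W, t], W = 10 ns by default — i.e.
the last `W/Δt` = 5 snapshots including t, so each snapshot contributes to
exactly `W/Δt` windows.  `cumulative_inserted(t)` counts trajectories with
insertion at a snapshot ≤ t, normalised either over the inserted subset
(default, matching how insertion-ratio curves are usually drawn) or over
the full ensemble (`inserted_denominator="all"`).

## Distance kernel

Minimum distances use the minimum-image convention on all three axes of
the orthorhombic box.  The fast path wraps coordinates into the primary
cell and queries a `scipy.spatial.cKDTree` built with periodic `boxsize`;
an all-pairs broadcast scan is kept as the independent reference, and the
two are held to agreement within 1e-9 nm in tests (observed disagreement
is at machine precision, ~2e-15 nm).  Because distances are periodic in z
as well, the generator keeps a clearance margin below the box top so that
no spurious through-boundary protein–tail contact can occur.

## Residue contact probabilities

For a phase window — `after_insertion` (snapshots ≥ insertion, inserted
trajectories only), `before_insertion` ([first contact, insertion) of
inserted trajectories) or `after_first_contact` (snapshots ≥ first
contact, any contacting trajectory) — the probability of residue r is the
pooled, snapshot-weighted ratio: contacts of r with head-group beads
(C1A, C1B, NH3, PO4; same 0.6 nm threshold, independently configurable)
divided by total pooled window snapshots.  Pooling weights trajectories by
their window lengths; `weighting="per_trajectory"` averages per-trajectory
probabilities instead.  An empty pooled window (e.g. `after_insertion`
with zero inserted trajectories) raises an error rather than returning a
deceptive all-zero profile.  The `before_insertion` and `after_insertion`
windows of one trajectory are disjoint and partition
[first contact, end).

There is no canonical numeric cutoff for calling a residue part of the
binding interface; `high_contact_residues` therefore takes the cutoff as
an explicit argument (the pipeline default is 0.5).

## The synthetic generator

The generator is a phenomenological Brownian-dynamics surrogate, not a
re-implementation of a bead force field: thermostats, barostats, elastic
networks and lipid dynamics are out of scope.  It reproduces the
*observable event structure* of an anchored-protein simulation with exact
ground truth, which is what validating the analysis requires.

**Membrane.**  A static single leaflet: lipids on a jittered square
lattice at the default areal density of ~410 lipids per 11 × 11 nm (per-
lipid jitter ≤ 5% of the lattice spacing, so lipid centres stay ≥ 0.8
spacings apart).  Each lipid has four head beads (NH3, PO4, C1A, C1B)
within ±0.2 nm of the surface plane and eight tail beads below it.  One
leaflet suffices because the protein only ever touches one; solvent is
implicit.  At this density any point on the surface plane is within the
contact threshold of some head bead, which guarantees that a pinned anchor
stays in permanent head-group contact.

**Protein.**  A rigid bead cloud (two beads per residue, 163 residues by
default, radius of gyration rescaled exactly to its 2.0 nm target) built
from a fixed-step random walk.  Dimer mode appends a second copy rotated
180° about the anchor with the two anchor residues adjacent, standing in
for a disulfide-linked dimer.  Initial orientations are uniform random
rotations — the distribution of starting orientations is not otherwise
constrained, so the maximum-entropy choice is used.

**Dynamics.**  Per snapshot (Δt = 2 ns): an isotropic Gaussian
centre-of-mass step with variance 2·D·Δt per axis (D = 0.05 nm²/ns), a
Gaussian rotation about a random axis with variance 2·D_r·Δt
(D_r = 0.2 rad²/ns), and a downhill drift toward the membrane,
v(h) = −A·exp(−h/λ) with A = 1.2 nm/ns and λ = 1.5 nm, where h is the
centre-of-mass height above the surface plane.  The surface plane is a
soft wall; the box top reflects with a safety margin.  x–y positions are
unbounded (the distance kernel's minimum-image handling makes wrapping
unnecessary).  These defaults were chosen so the anchored ensemble
reproduces the qualitative regime of the reference study design at 500
snapshots: every trajectory approaches the membrane, contacts are made
and lost repeatedly, and roughly two-thirds to three-quarters of anchored
runs end inserted.

**Capture and insertion.**  While the anchor residue is within
`anchor_capture_distance` (default 0.6 nm) of a head bead, insertion fires
with probability `anchor_capture_hazard` (default 0.2) per snapshot.  On
firing, the anchor side-chain bead is tethered to the surface plane (z
pinned, lateral diffusion free) for all later frames — insertion is
modelled as pin-to-plane rather than acyl-chain dynamics because the
analysis only requires the anchor to remain in head-bead contact, which
the pin guarantees.  In reversible mode (`irreversible=False`) the tether
releases with the same hazard per snapshot.

**Ground truth and detectability.**  The log records the true first
contact, the true insertion frame, and the per-frame anchored state.  Two
generator rules make the analysis-side detector *provably* recover the
logged insertion frame:

1. A failed capture attempt at the end of `insertion_run_length − 1`
   successive anchor-contact snapshots triggers a detachment kick that
   lifts the anchor clear of contact on the next snapshot.  Un-captured
   anchor-contact runs therefore never reach the insertion run length —
   transient contacts cannot masquerade as insertion — and this is also
   the mechanism behind the "made and lost contact before insertion"
   phenomenology.  For the same reason `anchor_capture_distance` must be
   ≥ the contact threshold, so every anchor-contact snapshot is a capture
   attempt.  (The kick also applies to non-anchored variants, whose
   anchor site has no special membrane affinity.)
2. The logged insertion frame is the first snapshot of the anchor-contact
   run that culminates in the capture — the event-definition time, which
   precedes the capture draw by at most `run_length − 1` snapshots.  A
   capture firing within the last `run_length − 1` snapshots of a run is
   not logged: the required number of successive snapshots can no longer
   be observed, so by definition no insertion event occurred.

Under "forced proximity" configurations (capture range spanning the box,
diffusion off), capture attempts occur every snapshot and the number of
observable inserted trajectories follows the geometric waiting-time
closed form 1 − (1 − p)^(N − L + 1); this is used as a statistical check
of the whole generate-and-detect loop.

With `insertion_run_length = 1` and 0 < hazard < 1 exact recovery is not
achievable (any failed attempt already happened at a contact snapshot);
the default run length is 3 and the limitation is noted here.

## What the synthetic data does and does not show

The generator emulates: diffusive approach from a 7 nm z-offset,
transient whole-protein contacts, stochastic irreversible anchor
insertion, permanent post-insertion anchor contact, and the three-system
ensemble design (anchored / non-anchored / taller-box dimer).  It does
not emulate: force-field energetics, lipid mobility or mixing, specific
residue chemistry (pre-insertion contacts are orientationally random by
construction), or acyl-chain insertion dynamics.  Passing tests therefore
demonstrate the correctness of the *analysis* (bookkeeping, kernels,
event logic, curve and profile arithmetic) and the internal consistency
of the generator — not the biophysics of any particular protein.

## Problem sizes

Unit and property tests use desk-scale systems (16–100 lipids at the
default areal density, 20–500 snapshots, ensembles of 3–10); the
end-to-end checks use a 100-trajectory anchored ensemble at 500 snapshots
(~1,500 beads) and n = 200 ensembles for the waiting-time statistics.
`scripts/acceptance.py` runs the full 410-lipid geometry with the
100/10/16 ensemble design.  These sizes are the package's own choices for
a reproducible desk-scale replica; all of them are parameters, not
limits.

## Known limitations

* Static membrane: no lipid response to the protein, so residue
  probabilities near the pinned anchor are sharper than a fluid bilayer
  would give.
* Rigid protein: no induced fit at the interface.
* The detachment-kick rule couples the generator to the analysis
  definition of an event (by design, for exact validation); it is not a
  physical model of failed insertion attempts.
* GRO coordinates carry 3 decimal places (0.001 nm); distances recovered
  from written files can differ from in-memory values by up to ~1.7 pm,
  which can flip a contact exactly at the threshold.
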