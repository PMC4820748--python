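# memassoc

Membrane-association analysis for coarse-grained protein/bilayer
trajectories: snapshot-level contact detection, lipid-anchor insertion
events, ensemble association curves, and per-residue lipid-contact
probability maps — plus a seeded Brownian-dynamics generator of synthetic
protein-near-membrane ensembles with exact ground truth.

## The problem

Peripheral membrane proteins such as ankyrin-G (AnkG) are recruited to the
plasma membrane by s-palmitoylation: a C16 acyl chain attached to a
cysteine (Cys70, between the first two ankyrin repeats, in AnkG's
membrane-binding domain) that inserts into the bilayer and locks the
protein onto a defined binding interface.  Coarse-grained MD makes the
microsecond timescale of this process samplable, but turning hundreds of
trajectories into statements like "72 of 100 runs anchored irreversibly"
requires a reproducible event-analysis pipeline.  That pipeline is what
this package provides, for anyone studying protein–membrane association in
Martini-style coarse-grained ensembles.

## The statistics it computes

For an ensemble of trajectories analysed at interval Δt (default 2 ns, so
a 1-μs run yields 500 snapshots; the t = 0 structure is not a snapshot):

* **Contact** — snapshot *i* is a contact iff
  min<sub>a∈protein, b∈membrane</sub> ‖x<sub>a</sub> − x<sub>b</sub>‖ < d<sub>c</sub>,
  with d<sub>c</sub> = 0.6 nm (6 Å, strict) under the minimum-image
  convention in the orthorhombic periodic box.
* **Insertion event** — the first run of L = 3 successive snapshots in
  which the anchor residue (Cys70) is in membrane contact; a trajectory
  with an insertion event is classified *inserted*.
* **Ensemble curves** — per snapshot t: the *cumulative* fraction of
  trajectories with a contact at any snapshot ≤ t; the *subtotal*, the
  fraction with a contact in the trailing window (t − W, t] with
  W = 10 ns; and the cumulative inserted fraction (normalised over the
  inserted subset or the full ensemble).
* **Residue contact probability** — for residue r and a phase window
  (after insertion; between first contact and insertion; or after first
  contact), P(r) = (pooled snapshots where residue r is within
  d<sub>c</sub> of a lipid head-group bead — C1A, C1B, NH3 or PO4) /
  (pooled window snapshots).  Profiles can be written into a PDB B-factor
  column for structure colouring.

The synthetic generator replaces the MD engine with an overdamped
rigid-body model (diffusive approach, transient contacts, irreversible
stochastic anchor capture) whose event times are logged exactly, so every
stage of the analysis is validated against known ground truth.  See
`docs/methods.md` for the model and its limitations.

## Worked example

```python
from memassoc import (AnalysisParams, SimConfig, analyze_trajectory,
                      residue_contact_probability, run_ensemble,
                      subsample_frames, summarize)

params = AnalysisParams()          # 0.6 nm, 3 snapshots, 10 ns, 2 ns
cfg = SimConfig(n_lipids=100, box=(5.5, 5.5, 17.0), n_frames=500)
trajs, truth = run_ensemble(cfg, n_trajectories=10, base_seed=7)

snapshots = [subsample_frames(t, params.frame_interval) for t in trajs]
records = [analyze_trajectory(t, params, g.trajectory_id)
           for t, g in zip(snapshots, truth)]
print(summarize(records))

profile = residue_contact_probability(snapshots, records, params,
                                      "after_insertion")
```

prints (exactly, for these seeds):

```
{'n': 10, 'counts': {'inserted': 7, 'contact_only': 3, 'no_contact': 0},
 'inserted_fraction': 0.7, 'median_first_contact_ns': 48.0,
 'median_insertion_ns': 540.0, 'irreversibility_fraction': 1.0}
```

Seven of the ten 1-μs runs end irreversibly anchored (every post-insertion
snapshot is a contact — irreversibility fraction 1.0); the median run first
touches the membrane at 48 ns.  The after-insertion profile concentrates on
the anchor and its neighbours (residues 69–71 have head-group contact
probability ≈ 1.0) while all other residues stay low — the signature of an
anchor-defined binding interface.

The same workflow is available from the shell:

```bash
memassoc simulate --n-trajectories 10 --seed 7 --out runs/
memassoc analyze runs/*.gro --out analysis/
memassoc profile runs/*.gro --phase after_insertion --out profile.csv
memassoc map-structure --structure model.pdb --profile profile.csv --out colored.pdb
memassoc run-all --seed 1 --out replica/
```

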