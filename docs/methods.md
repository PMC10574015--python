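# Methods

## Stiff-core superposition and the activation metric

Class-A GPCR activation moves TM6 and TM7 while a densely packed core of
TM3/TM4/TM5 stays put. All comparisons in this package therefore run in
the frame defined by a least-squares rigid fit on that core. For CB1 the
default core ("basement") selection is residues 195–199 (TM3), 243–249
(TM4) and 275–289 (TM5), Cα atoms, in author numbering; a shorter TM5
variant ending at 283 — the maximally reinforced part of the helix
before its kink at Leu286 — is available via
`default_selections(tm5_short=True)`. The activation indicator is the
pooled set of TM6 (351–361) and TM7 (381–391) Cα atoms: after the core
fit the package reports one RMSD and one maximum per-atom displacement
over the pooled set against each reference. Per-column comparisons use
independent fits of the query to each reference, not a shared frame.

Classification is nearest-reference with an indeterminate band: the
query is called active-like only when its indicator RMSD to the active
reference beats the RMSD to the inactive reference by more than a margin
(default 0.5 Å), and symmetrically; everything else — including the
"partial activation" regime where the two RMSDs are comparable — is
reported as indeterminate. The margin is a reporting convention, not a
physical claim; it is configurable.

The Kabsch fit uses the SVD construction with the determinant sign fix,
so reflections are never returned; rank-deficient (collinear) atom sets
produce a warning and an arbitrary-but-proper rotation. Metrics
(`rmsd`, `max_pair_distance`) never fit internally — they measure
whatever frame the caller established, which is what "RMSD after core
superposition" requires. Atoms missing from either structure are
dropped from the pairing and reported; they are never interpolated.

## Residue addressing

Structures keep PDB author numbering and insertion codes verbatim,
because that is how receptor residues are cited (Ser383, F381…).
Crystal constructs carry fusion proteins and antibody chains; the
receptor chain of such an entry is inferred as the chain with the most
residues numbered 100–420, overridable everywhere. Alternate locations
resolve to the highest occupancy (ties: lexicographically first
altloc). Parsing and writing go through gemmi.

## RMSF and stiff-core detection

Trajectories are aligned to their time-mean structure (two passes: fit
to the raw mean, recompute, refit), optionally on a fit selection only.
RMSF_i = √⟨|r_i(t) − ⟨r_i⟩|²⟩ about the time mean, which makes the
profile invariant to frame order. The stiff-core detector cuts the
profile at a quantile (default 0.25, strict inequality, so a uniform
profile yields nothing) and keeps contiguous residue runs of at least
`min_run` (default 4, since core segments are 5–15 residues long).
Because the cut is a sample quantile, a handful of ordinary residues in
the background's lower tail can attach to (or extend) detected runs;
the tests treat recovery as containment of the planted range rather
than exact equality.

## Steering schedules and work accounting

The pulling algorithm moves the center of a harmonic restraint
U = k|r − r₀|²/2 in N discrete stages. After stage i the next center is
placed on the segment from the measured stage-mean position toward the
destination, advancing 1/(N−i) of the remaining gap; at i = N−1 the
destination is returned bitwise, so the endpoint is exact regardless of
rounding. When the system tracks the restraint, the center advances by
d/(N−1) per stage — 0.1–0.15 Å for a 2–3 Å displacement at N = 21,
the regime the defaults (N = 21, k_pull = 500, k_core = 80 kcal/(mol Å²))
are taken from. Core atoms are restrained at their initial coordinates
throughout and contribute no switching work.

Work is accounted stepwise: each center jump changes the restraint
energy at the instantaneous coordinates, and the run accumulates those
jumps. This is exact for a piecewise-constant protocol and needs no
integral definition. Two deliberate choices:

* **Averaging window and decorrelation guard.** The stage mean ⟨r⟩⁽ⁱ⁾ is
  taken over a mid-stage window (default 50% of the stage), after which
  the dynamics runs a further guard stretch (default 25%) before the
  jump. The center update is feedback control — the new center is a
  function of measured positions — and if the jump lands on the very
  samples that produced the mean, the correlation biases the work
  estimator downward (an information-engine effect: noisy measurements
  let the controller place the center favourably). The guard
  decorrelates the switch coordinates from the mean estimate and removes
  the bias at negligible cost.
* **No bias subtraction.** The accumulated number is the raw external
  switching work; no end-state restraint-energy correction is applied.

### What the toy validation does and does not show

The Brownian engine integrates overdamped Langevin dynamics
(Euler–Maruyama; stability requires k·dt/γ < 2, and the stationary
variance of the discretisation is kBT/k·(1 − k·dt/2γ)⁻¹, which the
equipartition test corrects for). For a particle in a well k_s steered
by a restraint k whose center travels a distance d, the free-energy
change is ΔF = ½·k·k_s/(k+k_s)·d² — temperature-independent, exact.

Two facts shape the validation conditions:

1. With fully equilibrated stages, the stepwise protocol still
   dissipates Σᵢ k²δᵢ²/(2(k+k_s)) over its center jumps δᵢ. This excess
   does not vanish with stage length, only with finer center paths, and
   it grows with k: a stiff pull spring makes the N = 21 protocol
   measurably super-quasi-static.
2. With short or noisy averaging windows, the feedback rule extracts
   work (measured mean work can fall below ΔF, even below zero at high
   temperature) — the second-law bound W ≥ ΔF is a theorem only for
   predetermined protocols.

The quasi-static agreement test therefore runs a *soft* pull
(k = 0.2, k_s = 1, d = 2 Å, kBT = 0.3 kcal/mol, N = 21, 2000-step
stages, 10 seeds), where the switching excess (≈ 0.02 kcal/mol) is far
below statistical resolution and the mean work must match ΔF = 0.333
within 3 standard errors. The dissipation test runs a *stiff* pull at
low noise (k = 5, kBT = 0.05, 30-step stages), where the schedule lags
and the lag dissipation dominates any measurement-noise extraction, so
the mean work must exceed ΔF. The absolute deviation |⟨W⟩ − ΔF| also
shrinks monotonically with stage length on the soft system. These runs
validate the restraint bookkeeping, not the kinetics of any real
receptor; the toy system has one particle and no barriers.

## Synthetic data

The bundle generator places seven ideal Cα helices (rise 1.5 Å/residue,
twist 100°, radius 2.3 Å; consecutive Cα–Cα distance 3.83 Å from the
chord formula) on an 11 Å ring, alternating direction, with residue
numbering spanning 100–400 so every CB1 selection resolves completely,
plus three stub residues (102, 113, 125) anchoring the angle collective
variable. The seed randomises helix phases only. Displacement pairs
move a chosen selection rigidly and return the exact per-atom
displacement table; the call refuses to move atoms inside a protected
(core) selection, because the metric-exactness guarantees rest on an
unperturbed fitting frame. Jitter trajectories add isotropic Gaussian
noise with per-residue amplitude; E[RMSF] = √3·σ.

What the synthetic fixtures do **not** emulate: real helices are bent
and kinked, activation movements are not rigid, thermal motion is
correlated along the chain rather than independent per atom, and crystal
structures carry missing residues, altlocs and fusion partners beyond
the minimal cases the I/O tests construct. Passing the synthetic suite
therefore demonstrates correctness of the geometry, bookkeeping and
statistics — not that any particular biological structure will be
classified correctly. The crystal-structure comparisons (5XRA/5XR8/5TGZ)
run only when the user supplies those coordinates under `data/`.

## Numerical conventions

Distances in Å, energies in kcal/mol, temperatures as kB·T in kcal/mol,
angles in degrees in [0, 180]. No mass weighting anywhere (the metrics
are Cα-only). PDB coordinate round-trips are stable to the format's
0.001 Å precision. All generators and stochastic runs are deterministic
under a fixed seed.

## Known limitations

* The activation call depends on the margin convention near the
  indeterminate boundary; report the raw RMSD pairs alongside the label.
* The stiff-core detector assumes a contiguous-in-numbering core; cores
  assembled from interleaved chains would need chain-aware ranges.
* The steering work estimator is unbiased only with an adequate
  decorrelation guard (≳ a few relaxation times between averaging and
  jump); very short stages under-decorrelate by construction.
* Multi-model PDB trajectories are read whole into memory.
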