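# actimetry

Activation-state metrics for seven-transmembrane (7TM) receptor
structures, built around the idea of a **stiff core**: in class-A GPCRs
such as the cannabinoid receptor CB1, a set of transmembrane segments
(parts of TM3, TM4 and TM5) barely moves between the active and inactive
conformations, while TM6 and TM7 swing. Superposing structures on that
core — instead of on the whole chain — makes the activation movement
directly measurable.

The package provides:

* **Stiff-core superposition** — least-squares (Kabsch) rigid fits on
  residue-range selections in author (PDB) numbering, e.g. the CB1 core
  `195-199 (TM3), 243-249 (TM4), 275-289 (TM5)`.
* **Activation scoring** — after the core fit, the pooled Cα RMSD and
  maximum displacement of the indicator region (TM6 `351-361` + TM7
  `381-391`) against active and inactive reference structures, with an
  active-like / inactive-like / indeterminate call:
  `active-like ⇔ RMSD_act + margin < RMSD_inact` (margin 0.5 Å by default).
* **Collective variables** — Cα–Cα distances (e.g. F381–V179) and
  three-Cα angles (e.g. T125–P113–F102).
* **RMSF analysis** — per-residue root-mean-square fluctuation about the
  time-mean structure of an aligned trajectory, plus a quantile-cut
  detector that extracts contiguous low-fluctuation runs (the stiff core).
* **Steered restraint schedules** — a staged harmonic-restraint pulling
  algorithm: the restraint center moves from the measured stage mean
  ⟨**r**⟩⁽ⁱ⁾ toward the destination **r**\* via
  **r**₀⁽ⁱ⁺¹⁾ = ⟨**r**⟩⁽ⁱ⁾ − (⟨**r**⟩⁽ⁱ⁾ − **r**\*)/(N − i),
  landing on **r**\* exactly at stage N, with stepwise switching-work
  accounting (defaults N = 21, k = 500 kcal/(mol Å²) on pulled atoms,
  80 kcal/(mol Å²) on the retained core).
* **A Brownian toy engine and synthetic structure generators** —
  overdamped Langevin dynamics with closed-form free-energy oracles, and
  ideal α-helix bundles with CB1-like numbering whose rigid
  displacements and fluctuation amplitudes are known exactly.

## Worked example

Generate a synthetic bundle, displace the TM6/TM7 indicator region by a
known 2 Å, and score the displaced structure with itself as the "active"
reference and the original as "inactive":

```sh
actimetry synth pair --seed 2 --shift 2.0 0.0 0.0 \
    --out-ref ref.pdb --out-displaced disp.pdb
actimetry activation --query disp.pdb --active disp.pdb --inactive ref.pdb
```

prints

```
rmsd_active	max_active	rmsd_inactive	max_inactive	label
0.00	0.00	2.00	2.00	active-like
```

i.e. the query is identical to the active reference (0.00/0.00) and sits
exactly the planted 2 Å from the inactive one — the stiff-core fit is
exact, so a rigid indicator translation is read back without distortion.
The same call on real coordinates reproduces the crystal-to-crystal
comparison (antagonist-bound vs agonist-bound CB1 scores ≈ 3.7/5.4 Å on
the indicator region after the core fit).

Library use mirrors the CLI:

```python
from actimetry import read_structure, activation_score, default_selections

basement, indicator = default_selections(chain="A")
report = activation_score(query, active_ref, inactive_ref, basement, indicator)
print(report.rmsd_to_active, report.max_to_active, report.label)
```

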