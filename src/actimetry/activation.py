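"""Activation-state scoring for CB1-like 7TM structures.

The activation indicator works in two steps.  First the query structure
is rigidly superposed on a reference using only the stiff core
("basement") of the transmembrane domain — TM3 residues 195-199, TM4
243-249 and TM5 275-289 in CB1 author numbering.  This core barely moves
between the active and inactive conformations, so the fit factors out
global placement without hiding the conformational change.  Second, the
pooled Calpha RMSD and maximum displacement of the indicator region —
TM6 351-361 plus TM7 381-391, the segments that swing during activation
— are measured in that frame against both an active-state and an
inactive-state reference.  A query is called active-like when it sits
decisively closer (by a configurable margin) to the active reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import kabsch_fit, max_pair_distance, rmsd
from .structure_io import (
    PairedCoordinates,
    ResidueRangeSelection,
    StructureModel,
    pair_structures,
)

__all__ = [
    "ActivationReport",
    "activation_score",
    "default_selections",
    "helix_displacement_profile",
    "DEFAULT_MARGIN",
]

#: Indeterminate band (Angstrom): |rmsd_active - rmsd_inactive| below this
#: is reported as indeterminate ("partial activation") rather than forced
#: into a binary call.
DEFAULT_MARGIN = 0.5


@dataclass(frozen=True)
class ActivationReport:
    rmsd_to_active: float
    max_to_active: float
    rmsd_to_inactive: float
    max_to_inactive: float
    basement_fit_rmsd_active: float
    basement_fit_rmsd_inactive: float
    n_basement_atoms: int
    n_indicator_atoms: int
    label: str  # active-like | inactive-like | indeterminate
    margin: float

    def as_dict(self) -> dict:
        return {
            "rmsd_active": self.rmsd_to_active,
            "max_active": self.max_to_active,
            "rmsd_inactive": self.rmsd_to_inactive,
            "max_inactive": self.max_to_inactive,
            "basement_fit_rmsd_active": self.basement_fit_rmsd_active,
            "basement_fit_rmsd_inactive": self.basement_fit_rmsd_inactive,
            "n_basement_atoms": self.n_basement_atoms,
            "n_indicator_atoms": self.n_indicator_atoms,
            "label": self.label,
        }


def default_selections(
    chain: str = "A", tm5_short: bool = False
) -> tuple[ResidueRangeSelection, ResidueRangeSelection]:
    """The CB1 stiff-core and indicator selections (Calpha atoms).

    Basement: 195-199 (TM3), 243-249 (TM4), 275-289 (TM5); with
    ``tm5_short`` the TM5 segment is truncated at 283, the maximally
    reinforced part of the helix before its kink.  Indicator: 351-361
    (TM6) and 381-391 (TM7).
    """
    tm5_end = 283 if tm5_short else 289
    basement = ResidueRangeSelection.from_ranges(
        [(chain, 195, 199), (chain, 243, 249), (chain, 275, tm5_end)]
    )
    indicator = ResidueRangeSelection.from_ranges(
        [(chain, 351, 361), (chain, 381, 391)]
    )
    return basement, indicator


def _score_against(
    query: StructureModel,
    reference: StructureModel,
    basement: ResidueRangeSelection,
    indicator: ResidueRangeSelection,
) -> tuple[float, float, float, int, int]:
    base: PairedCoordinates = pair_structures(query, reference, basement)
    fit = kabsch_fit(base.coords_a, base.coords_b)
    ind: PairedCoordinates = pair_structures(query, reference, indicator)
    moved = fit.transform.apply(ind.coords_a)
    return (
        rmsd(moved, ind.coords_b),
        max_pair_distance(moved, ind.coords_b),
        fit.fit_rmsd,
        base.n,
        ind.n,
    )


def activation_score(
    query: StructureModel,
    active_ref: StructureModel,
    inactive_ref: StructureModel,
    basement: ResidueRangeSelection | None = None,
    indicator: ResidueRangeSelection | None = None,
    margin: float = DEFAULT_MARGIN,
) -> ActivationReport:
    """Score a query conformation against active and inactive references.

    The query is fitted independently to each reference on the basement
    selection; indicator metrics are pooled over all paired TM6+TM7
    atoms.  Classification: active-like iff
    ``rmsd_to_active + margin < rmsd_to_inactive`` (and symmetrically),
    otherwise indeterminate.
    """
    if basement is None or indicator is None:
        d_base, d_ind = default_selections()
        basement = basement if basement is not None else d_base
        indicator = indicator if indicator is not None else d_ind

    ra, ma, fa, nb, ni = _score_against(query, active_ref, basement, indicator)
    ri, mi, fi, _, _ = _score_against(query, inactive_ref, basement, indicator)

    degenerate = _references_identical(active_ref, inactive_ref)
    if degenerate:
        warnings.warn(
            "active and inactive references are identical; "
            "classification is indeterminate",
            RuntimeWarning,
            stacklevel=2,
        )
        label = "indeterminate"
    elif ra + margin < ri:
        label = "active-like"
    elif ri + margin < ra:
        label = "inactive-like"
    else:
        label = "indeterminate"

    return ActivationReport(
        rmsd_to_active=ra,
        max_to_active=ma,
        rmsd_to_inactive=ri,
        max_to_inactive=mi,
        basement_fit_rmsd_active=fa,
        basement_fit_rmsd_inactive=fi,
        n_basement_atoms=nb,
        n_indicator_atoms=ni,
        label=label,
        margin=margin,
    )


def _references_identical(a: StructureModel, b: StructureModel) -> bool:
    if len(a.atoms) != len(b.atoms):
        return False
    for x, y in zip(a.atoms, b.atoms):
        if x.label != y.label or not np.allclose(x.pos, y.pos, atol=1e-9):
            return False
    return True


def helix_displacement_profile(
    query: StructureModel,
    reference: StructureModel,
    basement: ResidueRangeSelection,
    probe: ResidueRangeSelection,
) -> pd.DataFrame:
    """Per-residue displacement of a probe region after basement fit.

    Returns a DataFrame (chain, resnum, atom, displacement_A) ordered by
    the probe selection, e.g. to read off how far each TM2 residue moved
    relative to the stiff core.
    """
    base = pair_structures(query, reference, basement)
    fit = kabsch_fit(base.coords_a, base.coords_b)
    paired = pair_structures(query, reference, probe)
    moved = fit.transform.apply(paired.coords_a)
    disp = np.linalg.norm(moved - paired.coords_b, axis=1)
    return pd.DataFrame(
        {
            "chain": [lab[0] for lab in paired.labels],
            "resnum": [lab[1] for lab in paired.labels],
            "atom": [lab[3] for lab in paired.labels],
            "displacement_A": disp,
        }
    )
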