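"""Reference cohort definitions for the six striatonigrostriatal circuits.

The published study that this pipeline reimplements reports, for every
circuit configuration, how many recorded cells responded in each assay.
Those count pairs serve here as fixture definitions: simulating a cohort
with its ground-truth flags pinned to the reported counts and running the
full pipeline must reproduce the reported integer percentages.

Counts are (n_responding, n_tested):

* connectivity -- cells with a light-evoked IPSC in whole-cell mode;
* suppression  -- cells whose tonic firing the light train suppressed;
* train        -- cells responding to the 20 Hz / 3 s train at -40 mV.
"""

from __future__ import annotations

from cracm.synthetic_data import CohortSpec

CONNECTIVITY_COHORTS: dict[str, tuple[int, int]] = {
    "SNr_to_DLSproj": (18, 26),
    "SNr_to_DMSproj": (13, 15),
    "DLS_loop": (9, 17),
    "DMS_loop": (16, 24),
    "ascending_spiral": (15, 30),
    "descending_spiral": (13, 29),
}

SUPPRESSION_COHORTS: dict[str, tuple[int, int]] = {
    "SNr_to_DLSproj": (19, 28),
    "SNr_to_DMSproj": (11, 22),
    "DLS_loop": (9, 18),
    "DMS_loop": (9, 26),
    "ascending_spiral": (0, 23),
    "descending_spiral": (1, 26),
}

TRAIN_COHORTS: dict[str, tuple[int, int]] = {
    "DLS_loop": (7, 15),
    "ascending_spiral": (11, 22),
    "DMS_loop": (7, 14),
    "descending_spiral": (5, 18),
}


def connectivity_cohort_spec(circuit: str, seed: int) -> CohortSpec:
    """Whole-cell connectivity cohort with truth pinned to the reported counts."""
    k, n = CONNECTIVITY_COHORTS[circuit]
    return CohortSpec(
        circuit=circuit,
        n_cells=n,
        connected_truth=[True] * k + [False] * (n - k),
        conditions=("vc",),
        seed=seed,
    )


def suppression_cohort_spec(circuit: str, seed: int) -> CohortSpec:
    """Loose-seal suppression cohort with truth pinned to the reported counts."""
    k, n = SUPPRESSION_COHORTS[circuit]
    truth = [True] * k + [False] * (n - k)
    return CohortSpec(
        circuit=circuit,
        n_cells=n,
        connected_truth=truth,
        suppressed_truth=truth,
        conditions=("loose_seal",),
        n_sweeps=10,  # the standard loose-seal protocol records 10 sweeps
        seed=seed,
    )
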