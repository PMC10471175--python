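"""End-to-end screen orchestration.

Runs the two-stage screen over a prepared fixture or over files: pool-stage
positivity calls (bulk arm), deconvolution of positive pools into a singleton
retest list, singleton-stage calls in bulk/CD4/CD8 arms, and the final
mutation-level hit table with subset attribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .elispot import ElispotCondition, PositivityCall, Thresholds, call_plate
from .pools import PeptidePool, candidates_from_positive_pools, summarize_hits
from .simulate import Fixture

__all__ = ["ScreenResult", "run_screen", "screen_fixture", "hits_match_truth"]


@dataclass
class ScreenResult:
    """All intermediate decisions plus the final hit table."""

    pool_calls: list
    positive_pool_ids: list
    retest_peptide_ids: list
    single_calls: dict  # arm -> {peptide_id: PositivityCall}
    hits: pd.DataFrame


def _calls_by_id(calls: Sequence[PositivityCall]) -> dict:
    return {c.stimulus_id: c for c in calls}


def run_screen(
    pools: Sequence[PeptidePool],
    plate_pool: Sequence[ElispotCondition],
    plates_single: Mapping[str, Sequence[ElispotCondition]],
    peptide_manifest: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    control_id: str = "control",
) -> ScreenResult:
    """Two-stage screen: pool calls -> deconvolution -> singleton calls -> hits.

    ``plates_single`` maps arm names to singleton-stage conditions; the bulk
    arm drives the hit table, the CD4/CD8 arms attribute subsets.  Only
    peptides deconvoluted from positive pools are evaluated at the singleton
    stage.
    """
    pool_calls = call_plate(plate_pool, control_id, thresholds)
    positive_pool_ids = [c.stimulus_id for c in pool_calls if c.positive]
    retest = candidates_from_positive_pools(pools, positive_pool_ids)
    retest_set = set(retest)

    single_calls: dict[str, dict] = {}
    for arm, conditions in plates_single.items():
        arm_calls = call_plate(list(conditions), control_id, thresholds)
        single_calls[arm] = {
            c.stimulus_id: c for c in arm_calls if c.stimulus_id in retest_set
        }

    bulk = single_calls.get("bulk", {})
    hits = summarize_hits(
        bulk,
        peptide_manifest,
        cd4_arm_calls=single_calls.get("CD4"),
        cd8_arm_calls=single_calls.get("CD8"),
    )
    return ScreenResult(
        pool_calls=pool_calls,
        positive_pool_ids=positive_pool_ids,
        retest_peptide_ids=retest,
        single_calls=single_calls,
        hits=hits,
    )


def screen_fixture(fixture: Fixture, thresholds: Thresholds = Thresholds()) -> ScreenResult:
    """Run the screen on a synthetic fixture."""
    return run_screen(
        fixture.pools,
        fixture.plate_pool,
        fixture.plates_single,
        fixture.manifest,
        thresholds,
    )


def hits_match_truth(hits: pd.DataFrame, fixture: Fixture) -> bool:
    """True iff the recovered hit table equals the planted truth exactly.

    Exact means: the same set of hit mutations, each with the planted subset
    label and exactly its planted immunogenic peptides called positive.
    """
    expected = fixture.expected_hits()
    if set(hits["mutation_id"].astype(str)) != set(expected):
        return False
    for row in hits.to_dict("records"):
        label, pids = expected[str(row["mutation_id"])]
        if row["subset_label"] != label:
            return False
        called = set(str(row["positive_peptides"]).split(",")) if row["positive_peptides"] else set()
        if called != pids:
            return False
    return True
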