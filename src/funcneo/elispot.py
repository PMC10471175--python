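"""ELISPOT positivity statistics.

An IFN-γ ELISPOT condition is a set of replicate wells, each yielding a
spot-forming-cell (SFC) count on a shared cells-per-well basis.  A stimulus is
called positive against a no-peptide control when ALL four criteria hold:

1. **count** — the mean test SFC is at least ``min_sfc`` (default 50, inclusive);
2. **p** — a two-tailed pooled-variance Student's t test of test vs control
   wells gives p < ``p_max`` (default 0.05, strict);
3. **si** — the stimulation index, mean(test)/mean(control), exceeds
   ``si_min`` (default 2, strict);
4. **poisson** — under a Poisson model of well counts with the control mean
   as rate, the upper-tail probability of seeing at least the (rounded) test
   mean is below ``poisson_max`` (default 0.05, strict).

The Poisson criterion asks whether background alone could plausibly have
produced the observed signal, treating spot counts as Poisson events; this is
a standard reading of a "Poisson < 5%" positivity rule and is a documented
modelling choice (see docs/methods.md).  The count criterion uses the raw
test mean; ``background_subtract=True`` switches it to mean(test) −
mean(control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ElispotCondition",
    "PositivityCall",
    "Thresholds",
    "stimulation_index",
    "two_sample_t",
    "poisson_tail",
    "call_positive",
    "call_plate",
    "read_plate",
    "calls_to_frame",
]


class ElispotError(ValueError):
    """Invalid replicate data for an ELISPOT statistic."""


@dataclass(frozen=True)
class ElispotCondition:
    """Replicate SFC counts for one stimulus (peptide, pool, or control)."""

    stimulus_id: str
    replicate_counts: tuple
    arm: str = "bulk"  # {bulk, CD4, CD8}
    tissue: Optional[str] = None

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.replicate_counts)
        object.__setattr__(self, "replicate_counts", counts)
        if any(c < 0 for c in counts):
            raise ElispotError(f"condition {self.stimulus_id!r}: negative spot counts")

    @property
    def mean(self) -> float:
        if not self.replicate_counts:
            raise ElispotError(f"condition {self.stimulus_id!r}: no replicate wells")
        return float(np.mean(self.replicate_counts))


@dataclass(frozen=True)
class Thresholds:
    """The four positivity thresholds."""

    min_sfc: float = 50.0
    p_max: float = 0.05
    si_min: float = 2.0
    poisson_max: float = 0.05


@dataclass(frozen=True)
class PositivityCall:
    """The four-criterion decision for one stimulus condition."""

    stimulus_id: str
    arm: str
    mean_sfc: float
    si: float
    si_infinite: bool
    p_value: float
    poisson_tail: float
    crit_count: bool
    crit_p: bool
    crit_si: bool
    crit_poisson: bool

    @property
    def positive(self) -> bool:
        return self.crit_count and self.crit_p and self.crit_si and self.crit_poisson


def _as_array(counts, name: str) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ElispotError(f"{name} replicate list is empty")
    return arr


def stimulation_index(test_counts, control_counts) -> tuple[float, bool]:
    """Mean(test) / mean(control).

    Returns ``(si, infinite_flag)``.  A zero-background control gives an
    infinite SI with the flag set; callers should treat the SI criterion as
    met iff the test mean is positive.
    """
    test = _as_array(test_counts, "test")
    control = _as_array(control_counts, "control")
    cm = control.mean()
    tm = test.mean()
    if cm == 0:
        return (math.inf if tm > 0 else math.nan, True)
    return (tm / cm, False)


def two_sample_t(test_counts, control_counts) -> float:
    """Two-tailed p from a pooled-variance (classic Student) two-sample t test.

    df = n1 + n2 - 2.  Degenerate zero-variance data follow the limit
    convention: equal means give p = 1, unequal means give p = 0.
    """
    test = _as_array(test_counts, "test")
    control = _as_array(control_counts, "control")
    n1, n2 = test.size, control.size
    if n1 < 2 or n2 < 2:
        raise ElispotError("two_sample_t requires at least 2 replicates per group")
    m1, m2 = test.mean(), control.mean()
    v1 = test.var(ddof=1)
    v2 = control.var(ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if pooled == 0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(abs(t), n1 + n2 - 2))


def poisson_tail(test_counts, control_counts) -> float:
    """P(X >= k) for X ~ Poisson(mean control), k = rounded mean test count.

    Rounding is half-up.  A zero rate yields probability 0 for k > 0 and 1
    for k = 0; k = 0 always yields 1 (every count is >= 0).
    """
    test = _as_array(test_counts, "test")
    control = _as_array(control_counts, "control")
    lam = control.mean()
    k = int(math.floor(test.mean() + 0.5))
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


def call_positive(
    test: ElispotCondition,
    control: ElispotCondition,
    thresholds: Thresholds = Thresholds(),
    background_subtract: bool = False,
) -> PositivityCall:
    """Apply the four-criterion positivity rule to one stimulus condition."""
    si, si_inf = stimulation_index(test.replicate_counts, control.replicate_counts)
    p = two_sample_t(test.replicate_counts, control.replicate_counts)
    ptail = poisson_tail(test.replicate_counts, control.replicate_counts)
    mean_sfc = test.mean - control.mean if background_subtract else test.mean
    crit_si = (test.mean > 0) if si_inf else (si > thresholds.si_min)
    return PositivityCall(
        stimulus_id=test.stimulus_id,
        arm=test.arm,
        mean_sfc=mean_sfc,
        si=si,
        si_infinite=si_inf,
        p_value=p,
        poisson_tail=ptail,
        crit_count=mean_sfc >= thresholds.min_sfc,
        crit_p=p < thresholds.p_max,
        crit_si=crit_si,
        crit_poisson=ptail < thresholds.poisson_max,
    )


def call_plate(
    conditions: Sequence[ElispotCondition],
    control_id: str = "control",
    thresholds: Thresholds = Thresholds(),
    background_subtract: bool = False,
) -> list[PositivityCall]:
    """Call every non-control condition against the same-arm control wells."""
    controls = {c.arm: c for c in conditions if c.stimulus_id == control_id}
    if not controls:
        raise ElispotError(f"no control condition with stimulus_id {control_id!r}")
    calls = []
    for cond in conditions:
        if cond.stimulus_id == control_id:
            continue
        if cond.arm not in controls:
            raise ElispotError(f"no {control_id!r} condition for arm {cond.arm!r}")
        calls.append(call_positive(cond, controls[cond.arm], thresholds, background_subtract))
    return calls


# ---------------------------------------------------------------------------
# Plate I/O

def read_plate(path) -> list[ElispotCondition]:
    """Read a long-format plate table: stimulus_id, arm, tissue, well_index, sfc."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    needed = {"stimulus_id", "arm", "well_index", "sfc"}
    missing = needed - set(df.columns)
    if missing:
        raise ElispotError(f"plate table is missing columns: {sorted(missing)}")
    out = []
    for (stim, arm), grp in df.groupby(["stimulus_id", "arm"], sort=False):
        grp = grp.sort_values("well_index")
        tissue = None
        if "tissue" in grp.columns:
            vals = [t for t in grp["tissue"].unique() if not pd.isna(t) and t != ""]
            tissue = str(vals[0]) if vals else None
        out.append(
            ElispotCondition(
                stimulus_id=str(stim),
                arm=str(arm),
                tissue=tissue,
                replicate_counts=tuple(int(x) for x in grp["sfc"]),
            )
        )
    return out


def write_plate(conditions: Sequence[ElispotCondition], path) -> None:
    rows = []
    for c in conditions:
        for i, sfc in enumerate(c.replicate_counts, start=1):
            rows.append(
                {
                    "stimulus_id": c.stimulus_id,
                    "arm": c.arm,
                    "tissue": c.tissue or "",
                    "well_index": i,
                    "sfc": sfc,
                }
            )
    pd.DataFrame(rows, columns=["stimulus_id", "arm", "tissue", "well_index", "sfc"]).to_csv(
        path, sep="\t", index=False
    )


def calls_to_frame(calls: Sequence[PositivityCall]) -> pd.DataFrame:
    rows = [
        {
            "stimulus_id": c.stimulus_id,
            "arm": c.arm,
            "mean_sfc": c.mean_sfc,
            "si": c.si,
            "p_value": c.p_value,
            "poisson_tail": c.poisson_tail,
            "crit_count": int(c.crit_count),
            "crit_p": int(c.crit_p),
            "crit_si": int(c.crit_si),
            "crit_poisson": int(c.crit_poisson),
            "positive": int(c.positive),
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
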