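"""Peptide pooling, pool deconvolution, and mutation-level hit summaries.

Candidate peptides are screened in two stages: first as pools of ~5 peptides
against antigen-presenting cells, then — for pools producing significant
IFN-γ responses — each member peptide is retested singly.  Single-peptide
positives are rolled up to mutation-level hits, and separate CD4+/CD8+
T cell arm screens attribute each hit to the responding subset(s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .elispot import PositivityCall

__all__ = [
    "PeptidePool",
    "SubsetClassification",
    "assign_pools",
    "candidates_from_positive_pools",
    "classify_epitope_subsets",
    "summarize_hits",
    "pools_to_frame",
    "read_pool_manifest",
]


class PoolError(ValueError):
    """Invalid pooling or deconvolution input."""


@dataclass(frozen=True)
class PeptidePool:
    """A disjoint group of peptides screened together in one well series."""

    pool_id: str
    member_peptide_ids: tuple

    def __post_init__(self) -> None:
        members = tuple(str(m) for m in self.member_peptide_ids)
        object.__setattr__(self, "member_peptide_ids", members)
        if not members:
            raise PoolError(f"pool {self.pool_id!r} is empty")
        if len(set(members)) != len(members):
            raise PoolError(f"pool {self.pool_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.member_peptide_ids)


@dataclass(frozen=True)
class SubsetClassification:
    """Which T cell subset(s) respond to a mutation's peptides."""

    mutation_id: str
    label: str  # {CD4_only, CD8_only, dual, none}
    cd4_positive_peptides: tuple = ()
    cd8_positive_peptides: tuple = ()


def _peptide_ids(peptides: Sequence) -> list[str]:
    ids = [p if isinstance(p, str) else p.peptide_id for p in peptides]
    if len(set(ids)) != len(ids):
        raise PoolError("duplicate peptide ids in pooling input")
    return ids


def assign_pools(
    peptides: Sequence, n_pools: int, ordering_seed: int = 0
) -> list[PeptidePool]:
    """Round-robin peptides into ``n_pools`` pools after a seeded shuffle.

    Deterministic given (input order, n_pools, ordering_seed); pool sizes
    differ by at most one, with the earlier pools taking the remainder.
    Accepts peptide ids or any objects with a ``peptide_id`` attribute.
    """
    ids = _peptide_ids(peptides)
    if n_pools < 1:
        raise PoolError(f"n_pools must be >= 1, got {n_pools}")
    if n_pools > len(ids):
        raise PoolError(f"n_pools ({n_pools}) exceeds peptide count ({len(ids)})")
    rng = np.random.default_rng(ordering_seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    width = len(str(n_pools))
    members: list[list[str]] = [[] for _ in range(n_pools)]
    for i, pid in enumerate(shuffled):
        members[i % n_pools].append(pid)
    return [
        PeptidePool(pool_id=f"Pool_{i + 1:0{width}d}", member_peptide_ids=tuple(m))
        for i, m in enumerate(members)
    ]


def candidates_from_positive_pools(
    pools: Sequence[PeptidePool], positive_pool_ids: Iterable[str]
) -> list[str]:
    """Union of members of positive pools: the singleton retest list.

    Deduplicated, in pool order then within-pool order.
    """
    positive = set(positive_pool_ids)
    known = {p.pool_id for p in pools}
    unknown = positive - known
    if unknown:
        raise PoolError(f"unknown pool ids: {sorted(unknown)}")
    seen: set[str] = set()
    out: list[str] = []
    for pool in pools:
        if pool.pool_id not in positive:
            continue
        for pid in pool.member_peptide_ids:
            if pid not in seen:
                seen.add(pid)
                out.append(pid)
    return out


CallLike = Union[bool, PositivityCall]


def _positives(calls: Mapping[str, CallLike]) -> list[str]:
    out = []
    for pid, call in calls.items():
        positive = call.positive if isinstance(call, PositivityCall) else bool(call)
        if positive:
            out.append(pid)
    return out


def classify_epitope_subsets(
    mutation_id: str,
    cd4_arm_calls: Mapping[str, CallLike],
    cd8_arm_calls: Mapping[str, CallLike],
) -> SubsetClassification:
    """Label a mutation by which sorted T cell arm(s) recognize its peptides.

    ``dual`` when both arms have at least one positive peptide, ``CD4_only`` /
    ``CD8_only`` when exactly one does, ``none`` otherwise.  Calls may be
    booleans or PositivityCall objects keyed by peptide id.
    """
    if not cd4_arm_calls and not cd8_arm_calls:
        raise PoolError(f"mutation {mutation_id!r}: no peptides screened in either arm")
    cd4_pos = _positives(cd4_arm_calls)
    cd8_pos = _positives(cd8_arm_calls)
    if cd4_pos and cd8_pos:
        label = "dual"
    elif cd4_pos:
        label = "CD4_only"
    elif cd8_pos:
        label = "CD8_only"
    else:
        label = "none"
    return SubsetClassification(
        mutation_id=mutation_id,
        label=label,
        cd4_positive_peptides=tuple(cd4_pos),
        cd8_positive_peptides=tuple(cd8_pos),
    )


def summarize_hits(
    single_calls: Mapping[str, CallLike],
    peptide_manifest: pd.DataFrame,
    cd4_arm_calls: Optional[Mapping[str, CallLike]] = None,
    cd8_arm_calls: Optional[Mapping[str, CallLike]] = None,
) -> pd.DataFrame:
    """Roll single-peptide positivity up to one row per hit mutation.

    ``single_calls`` holds the singleton-retest decisions (bulk arm) keyed by
    peptide id; every called peptide must exist in the manifest (columns
    ``peptide_id``, ``mutation_id``, ``gene``).  Sibling peptides of one
    mutation (different anchors or splice products) all contribute, so a
    mutation row lists every positive peptide.  When sorted-arm calls are
    supplied the row carries the subset label, else ``none``.
    """
    manifest_ids = set(peptide_manifest["peptide_id"].astype(str))
    orphans = [pid for pid in single_calls if pid not in manifest_ids]
    if orphans:
        raise PoolError(f"called peptides missing from manifest: {sorted(orphans)}")

    meta = peptide_manifest.set_index(peptide_manifest["peptide_id"].astype(str))
    positives = _positives(single_calls)

    by_mutation: dict[str, list[str]] = {}
    for pid in positives:
        mut = str(meta.loc[pid, "mutation_id"])
        by_mutation.setdefault(mut, []).append(pid)

    rows = []
    for mut, pids in by_mutation.items():
        gene = str(meta.loc[pids[0], "gene"]) if "gene" in meta.columns else ""
        label = "none"
        cd4_pos: tuple = ()
        cd8_pos: tuple = ()
        if cd4_arm_calls is not None or cd8_arm_calls is not None:
            mut_peptides = set(
                peptide_manifest.loc[
                    peptide_manifest["mutation_id"].astype(str) == mut, "peptide_id"
                ].astype(str)
            )
            cd4 = {p: c for p, c in (cd4_arm_calls or {}).items() if p in mut_peptides}
            cd8 = {p: c for p, c in (cd8_arm_calls or {}).items() if p in mut_peptides}
            if cd4 or cd8:
                cls = classify_epitope_subsets(mut, cd4, cd8)
                label = cls.label
                cd4_pos = cls.cd4_positive_peptides
                cd8_pos = cls.cd8_positive_peptides
        rows.append(
            {
                "mutation_id": mut,
                "gene": gene,
                "subset_label": label,
                "positive_peptides": ",".join(pids),
                "cd4_positive_peptides": ",".join(cd4_pos),
                "cd8_positive_peptides": ",".join(cd8_pos),
            }
        )
    cols = [
        "mutation_id", "gene", "subset_label", "positive_peptides",
        "cd4_positive_peptides", "cd8_positive_peptides",
    ]
    return pd.DataFrame(rows, columns=cols).sort_values("mutation_id").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Manifest I/O

def pools_to_frame(pools: Sequence[PeptidePool]) -> pd.DataFrame:
    rows = [
        {"pool_id": p.pool_id, "peptide_id": pid}
        for p in pools
        for pid in p.member_peptide_ids
    ]
    return pd.DataFrame(rows, columns=["pool_id", "peptide_id"])


def write_pool_manifest(pools: Sequence[PeptidePool], path) -> None:
    pools_to_frame(pools).to_csv(path, sep="\t", index=False)


def read_pool_manifest(path) -> list[PeptidePool]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pool_id", "peptide_id"} <= set(df.columns):
        raise PoolError("pool manifest needs columns: pool_id, peptide_id")
    pools = []
    for pool_id, grp in df.groupby("pool_id", sort=False):
        pools.append(PeptidePool(pool_id=str(pool_id), member_peptide_ids=tuple(grp["peptide_id"])))
    return pools
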