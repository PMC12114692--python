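"""Cohort construction on raw ICSR collections.

Applies inclusion criteria, detects and removes near-duplicate reports,
merges synonym PTs onto canonical terms and aggregates PT-level reactions to
MedDRA System Organ Class (SOC) level with case-level counting (a report
contributes at most one count to a SOC however many of its PTs map there).
"""

from __future__ import annotations

from dataclasses import dataclass

from .icsr import CohortCriteria, ICSRecord, MedDRAMap

__all__ = [
    "DuplicateGroup",
    "UNMAPPED_SOC",
    "apply_cohort_criteria",
    "drop_incomplete",
    "find_duplicates",
    "drop_duplicates",
    "normalize_reactions",
    "aggregate_to_soc",
]

#: bucket label for canonical PTs absent from the PT->SOC table
UNMAPPED_SOC = "Unmapped"


@dataclass(frozen=True)
class DuplicateGroup:
    """A set of mutually similar reports of which one is retained.

    Groups over a dataset are pairwise disjoint; the retained member is the
    one with the earliest receipt date, ties broken by smallest report id.
    ``size`` counts records, which can exceed ``len(member_ids)`` when raw
    rows share a local report number.
    """

    member_ids: frozenset[str]
    retained_id: str
    size: int

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("a duplicate group needs at least 2 records")
        if not self.member_ids:
            raise ValueError("a duplicate group needs at least one report id")
        if self.retained_id not in self.member_ids:
            raise ValueError("retained_id must be a group member")


def apply_cohort_criteria(
    records: list[ICSRecord], criteria: CohortCriteria
) -> list[ICSRecord]:
    """Records satisfying all enabled criteria, in input order."""
    return [r for r in records if criteria.accepts(r)]


def drop_incomplete(records: list[ICSRecord]) -> list[ICSRecord]:
    """Drop reports missing seriousness, reactions or a suspect drug.

    The record model already guarantees non-empty reactions; missing drug
    sets are the one incompleteness representable in memory.
    """
    return [r for r in records if r.suspect_drugs and r.reactions]


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def find_duplicates(
    records: list[ICSRecord], reaction_threshold: float = 1.0
) -> list[DuplicateGroup]:
    """Group likely duplicate reports.

    Two reports are linked when they share a local report number, or when
    sex, age group and suspect-drug set are identical and the Jaccard
    similarity of their reaction-PT sets reaches ``reaction_threshold``
    (default 1.0, exact match).  Groups are the transitive closure of the
    pairwise relation and therefore disjoint.
    """
    if not 0.0 < reaction_threshold <= 1.0:
        raise ValueError("reaction_threshold must be in (0, 1]")
    n = len(records)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    # same local report number links directly
    by_id: dict[str, int] = {}
    for i, rec in enumerate(records):
        if rec.local_report_id in by_id:
            union(by_id[rec.local_report_id], i)
        else:
            by_id[rec.local_report_id] = i

    # demographic + drug blocking keeps the pairwise pass near-linear
    blocks: dict[tuple, list[int]] = {}
    for i, rec in enumerate(records):
        key = (rec.sex, rec.age_group, rec.suspect_drugs)
        blocks.setdefault(key, []).append(i)
    for members in blocks.values():
        if len(members) < 2:
            continue
        if reaction_threshold >= 1.0:
            by_rx: dict[frozenset[str], int] = {}
            for i in members:
                rx = frozenset(pt.casefold() for pt in records[i].reactions)
                if rx in by_rx:
                    union(by_rx[rx], i)
                else:
                    by_rx[rx] = i
        else:
            for ai, i in enumerate(members):
                rx_i = frozenset(pt.casefold() for pt in records[i].reactions)
                for j in members[ai + 1 :]:
                    rx_j = frozenset(pt.casefold() for pt in records[j].reactions)
                    if _jaccard(rx_i, rx_j) >= reaction_threshold:
                        union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    groups: list[DuplicateGroup] = []
    for members in clusters.values():
        if len(members) < 2:
            continue
        keep = min(members, key=lambda i: (records[i].receipt_date, records[i].local_report_id))
        groups.append(
            DuplicateGroup(
                member_ids=frozenset(records[i].local_report_id for i in members),
                retained_id=records[keep].local_report_id,
                size=len(members),
            )
        )
    groups.sort(key=lambda g: g.retained_id)
    return groups


def drop_duplicates(
    records: list[ICSRecord], groups: list[DuplicateGroup]
) -> list[ICSRecord]:
    """Keep only the retained member of each group; idempotent.

    Raises ``ValueError`` when a group references a report id that is not in
    ``records``.
    """
    known = {r.local_report_id for r in records}
    drop: set[str] = set()
    for group in groups:
        unknown = group.member_ids - known
        if unknown:
            raise ValueError(f"duplicate group references unknown id(s): {sorted(unknown)}")
        drop |= group.member_ids - {group.retained_id}
    # several raw rows may share the retained id; keep the earliest-dated one
    keep_index: dict[str, int] = {}
    retained_ids = {g.retained_id for g in groups}
    for i, rec in enumerate(records):
        rid = rec.local_report_id
        if rid in retained_ids and (
            rid not in keep_index or rec.receipt_date < records[keep_index[rid]].receipt_date
        ):
            keep_index[rid] = i
    out: list[ICSRecord] = []
    for i, rec in enumerate(records):
        rid = rec.local_report_id
        if rid in drop:
            continue
        if rid in retained_ids and keep_index[rid] != i:
            continue
        out.append(rec)
    return out


def normalize_reactions(records: list[ICSRecord], meddra: MedDRAMap) -> list[ICSRecord]:
    """Replace each PT by its canonical merged term, collapsing repeats.

    Idempotent; terms absent from the synonym table pass through unchanged.
    """
    out: list[ICSRecord] = []
    for rec in records:
        merged: list[str] = []
        seen: set[str] = set()
        for pt in rec.reactions:
            canonical = meddra.merge_term(pt)
            key = canonical.casefold()
            if key not in seen:
                seen.add(key)
                merged.append(canonical)
        out.append(rec.with_reactions(merged) if tuple(merged) != rec.reactions else rec)
    return out


def aggregate_to_soc(
    records: list[ICSRecord],
    meddra: MedDRAMap,
    unmapped_label: str = UNMAPPED_SOC,
) -> dict[str, int]:
    """Case-level SOC counts: each record adds at most 1 per SOC.

    Canonical PTs without a SOC entry count under ``unmapped_label``.
    Counts are independent of record order.
    """
    counts: dict[str, int] = {}
    for rec in records:
        socs = {meddra.soc_of(pt) or unmapped_label for pt in rec.reactions}
        for soc in socs:
            counts[soc] = counts.get(soc, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
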