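"""Descriptive statistics on a serious-report cohort.

Per-PT frequency tables, sex and age stratification with a continuity-
corrected chi-square test on the 2x2 table, and the fatal-outcome summary.

The stratified tables use the Yates-corrected chi-square statistic in its
non-floored form: every corrected deviation ``|O - E| - 0.5`` is squared as
signed, i.e. the correction is applied even when ``|O - E| < 0.5`` (where the
textbook convention would floor the deviation at zero).  This is the variant
SPSS-style 2x2 output produces and is offered next to the floored textbook
form via the ``floored`` flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .icsr import AgeGroup, ICSRecord, Sex

__all__ = [
    "ContingencyTable2x2",
    "StratifiedReactionTable",
    "DeathSummary",
    "reaction_frequency",
    "yates_chi_square",
    "sex_distribution",
    "age_distribution",
    "death_summary",
    "round_half_up",
]


def round_half_up(x: float, digits: int) -> float:
    """Decimal round-half-up, matching conventional display rounding."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 table (rows: event present/absent; columns: strata)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.total < 1:
            raise ValueError("contingency table must have a positive grand total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class StratifiedReactionTable:
    """One PT row of a sex- or age-stratified table.

    Percentages of each stratum refer to the row total; ``pct_of_all`` refers
    to the full cohort size.  ``p_value`` is None when the test is not
    applicable (a zero margin), mirroring an "N.A." table entry.
    """

    term: str
    count_stratum1: int
    count_stratum2: int
    cohort_size: int
    chi2: float | None
    p_value: float | None

    @property
    def row_total(self) -> int:
        return self.count_stratum1 + self.count_stratum2

    @property
    def pct_stratum1(self) -> float:
        return 100.0 * self.count_stratum1 / self.row_total if self.row_total else 0.0

    @property
    def pct_stratum2(self) -> float:
        return 100.0 * self.count_stratum2 / self.row_total if self.row_total else 0.0

    @property
    def pct_of_all(self) -> float:
        return round_half_up(100.0 * self.row_total / self.cohort_size, 1)


def reaction_frequency(
    records: Sequence[ICSRecord], min_count: int = 1
) -> list[tuple[str, int, float]]:
    """Per-PT case counts in descending order with percent of all reports.

    ``pct_of_all`` is computed against the full cohort size even though rows
    below ``min_count`` are omitted.  Records are assumed synonym-normalized.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    n = len(records)
    counts: dict[str, int] = {}
    labels: dict[str, str] = {}
    for rec in records:
        for pt in rec.reactions:
            key = pt.casefold()
            labels.setdefault(key, pt)
            counts[key] = counts.get(key, 0) + 1
    rows = [
        (labels[k], c, round_half_up(100.0 * c / n, 1))
        for k, c in counts.items()
        if c >= min_count
    ]
    rows.sort(key=lambda r: (-r[1], r[0].casefold()))
    return rows


def yates_chi_square(
    table: ContingencyTable2x2, floored: bool = False
) -> tuple[float, float]:
    """Continuity-corrected chi-square on a 2x2 table with 1 df.

    With ``floored=False`` (default) the corrected deviation is squared even
    when ``|O - E| < 0.5``; with ``floored=True`` it is floored at zero
    (textbook Yates).  Degenerate margins (a zero row or column) return
    ``(0.0, 1.0)`` with a warning.  The p-value is the upper tail of the
    chi-squared distribution with one degree of freedom, equal to
    ``erfc(sqrt(chi2 / 2))``.
    """
    a, b, c, d = (float(x) for x in table.cells)
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        warnings.warn(
            "degenerate 2x2 margins: chi-square not applicable, returning p = 1",
            stacklevel=2,
        )
        return 0.0, 1.0
    chi2 = 0.0
    for obs, r, col in ((a, row1, col1), (b, row1, col2), (c, row2, col1), (d, row2, col2)):
        expected = r * col / n
        dev = abs(obs - expected) - 0.5
        if floored:
            dev = max(dev, 0.0)
        chi2 += dev * dev / expected
    return chi2, math.erfc(math.sqrt(chi2 / 2.0))


def _stratified(
    records: Sequence[ICSRecord],
    term: str,
    in_stratum1,
    in_stratum2,
    floored: bool,
) -> StratifiedReactionTable:
    n1 = n2 = k1 = k2 = 0
    found = False
    for rec in records:
        has = rec.has_reaction(term)
        found = found or has
        if in_stratum1(rec):
            n1 += 1
            k1 += has
        elif in_stratum2(rec):
            n2 += 1
            k2 += has
    if not found:
        raise ValueError(f"term {term!r} absent from the cohort")
    table = ContingencyTable2x2(a=k1, b=k2, c=n1 - k1, d=n2 - k2)
    if k1 == 0 or k2 == 0:
        # term present in only one stratum: not applicable, no test
        chi2: float | None = None
        p: float | None = None
    else:
        chi2, p = yates_chi_square(table, floored=floored)
    return StratifiedReactionTable(
        term=term,
        count_stratum1=k1,
        count_stratum2=k2,
        cohort_size=len(records),
        chi2=chi2,
        p_value=p,
    )


def sex_distribution(
    records: Sequence[ICSRecord], term: str, floored: bool = False
) -> StratifiedReactionTable:
    """Male/female 2x2 for ``term`` with the corrected chi-square attached.

    Unknown-sex records are excluded from the test margins but retained in
    the ``pct_of_all`` denominator.
    """
    return _stratified(
        records,
        term,
        lambda r: r.sex is Sex.MALE,
        lambda r: r.sex is Sex.FEMALE,
        floored,
    )


def age_distribution(
    records: Sequence[ICSRecord],
    term: str,
    groups: tuple[frozenset[AgeGroup], frozenset[AgeGroup]] = (
        frozenset({AgeGroup.Y18_64}),
        frozenset({AgeGroup.Y65_85}),
    ),
    floored: bool = False,
) -> StratifiedReactionTable:
    """As :func:`sex_distribution` with columns given by two age strata.

    The cohort is restricted to the two strata for the test margins; the
    default contrast is adults (18-64) versus the elderly (65-85).
    """
    g1, g2 = groups
    if not g1 or not g2:
        raise ValueError("both age strata must be non-empty")
    if g1 & g2:
        raise ValueError(f"age strata overlap: {sorted(g.value for g in g1 & g2)}")
    return _stratified(
        records,
        term,
        lambda r: r.age_group in g1,
        lambda r: r.age_group in g2,
        floored,
    )


@dataclass(frozen=True)
class DeathSummary:
    """Fatal-outcome counts with percentages against stated denominators."""

    total: int
    cohort_size: int
    by_age: dict[AgeGroup, tuple[int, int]]  # group -> (deaths, stratum size)
    by_sex: dict[Sex, int]  # percentages vs. the full cohort

    @property
    def pct_total(self) -> float:
        return round_half_up(100.0 * self.total / self.cohort_size, 1)

    def pct_age(self, group: AgeGroup) -> float:
        deaths, n = self.by_age[group]
        return round_half_up(100.0 * deaths / n, 1) if n else 0.0

    def pct_sex(self, sex: Sex) -> float:
        return round_half_up(100.0 * self.by_sex.get(sex, 0) / self.cohort_size, 1)


def death_summary(
    records: Sequence[ICSRecord],
    exclude_terms: Iterable[str] = ("Completed suicide",),
    age_groups: Iterable[AgeGroup] = (AgeGroup.Y18_64, AgeGroup.Y65_85),
) -> DeathSummary:
    """Count fatal reports whose reactions avoid ``exclude_terms``.

    The default excludes completed suicide so the summary captures deaths
    from other causes.  Age percentages use the per-stratum sizes; sex
    percentages use the full cohort size.
    """
    exclude = {t.casefold() for t in exclude_terms}
    age_groups = tuple(age_groups)
    deaths_by_age = {g: 0 for g in age_groups}
    sizes_by_age = {g: 0 for g in age_groups}
    by_sex: dict[Sex, int] = {}
    total = 0
    for rec in records:
        if rec.age_group in sizes_by_age:
            sizes_by_age[rec.age_group] += 1
        if not rec.outcome_death:
            continue
        if any(pt.casefold() in exclude for pt in rec.reactions):
            continue
        total += 1
        if rec.age_group in deaths_by_age:
            deaths_by_age[rec.age_group] += 1
        by_sex[rec.sex] = by_sex.get(rec.sex, 0) + 1
    return DeathSummary(
        total=total,
        cohort_size=len(records),
        by_age={g: (deaths_by_age[g], sizes_by_age[g]) for g in age_groups},
        by_sex=by_sex,
    )
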