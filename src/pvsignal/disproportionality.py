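"""Case/non-case disproportionality between drug cohorts.

Within a spontaneous-reporting database, the reporting odds ratio (ROR)
compares the odds that a report for drug A mentions a given event against
the same odds for a comparator drug B:

    ROR = (a * d) / (b * c)

with a = drug-A reports mentioning the event, b = drug-A reports not
mentioning it, and c, d likewise for drug B.  The 95% confidence interval is
computed on the log scale (Woolf):

    exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))

A result is flagged as a signal when the lower CI bound exceeds 1.  The ROR
is a signal-detection statistic, not a causal risk estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from .descriptive import ContingencyTable2x2, round_half_up
from .icsr import ICSRecord, MedDRAMap

__all__ = [
    "Z_95",
    "DisproportionalityResult",
    "build_case_noncase",
    "ror_with_ci",
    "compare_drug_panel",
]

#: standard normal 97.5% quantile used for 95% intervals
Z_95 = 1.959964

ZeroCellPolicy = Literal["haldane", "none"]


@dataclass(frozen=True)
class DisproportionalityResult:
    """ROR point estimate with Woolf CI and signal flag for one event."""

    event_label: str
    drug_a: str
    drug_b: str
    table: ContingencyTable2x2
    ror: float
    ci_low: float
    ci_high: float
    z_quantile: float = Z_95
    corrected: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ror <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    @property
    def signal(self) -> bool:
        """Disproportionality signal: the CI lower bound exceeds 1."""
        return self.ci_low > 1.0

    @property
    def ror_display(self) -> float:
        return round_half_up(self.ror, 2)

    @property
    def ci_display(self) -> tuple[float, float]:
        return (round_half_up(self.ci_low, 2), round_half_up(self.ci_high, 2))


def _matches_event(record: ICSRecord, event: str, meddra: MedDRAMap | None) -> bool:
    if meddra is not None and event in meddra.socs:
        return any((meddra.soc_of(pt) or "") == event for pt in record.reactions)
    return record.has_reaction(event)


def build_case_noncase(
    records_a: Sequence[ICSRecord],
    records_b: Sequence[ICSRecord],
    event: str,
    meddra: MedDRAMap | None = None,
) -> ContingencyTable2x2:
    """Case/non-case 2x2 for ``event`` between two filtered cohorts.

    ``event`` names either a canonical PT or, when ``meddra`` is given and
    knows the label as a SOC, a System Organ Class; counting is case-level.
    """
    if not records_a or not records_b:
        raise ValueError("both cohorts must be non-empty")
    a = sum(_matches_event(r, event, meddra) for r in records_a)
    c = sum(_matches_event(r, event, meddra) for r in records_b)
    return ContingencyTable2x2(a=a, b=len(records_a) - a, c=c, d=len(records_b) - c)


def ror_with_ci(
    table: ContingencyTable2x2,
    event_label: str = "",
    drug_a: str = "A",
    drug_b: str = "B",
    z_quantile: float = Z_95,
    correction: ZeroCellPolicy = "haldane",
) -> DisproportionalityResult:
    """ROR with Woolf log-normal CI.

    A zero cell under the ``haldane`` policy adds 0.5 to every cell
    (Haldane-Anscombe) and marks the result ``corrected``; under ``none`` a
    zero in b or c raises, since the ratio is undefined.
    """
    a, b, c, d = (float(x) for x in table.cells)
    corrected = False
    if min(a, b, c, d) == 0.0:
        if correction == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        elif b == 0.0 or c == 0.0:
            raise ZeroDivisionError(
                "undefined ROR: zero non-case/case cell with correction policy 'none'"
            )
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(ror)
    return DisproportionalityResult(
        event_label=event_label,
        drug_a=drug_a,
        drug_b=drug_b,
        table=table,
        ror=ror,
        ci_low=math.exp(log_ror - z_quantile * se),
        ci_high=math.exp(log_ror + z_quantile * se),
        z_quantile=z_quantile,
        corrected=corrected,
    )


def compare_drug_panel(
    cohorts: Mapping[str, Sequence[ICSRecord]],
    events: Sequence[str],
    reference_pairs: Sequence[tuple[str, str]],
    meddra: MedDRAMap | None = None,
    z_quantile: float = Z_95,
    correction: ZeroCellPolicy = "haldane",
) -> list[DisproportionalityResult]:
    """One disproportionality result per (event, drug pair), in input order."""
    for pair in reference_pairs:
        for drug in pair:
            if drug not in cohorts:
                raise ValueError(f"unknown drug in reference pair: {drug!r}")
    results: list[DisproportionalityResult] = []
    for event in events:
        for drug_a, drug_b in reference_pairs:
            table = build_case_noncase(cohorts[drug_a], cohorts[drug_b], event, meddra)
            results.append(
                ror_with_ci(
                    table,
                    event_label=event,
                    drug_a=drug_a,
                    drug_b=drug_b,
                    z_quantile=z_quantile,
                    correction=correction,
                )
            )
    return results
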