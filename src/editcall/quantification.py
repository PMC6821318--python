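"""Aggregation of per-read calls into frequencies, ratios and fold-changes."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .outcome_classifier import CATEGORIES, ReadCall

_SCORED = ("WT", "HDR", "MIX", "NHEJ", "MMEJ")


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeCounts:
    """Per-target tally of read categories.

    Percentages are computed over non-discarded reads and sum to 100.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", {cat: int(self.counts.get(cat, 0)) for cat in CATEGORIES}
        )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def classified(self) -> int:
        return sum(self.counts[c] for c in _SCORED)

    @property
    def percentages(self) -> dict[str, float]:
        denom = self.classified
        if denom == 0:
            raise QuantificationError("no classifiable reads")
        return {c: 100.0 * self.counts[c] / denom for c in _SCORED}


def tabulate(calls: Iterable[ReadCall]) -> OutcomeCounts:
    """Count categories over a set of read calls.

    Raises if every read was discarded (or the input is empty): percentages
    are undefined without at least one classifiable read.
    """
    counts = Counter(call.category for call in calls)
    out = OutcomeCounts(counts)
    if out.classified == 0:
        raise QuantificationError("no classifiable reads")
    return out


def hdr_to_error_prone_ratio(
    hdr: float | OutcomeCounts, nhej: float | None = None, mmej: float | None = None
) -> float:
    """Ratio of HDR to the sum of the error-prone outcomes (NHEJ + MMEJ).

    Accepts either an :class:`OutcomeCounts` or three numbers (counts or
    percentages — the ratio is scale-invariant).  A zero denominator is an
    error, reported as such rather than as infinity.
    """
    if isinstance(hdr, OutcomeCounts):
        c = hdr.counts
        hdr, nhej, mmej = c["HDR"], c["NHEJ"], c["MMEJ"]
    if nhej is None or mmej is None:
        raise QuantificationError("need NHEJ and MMEJ values")
    denom = nhej + mmej
    if denom == 0:
        raise QuantificationError("undefined ratio: NHEJ + MMEJ is zero")
    return hdr / denom


def mean_ratio_of_runs(per_run: Sequence[tuple[float, float, float]]) -> float:
    """Mean of per-run HDR/(NHEJ+MMEJ) ratios, for per-gene averaging.

    The alternative estimator to the ratio-of-averages; the two disagree
    whenever per-run denominators vary.
    """
    if not per_run:
        raise QuantificationError("no runs")
    return sum(hdr_to_error_prone_ratio(h, n, m) for h, n, m in per_run) / len(per_run)


def fold_change(a: float, b: float) -> float:
    """``a / b`` rounded to one decimal, matching the reporting granularity."""
    if b == 0:
        raise QuantificationError("fold change undefined for zero denominator")
    return round(a / b, 1)


def multiplex_table(per_target: Mapping[str, OutcomeCounts]) -> pd.DataFrame:
    """One row per target with category percentages and read counts.

    Row order follows the input mapping order.
    """
    if not per_target:
        raise QuantificationError("need at least one target")
    rows = []
    for name, counts in per_target.items():
        row: dict[str, object] = {"target": name}
        row.update({f"{c}_pct": p for c, p in counts.percentages.items()})
        row.update({f"{c}_n": counts.counts[c] for c in CATEGORIES})
        row["total_reads"] = counts.total
        rows.append(row)
    return pd.DataFrame(rows).set_index("target")
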