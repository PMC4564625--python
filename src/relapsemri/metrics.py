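"""Balanced error rate per decision-aligned offset and its weighted summary.

For each offset i relative to the decision session, the balanced error
rate averages the two per-class misclassification rates

    BER_i = (ERR_i^resp + ERR_i^prog) / 2,

where ERR^resp is the fraction of responsive patients predicted
progressive and ERR^prog the converse.  When only one class is present
at an offset, the error rate of that class alone is reported (the other
term is 0/0 and is dropped); a single misclassified lone patient thus
scores 1, not 0.5.

Per-offset BERs are summarised into one number, the weighted BER

    wBER = sum_i W_p^i W_t^i BER_i / sum_i W_p^i W_t^i,

with a temporal weight W_t = 1 at and after the decision and
1 - (0.5/11) * k at k sessions before it (a linear ramp reaching 0.5 at
the study's deepest pre-decision offset, 11), and a population weight
W_p proportional to the number of patients observed at the offset (its
normaliser cancels in the ratio).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .schema import CLASSES, PROGRESSIVE, RESPONSIVE

#: slope of the pre-decision temporal ramp
TEMPORAL_SLOPE = 0.5 / 11


class MetricsError(ValueError):
    pass


def balanced_error_rate(
    truth: Sequence[str], predicted: Sequence[str]
) -> float:
    """Mean per-class error rate; single-class inputs use the present class."""
    if len(truth) == 0:
        raise MetricsError("empty input")
    if len(truth) != len(predicted):
        raise MetricsError("truth and predicted differ in length")
    bad = set(truth) | set(predicted)
    if not bad <= set(CLASSES):
        raise MetricsError(f"unknown labels: {sorted(bad - set(CLASSES))}")
    rates = []
    for cls in (RESPONSIVE, PROGRESSIVE):
        total = sum(t == cls for t in truth)
        if total == 0:
            continue
        wrong = sum(t == cls and p != cls for t, p in zip(truth, predicted))
        rates.append(wrong / total)
    return sum(rates) / len(rates)


def temporal_weight(i: int) -> float:
    """Weight for a session i ordinal steps before the decision (i=0: at/after)."""
    if i < 0:
        raise MetricsError("i counts steps before the decision; must be >= 0")
    return 1.0 if i == 0 else 1.0 - TEMPORAL_SLOPE * i


@dataclass
class BerSeries:
    """Per-offset balanced error rates with per-offset patient counts.

    ``entries`` maps signed offset -> (ber, n_patients); an offset with
    no data simply has no entry.
    """

    entries: dict[int, tuple[float, int]] = field(default_factory=dict)

    def add(self, offset: int, ber: float, n_patients: int) -> None:
        if n_patients < 1:
            raise MetricsError("n_patients must be >= 1 where a BER exists")
        if not 0.0 <= ber <= 1.0:
            raise MetricsError(f"BER out of [0,1]: {ber}")
        self.entries[offset] = (float(ber), int(n_patients))

    def offsets(self) -> list[int]:
        return sorted(self.entries, reverse=True)


def weighted_ber(series: BerSeries) -> float:
    """Temporal- and population-weighted average of a BER series.

    Offsets without data contribute nothing; the population-weight
    normaliser cancels, so only the per-offset counts matter.
    """
    if not series.entries:
        raise MetricsError("empty BER series")
    num = 0.0
    den = 0.0
    for offset, (ber, n) in series.entries.items():
        w = n * temporal_weight(max(0, -offset))
        num += w * ber
        den += w
    return num / den


# ---------------------------------------------------------------------------
# Offset-labelled table I/O ("L + 1", "L", "L - 11", ...)

_LABEL_RE = re.compile(r"^\s*L\s*(?:([+−–-])\s*(\d+))?\s*$")


def parse_offset_label(label: str) -> int:
    """Parse an "L±k" time-point label into a signed offset."""
    m = _LABEL_RE.match(str(label))
    if not m:
        raise MetricsError(f"cannot parse time-point label {label!r}")
    if m.group(1) is None:
        return 0
    sign = 1 if m.group(1) == "+" else -1
    return sign * int(m.group(2))


def format_offset_label(offset: int) -> str:
    if offset == 0:
        return "L"
    return f"L{'+' if offset > 0 else '-'}{abs(offset)}"


def read_counts_table(path: str | Path) -> dict[int, int]:
    """Read a per-offset patient-count table (columns: time_point, count)."""
    frame = pd.read_csv(path)
    cols = list(frame.columns)
    if len(cols) < 2:
        raise MetricsError("counts table needs a label column and a count column")
    label_col, count_col = cols[0], cols[1]
    return {
        parse_offset_label(row[label_col]): int(row[count_col])
        for _, row in frame.iterrows()
    }


def wber_from_tables(
    ber_table: str | Path, counts_table: str | Path | Mapping[int, int]
) -> dict[str, float]:
    """Weighted BER per classifier column of an offset-labelled BER table.

    ``ber_table`` has one row per "L±k" label and one column per
    classifier, with blank cells where no session was available; the
    counts table maps the same labels to patient counts.  Offsets with a
    zero count or a blank BER contribute nothing.
    """
    frame = pd.read_csv(ber_table)
    label_col = frame.columns[0]
    if isinstance(counts_table, (str, Path)):
        counts = read_counts_table(counts_table)
    else:
        counts = dict(counts_table)
    result: dict[str, float] = {}
    offsets = [parse_offset_label(v) for v in frame[label_col]]
    missing = [format_offset_label(o) for o in offsets if o not in counts]
    if missing:
        raise MetricsError(f"offsets absent from counts table: {missing}")
    for col in frame.columns[1:]:
        series = BerSeries()
        for offset, value in zip(offsets, frame[col]):
            if pd.isna(value) or counts[offset] == 0:
                continue
            series.add(offset, float(value), counts[offset])
        if not series.entries:
            raise MetricsError(f"classifier column {col!r} has no BER values")
        result[col] = weighted_ber(series)
    return result


def series_to_frame(
    series_by_classifier: Mapping[str, BerSeries],
    offsets: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Render BER series as an offset-labelled table (NaN where absent)."""
    if offsets is None:
        all_offsets: set[int] = set()
        for series in series_by_classifier.values():
            all_offsets.update(series.entries)
        offsets = sorted(all_offsets, reverse=True)
    offsets = list(offsets)
    data = {
        name: [series.entries.get(o, (math.nan, 0))[0] for o in offsets]
        for name, series in series_by_classifier.items()
    }
    return pd.DataFrame(
        {"time_point": [format_offset_label(o) for o in offsets], **data}
    )
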