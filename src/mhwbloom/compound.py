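"""Compound SST-chlorophyll extremes within regional blooming periods.

The biological hypothesis: heatwaves stratify the water column and starve the
surface of nutrients, so an MHW is expected to pair with a *low* Chl-a
extreme; cold-spells deepen mixing, so an MCS pairs with a *high* Chl-a
extreme. Each regional blooming period (one winter season) is one case: its
SST extremes are matched against Chl-a extremes that overlap them or start
within a short delay after them, and the season is classified by the best
match it contains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .events import ExtremeEvent

__all__ = [
    "BloomingPeriod",
    "Match",
    "CompoundCase",
    "CaseSummary",
    "DEFAULT_BLOOMING_PERIODS",
    "resolve_period",
    "match_compounds",
    "classify_blooming_period",
    "summarize_cases",
    "cases_to_frame",
]

Classification = Literal["expected", "opposite", "sst_only", "none"]


@dataclass(frozen=True)
class BloomingPeriod:
    """A regional blooming window as (month, day) endpoints.

    ``end_day=None`` means the last day of ``end_month`` in the resolved year
    (so December-February windows end on 28 or 29 February as appropriate).
    Windows whose end falls before their start in the calendar cross the year
    boundary and end in the following year.
    """

    region: str
    start_month: int
    start_day: int = 1
    end_month: int = 12
    end_day: int | None = None


#: Regional winter blooming windows plus the basin-wide six-month window.
DEFAULT_BLOOMING_PERIODS: dict[str, BloomingPeriod] = {
    "NRS": BloomingPeriod("NRS", 1, 1, 3, 31),          # January - March
    "NCRS": BloomingPeriod("NCRS", 12, 1, 2, None),     # December - February
    "SCRS": BloomingPeriod("SCRS", 12, 1, 2, None),     # December - February
    "SRS": BloomingPeriod("SRS", 10, 1, 1, 31),         # October - January
    "basin": BloomingPeriod("basin", 10, 1, 3, 31),     # October - March
}


def resolve_period(period: BloomingPeriod, season_year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Concrete date span of a blooming period for one season.

    ``season_year`` is the year containing the window start; cross-year
    windows (e.g. October-January) end in ``season_year + 1``.
    """
    try:
        start = pd.Timestamp(season_year, period.start_month, period.start_day)
    except ValueError as exc:
        raise ValueError(f"invalid period start for {period.region}: {exc}") from exc
    end_year = season_year
    if (period.end_month, period.end_day or 1) < (period.start_month, period.start_day):
        end_year += 1
    end_day = period.end_day
    if end_day is None:
        end_day = pd.Timestamp(end_year, period.end_month, 1).days_in_month
    try:
        end = pd.Timestamp(end_year, period.end_month, end_day)
    except ValueError as exc:
        raise ValueError(f"invalid period end for {period.region}: {exc}") from exc
    if end < start:
        raise ValueError(f"period {period.region} resolves to a reversed span")
    return start, end


@dataclass(frozen=True)
class Match:
    """One matched (SST extreme, Chl-a extreme) pair."""

    sst_event: ExtremeEvent
    chla_event: ExtremeEvent
    relation: Literal["concurrent", "lagged"]

    @property
    def expected_direction(self) -> bool:
        """True for MHW-LChl-a or MCS-HChl-a (the hypothesised pattern)."""
        return self.sst_event.polarity != self.chla_event.polarity


def match_compounds(
    sst_events: Sequence[ExtremeEvent],
    chla_events: Sequence[ExtremeEvent],
    max_lag: int = 7,
) -> list[Match]:
    """All (SST, Chl-a) pairs that are concurrent or lagged.

    Concurrent: the spans share at least one calendar day. Lagged: the Chl-a
    event starts 1..max_lag days after the SST event's last day. An event may
    participate in several matches.
    """
    matches: list[Match] = []
    for se in sst_events:
        for ce in chla_events:
            if ce.overlaps(se.start, se.end):
                matches.append(Match(se, ce, "concurrent"))
            else:
                delay = (ce.start - se.end).days
                if 1 <= delay <= max_lag:
                    matches.append(Match(se, ce, "lagged"))
    return matches


@dataclass(frozen=True)
class CompoundCase:
    """One blooming period with its events, matches and classification."""

    period: BloomingPeriod
    season_year: int
    start: pd.Timestamp
    end: pd.Timestamp
    sst_events: tuple[ExtremeEvent, ...]
    chla_events: tuple[ExtremeEvent, ...]
    matches: tuple[Match, ...]
    classification: Classification
    ambiguous: bool = False    # both expected- and opposite-direction matches
    chl_only: bool = False     # Chl-a extremes present but no SST extreme


def classify_blooming_period(
    period: BloomingPeriod,
    season_year: int,
    sst_events: Sequence[ExtremeEvent],
    chla_events: Sequence[ExtremeEvent],
    max_lag: int = 7,
) -> CompoundCase:
    """Clip events to the resolved window, match them, classify the season.

    Classification precedence: ``expected`` (at least one expected-direction
    match) > ``opposite`` (matches exist, all in the unexpected direction) >
    ``sst_only`` (SST extremes but no matching Chl-a extreme) > ``none`` (no
    SST extreme overlaps the window). Event order never affects the result.
    An event belongs to the window if any of its days intersects it; event
    metrics are not re-clipped.
    """
    start, end = resolve_period(period, season_year)
    sst_in = tuple(sorted((e for e in sst_events if e.overlaps(start, end)),
                          key=lambda e: e.start))
    chla_in = tuple(sorted((e for e in chla_events if e.overlaps(start, end)),
                           key=lambda e: e.start))
    matches = tuple(match_compounds(sst_in, chla_in, max_lag=max_lag))
    has_expected = any(m.expected_direction for m in matches)
    has_opposite = any(not m.expected_direction for m in matches)
    if not sst_in:
        classification: Classification = "none"
    elif has_expected:
        classification = "expected"
    elif has_opposite:
        classification = "opposite"
    else:
        classification = "sst_only"
    return CompoundCase(
        period=period,
        season_year=season_year,
        start=start,
        end=end,
        sst_events=sst_in,
        chla_events=chla_in,
        matches=matches,
        classification=classification,
        ambiguous=has_expected and has_opposite,
        chl_only=(not sst_in and bool(chla_in)),
    )


@dataclass(frozen=True)
class CaseSummary:
    """Counts per classification and the expected-response rate.

    ``percent_expected`` uses only cases with at least one SST extreme as the
    denominator; seasons with Chl-a extremes but no SST extreme are counted
    separately in ``n_chl_only``.
    """

    n_cases: int
    counts: dict[str, int]
    n_with_sst: int
    n_chl_only: int
    percent_expected: float
    percent_expected_rounded: int


def summarize_cases(cases: Sequence[CompoundCase]) -> CaseSummary:
    if not cases:
        raise ValueError("no cases to summarize")
    counts = {"expected": 0, "opposite": 0, "sst_only": 0, "none": 0}
    for c in cases:
        counts[c.classification] += 1
    n_with_sst = sum(1 for c in cases if c.sst_events)
    if n_with_sst == 0:
        pct = float("nan")
        rounded = 0
    else:
        pct = 100.0 * counts["expected"] / n_with_sst
        rounded = int(round(pct))
    return CaseSummary(
        n_cases=len(cases),
        counts=counts,
        n_with_sst=n_with_sst,
        n_chl_only=sum(1 for c in cases if c.chl_only),
        percent_expected=pct,
        percent_expected_rounded=rounded,
    )


def cases_to_frame(cases: Iterable[CompoundCase]) -> pd.DataFrame:
    """Case table in the shape of a per-season supplementary table."""
    rows = []
    for c in cases:
        rows.append(
            {
                "region": c.period.region,
                "season_year": c.season_year,
                "window_start": c.start.date().isoformat(),
                "window_end": c.end.date().isoformat(),
                "n_mhw": sum(1 for e in c.sst_events if e.polarity == "high"),
                "n_mcs": sum(1 for e in c.sst_events if e.polarity == "low"),
                "n_hchla": sum(1 for e in c.chla_events if e.polarity == "high"),
                "n_lchla": sum(1 for e in c.chla_events if e.polarity == "low"),
                "n_matches": len(c.matches),
                "classification": c.classification,
                "ambiguous": c.ambiguous,
                "chl_only": c.chl_only,
            }
        )
    columns = [
        "region", "season_year", "window_start", "window_end", "n_mhw", "n_mcs",
        "n_hchla", "n_lchla", "n_matches", "classification", "ambiguous", "chl_only",
    ]
    return pd.DataFrame(rows, columns=columns)
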