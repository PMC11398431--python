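"""Federated aggregation of per-site cohort summaries.

Sites never exchange patient-level records; each runs the same code on its
local CLIF database and shares a :class:`SiteSummary` of counts and moments.
This module combines those summaries into a consortium-level table:
counts are summed, percentages recomputed from the combined numerator and
denominator, the combined age mean is the encounter-weighted mean of site
means, and the combined SD is the pooled between+within approximation
recovered from each site's (n, mean, SD).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd


@dataclass
class SiteSummary:
    """Characteristics and outcomes of one site's ICU encounters."""

    site: str
    encounters: int
    hospitals: int
    age_mean: float
    age_sd: float
    female: int
    race: dict = field(default_factory=dict)       # category -> n
    ethnicity: dict = field(default_factory=dict)  # category -> n
    imv: int = 0
    deaths: int = 0

    def __post_init__(self) -> None:
        if self.encounters < 0:
            raise ValueError("encounters must be non-negative")
        for label, counts in (("race", self.race), ("ethnicity", self.ethnicity)):
            for cat, n in counts.items():
                if n < 0 or n > self.encounters:
                    raise ValueError(
                        f"{label}[{cat}] count {n} outside [0, encounters]"
                    )
        for name in ("female", "imv", "deaths"):
            n = getattr(self, name)
            if n < 0 or n > self.encounters:
                raise ValueError(f"{name} count {n} outside [0, encounters]")

    # -- percentages -----------------------------------------------------
    def pct(self, numerator: int) -> float:
        return 100.0 * numerator / self.encounters if self.encounters else 0.0

    # -- serialization ---------------------------------------------------
    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SiteSummary":
        from ._io import load_json_source
        return cls(**load_json_source(source))


def _moments(summary: SiteSummary):
    """Recover (n, sum, sum of squares) of age from n/mean/SD so that pooling
    is exact and associative up to float rounding."""
    n = summary.encounters
    s1 = n * summary.age_mean
    s2 = (n - 1) * summary.age_sd ** 2 + n * summary.age_mean ** 2 if n > 1 else \
        n * summary.age_mean ** 2
    return n, s1, s2


def aggregate_sites(summaries, site_label: str = "combined") -> SiteSummary:
    """Combine per-site summaries into one consortium summary.

    Counts are summed; the combined age SD is the pooled approximation from
    site-level (n, mean, SD) and is approximate whenever site SDs were
    themselves rounded. Category sets must agree across sites.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("need at least one site summary")
    race_keys = set(summaries[0].race)
    eth_keys = set(summaries[0].ethnicity)
    for s in summaries[1:]:
        if set(s.race) != race_keys or set(s.ethnicity) != eth_keys:
            raise ValueError(
                f"mismatched category sets between {summaries[0].site!r} and {s.site!r}"
            )

    n_tot = sum(s.encounters for s in summaries)
    if n_tot == 0:
        raise ValueError("combined cohort is empty")
    s1 = sum(_moments(s)[1] for s in summaries)
    s2 = sum(_moments(s)[2] for s in summaries)
    mean = s1 / n_tot
    var = (s2 - n_tot * mean ** 2) / (n_tot - 1) if n_tot > 1 else 0.0
    sd = math.sqrt(max(var, 0.0))

    return SiteSummary(
        site=site_label,
        encounters=n_tot,
        hospitals=sum(s.hospitals for s in summaries),
        age_mean=mean,
        age_sd=sd,
        female=sum(s.female for s in summaries),
        race={k: sum(s.race[k] for s in summaries) for k in sorted(race_keys)},
        ethnicity={k: sum(s.ethnicity[k] for s in summaries) for k in sorted(eth_keys)},
        imv=sum(s.imv for s in summaries),
        deaths=sum(s.deaths for s in summaries),
    )


# ---------------------------------------------------------------------------
# Publication-style formatting
# ---------------------------------------------------------------------------

def format_pct(numerator: int, denominator: int) -> str:
    """Percentage with table-one rounding: one decimal below 10% (two
    significant figures), whole percent otherwise; zero prints as ``0%``."""
    if denominator <= 0 or numerator == 0:
        return "0%"
    pct = 100.0 * numerator / denominator
    if round(pct, 1) < 10.0:
        return f"{pct:.1f}%"
    return f"{pct:.0f}%"


def format_count_pct(numerator: int, denominator: int) -> str:
    """``"n (pct%)"`` cell, e.g. ``8920 (9.5%)``."""
    return f"{numerator} ({format_pct(numerator, denominator)})"


def format_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.1f} ({sd:.1f})"


def format_table_one(summaries, combined_label: str = "combined") -> pd.DataFrame:
    """Render site summaries plus the combined column as a table-one.

    Rows: encounters, hospitals, age, female, race and ethnicity categories,
    mechanical ventilation, hospital mortality. Returns a DataFrame whose
    columns are site labels; export with ``.to_csv`` or ``.to_markdown``.
    """
    summaries = list(summaries)
    if len(summaries) > 1:
        summaries = summaries + [aggregate_sites(summaries, combined_label)]

    rows: dict = {}

    def put(row: str, site: str, value: str) -> None:
        rows.setdefault(row, {})[site] = value

    for s in summaries:
        put("Encounters, n", s.site, str(s.encounters))
        put("Hospitals, n", s.site, str(s.hospitals))
        put("Age (years), mean (SD)", s.site, format_mean_sd(s.age_mean, s.age_sd))
        put("Female n (%)", s.site, format_count_pct(s.female, s.encounters))
        for cat in sorted(s.race):
            put(f"Race: {cat} n (%)", s.site, format_count_pct(s.race[cat], s.encounters))
        for cat in sorted(s.ethnicity):
            put(f"Ethnicity: {cat} n (%)", s.site,
                format_count_pct(s.ethnicity[cat], s.encounters))
        put("Mechanical ventilation n (%)", s.site, format_count_pct(s.imv, s.encounters))
        put("Hospital mortality n (%)", s.site, format_count_pct(s.deaths, s.encounters))

    table = pd.DataFrame(rows).T
    table.index.name = "characteristic"
    return table


def write_table_one(table: pd.DataFrame, csv_path=None, md_path=None) -> None:
    if csv_path is not None:
        table.to_csv(csv_path)
    if md_path is not None:
        Path(md_path).write_text(table.to_markdown())
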