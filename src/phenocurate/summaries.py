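"""Descriptive summary tables of a curated collection.

Provenance composition (with sub-1% countries grouped under "Others"),
record counts by trait and decade, the distribution of distinct
regeneration years per accession, and the table of year-effect BLUPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_model import FitResult
from .records import Dataset, TRAITS, UNKNOWN_ORIGIN, decade_of
from .util import round_half_up


@dataclass
class ProvenanceSummary:
    """Accession counts and percentages by country of origin.

    ``rows`` lists origins at or above the grouping threshold, sorted by
    count descending; sub-threshold origins are pooled under Others and
    Unknown is always reported on its own row.  Counts conserve:
    listed + others + unknown = total.
    """

    rows: list[tuple[str, int, float]]
    others_count: int
    others_n_countries: int
    unknown_count: int
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.rows)
        rows.append(
            (
                f"Others ({self.others_n_countries})",
                self.others_count,
                round_half_up(100.0 * self.others_count / self.total, 2),
            )
        )
        rows.append(
            (
                UNKNOWN_ORIGIN,
                self.unknown_count,
                round_half_up(100.0 * self.unknown_count / self.total, 2),
            )
        )
        rows.append(("Total", self.total, 100.0))
        return pd.DataFrame(rows, columns=["origin", "n_accessions", "percentage"])

    def percentage_of(self, origin: str) -> float:
        for code, _, pct in self.rows:
            if code == origin:
                return pct
        raise KeyError(origin)

    def count_of(self, origin: str) -> int:
        if origin == UNKNOWN_ORIGIN:
            return self.unknown_count
        for code, n, _ in self.rows:
            if code == origin:
                return n
        raise KeyError(origin)


def provenance_table(dataset: Dataset, threshold_pct: float = 1.0) -> ProvenanceSummary:
    """Accession provenance composition.

    Origins with a share *strictly below* ``threshold_pct`` are grouped
    under Others (an origin at exactly the threshold stays listed);
    Unknown is excluded from the grouping.  Percentages are computed
    against the total and rounded half-up to 2 decimals.
    """
    accessions = set(dataset.df["accession_id"])
    if not accessions:
        raise ValueError("empty dataset")
    counts: dict[str, int] = {}
    for acc in accessions:
        origin = dataset.origin_of(acc)
        counts[origin] = counts.get(origin, 0) + 1
    total = len(accessions)
    unknown = counts.pop(UNKNOWN_ORIGIN, 0)
    listed: list[tuple[str, int, float]] = []
    others_count = 0
    others_n = 0
    for code, n in counts.items():
        share = 100.0 * n / total
        if share < threshold_pct:
            others_count += n
            others_n += 1
        else:
            listed.append((code, n, round_half_up(share, 2)))
    listed.sort(key=lambda row: (-row[1], row[0]))
    return ProvenanceSummary(
        rows=listed,
        others_count=others_count,
        others_n_countries=others_n,
        unknown_count=unknown,
        total=total,
    )


def records_by_decade(dataset: Dataset) -> pd.DataFrame:
    """Record and distinct-accession counts per trait and decade, plus totals."""
    rows = []
    df = dataset.df
    for trait in TRAITS:
        sub = df[df["trait"] == trait]
        if not sub.empty:
            dec = sub["year"].map(decade_of)
            grouped = sub.groupby(dec).agg(
                n_records=("value", "size"), n_accessions=("accession_id", "nunique")
            )
            for decade, row in grouped.iterrows():
                rows.append(
                    {
                        "trait": trait,
                        "decade": int(decade),
                        "n_records": int(row["n_records"]),
                        "n_accessions": int(row["n_accessions"]),
                    }
                )
        rows.append(
            {
                "trait": trait,
                "decade": "total",
                "n_records": int(len(sub)),
                "n_accessions": int(sub["accession_id"].nunique()),
            }
        )
    return pd.DataFrame(rows, columns=["trait", "decade", "n_records", "n_accessions"])


def regeneration_distribution(dataset: Dataset, trait: str) -> dict[int, int]:
    """Histogram: number of accessions tested for ``trait`` in k distinct years."""
    sub = dataset.df[dataset.df["trait"] == trait]
    if sub.empty:
        return {}
    ks = sub.groupby("accession_id")["year"].nunique()
    hist: dict[int, int] = {}
    for k in ks:
        hist[int(k)] = hist.get(int(k), 0) + 1
    return dict(sorted(hist.items()))


def year_effect_table(fit: FitResult) -> pd.DataFrame:
    """Year-effect BLUPs of a converged fit, one row per retained year.

    Shrunken towards zero; their weighted sum is approximately zero.
    """
    if not fit.converged:
        raise ValueError("year effects require a converged fit")
    years = sorted(fit.year_effects)
    return pd.DataFrame(
        {"year": years, "effect": [fit.year_effects[y] for y in years]}
    )
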