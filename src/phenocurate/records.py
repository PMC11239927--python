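"""Phenotype records and tab-delimited study/assay table I/O.

Historical genebank regeneration trials are stored as ISA-Tab style
tab-separated tables: one row per accession-year with up to three trait
columns (HD, PH, TGW).  Internally everything is long format -- one
:class:`PhenotypeRecord` per non-missing trait value -- held in a
:class:`Dataset` backed by a pandas DataFrame.

Trait units: HD in days since January 1 (50% heading, BBCH 59), PH in cm
from soil surface to spike tip including awns, TGW in g per 1,000 grains
at ~15% moisture.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAITS: tuple[str, ...] = ("HD", "PH", "TGW")
GROWTH_HABITS: tuple[str, ...] = ("spring", "winter")
VALUE_TYPES: tuple[str, ...] = ("single", "average")

#: sentinel origin for accessions without a reported provenance
UNKNOWN_ORIGIN = "Unknown"

#: tokens treated as missing on read; written back as "NA"
NA_TOKENS = ("", "NA")

#: default calendar-year window accepted on read
DEFAULT_YEAR_WINDOW = (1951, 2020)

#: default header names of assay tables; override via ``column_map``
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "accession": "Accession_ID",
    "year": "Year",
    "HD": "HD",
    "PH": "PH",
    "TGW": "TGW",
    "origin": "Origin",
    "value_type": "Value_type",
}

#: trait validity ranges (lower exclusive, upper inclusive or None)
TRAIT_RANGES: dict[str, tuple[float, float | None]] = {
    "HD": (0.0, 366.0),
    "PH": (0.0, None),
    "TGW": (0.0, None),
}


class PhenotypeRecord(NamedTuple):
    """One accession x year x trait observation."""

    accession_id: str
    year: int
    trait: str
    value: float
    growth_habit: str
    origin: str = UNKNOWN_ORIGIN
    value_type: str = "single"

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.accession_id, self.year, self.trait)


@dataclass
class ParseReport:
    """Row/record bookkeeping of one assay-table read.

    Conservation: ``rows_read = producing_rows + len(rejected_rows)
    + empty_rows``.
    """

    rows_read: int = 0
    records_produced: int = 0
    producing_rows: int = 0
    empty_rows: int = 0
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)
    rejected_cells: list[tuple[int, str, str]] = field(default_factory=list)
    duplicate_records: int = 0

    @property
    def conserved(self) -> bool:
        return self.rows_read == (
            self.producing_rows + len(self.rejected_rows) + self.empty_rows
        )


_DF_COLUMNS = ["accession_id", "year", "trait", "value", "value_type"]


class Dataset:
    """Long-format collection of phenotype records for one growth habit.

    The design may be non-orthogonal: accessions appear in differing,
    partially overlapping sets of years.  ``(accession_id, year, trait)``
    identifies at most one record; duplicates are dropped (first kept)
    with a warning.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        growth_habit: str,
        provenance: Mapping[str, str] | None = None,
        parse_report: ParseReport | None = None,
        validate: bool = True,
    ) -> None:
        if growth_habit not in GROWTH_HABITS:
            raise ValueError(f"unknown growth habit {growth_habit!r}")
        df = df.loc[:, _DF_COLUMNS].copy()
        df["accession_id"] = df["accession_id"].astype(str)
        df["year"] = df["year"].astype(int)
        df["trait"] = df["trait"].astype(str)
        df["value"] = df["value"].astype(float)
        if validate:
            bad = set(df["trait"]) - set(TRAITS)
            if bad:
                raise ValueError(f"unknown trait(s) {sorted(bad)}")
            dup = df.duplicated(subset=["accession_id", "year", "trait"])
            if dup.any():
                logger.warning(
                    "dropping %d duplicate (accession, year, trait) records "
                    "(first occurrence kept)",
                    int(dup.sum()),
                )
                df = df.loc[~dup]
        self.df = df.reset_index(drop=True)
        self.growth_habit = growth_habit
        self.provenance: dict[str, str] = dict(provenance or {})
        self.parse_report = parse_report

    # -- basic views -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def accessions(self, trait: str | None = None) -> list[str]:
        df = self.df if trait is None else self.df[self.df["trait"] == trait]
        return sorted(df["accession_id"].unique())

    def years(self, trait: str | None = None) -> list[int]:
        df = self.df if trait is None else self.df[self.df["trait"] == trait]
        return sorted(df["year"].unique())

    def origin_of(self, accession_id: str) -> str:
        return self.provenance.get(accession_id, UNKNOWN_ORIGIN)

    @property
    def records(self) -> Iterator[PhenotypeRecord]:
        for row in self.df.itertuples(index=False):
            yield PhenotypeRecord(
                row.accession_id,
                int(row.year),
                row.trait,
                float(row.value),
                self.growth_habit,
                self.origin_of(row.accession_id),
                row.value_type,
            )

    def keys(self) -> list[tuple[str, int, str]]:
        return list(
            zip(self.df["accession_id"], self.df["year"].astype(int), self.df["trait"])
        )

    # -- subsetting --------------------------------------------------

    def for_trait(self, trait: str) -> "Dataset":
        if trait not in TRAITS:
            raise ValueError(f"unknown trait {trait!r}")
        return Dataset(
            self.df[self.df["trait"] == trait],
            self.growth_habit,
            self.provenance,
            validate=False,
        )

    def remove_keys(self, keys: Iterable[tuple[str, int, str]]) -> "Dataset":
        """Return a new dataset without the given record keys."""
        drop = set(keys)
        if not drop:
            return Dataset(self.df, self.growth_habit, self.provenance, validate=False)
        mask = [k not in drop for k in self.keys()]
        return Dataset(
            self.df.loc[mask], self.growth_habit, self.provenance, validate=False
        )

    def sorted_record_tuples(self) -> list[tuple]:
        """Canonical sorted multiset of records, for round-trip checks."""
        return sorted(
            (r.accession_id, r.year, r.trait, r.value, r.origin, r.value_type)
            for r in self.records
        )


def decade_of(year: int) -> int:
    """Decade bin of a calendar year: floor(year / 10) * 10."""
    return (int(year) // 10) * 10


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _is_na(cell: str) -> bool:
    return cell.strip() in NA_TOKENS


def read_assay_table(
    path: str | Path,
    growth_habit: str,
    column_map: Mapping[str, str] | None = None,
    year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
) -> Dataset:
    """Read a wide assay table into a long-format :class:`Dataset`.

    Each input row carries one accession-year with up to three trait
    columns; missing cells (empty or ``NA``) yield no record.  A
    :class:`ParseReport` is attached to the returned dataset.

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If a mandatory column (accession, year, or all three traits) is
        absent from the header; the message names the missing column.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    path = Path(path)
    raw = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    for role in ("accession", "year"):
        if cmap[role] not in raw.columns:
            raise ValueError(f"missing mandatory column {cmap[role]!r} ({role})")
    trait_cols = {t: cmap[t] for t in TRAITS if cmap[t] in raw.columns}
    if not trait_cols:
        raise ValueError(f"no trait column found (looked for {[cmap[t] for t in TRAITS]})")

    has_origin = cmap["origin"] in raw.columns
    has_vtype = cmap["value_type"] in raw.columns

    report = ParseReport(rows_read=len(raw))
    rows: list[tuple] = []
    provenance: dict[str, str] = {}
    lo, hi = year_window

    for idx, row in enumerate(raw.itertuples(index=False)):
        rowd = dict(zip(raw.columns, row))
        acc = str(rowd[cmap["accession"]]).strip()
        if not acc or acc in NA_TOKENS:
            report.rejected_rows.append((idx, "missing accession identifier"))
            continue
        year_cell = str(rowd[cmap["year"]]).strip()
        try:
            year = int(float(year_cell))
        except ValueError:
            report.rejected_rows.append((idx, f"non-numeric year {year_cell!r}"))
            continue
        if not (lo <= year <= hi):
            report.rejected_rows.append(
                (idx, f"year {year} outside window [{lo}, {hi}]")
            )
            continue

        origin = UNKNOWN_ORIGIN
        if has_origin:
            cell = str(rowd[cmap["origin"]]).strip()
            origin = cell if cell and not _is_na(cell) else UNKNOWN_ORIGIN
        vtype = "single"
        if has_vtype:
            cell = str(rowd[cmap["value_type"]]).strip().lower()
            if cell in VALUE_TYPES:
                vtype = cell

        cells: list[tuple[str, float]] = []
        bad_row = None
        n_missing = 0
        for trait, col in trait_cols.items():
            cell = str(rowd[col]).strip()
            if _is_na(cell):
                n_missing += 1
                continue
            try:
                value = float(cell)
            except ValueError:
                bad_row = f"non-numeric {trait} cell {cell!r}"
                break
            low, high = TRAIT_RANGES[trait]
            if value <= low or (high is not None and value > high):
                report.rejected_cells.append(
                    (idx, trait, f"value {value} out of range")
                )
                continue
            cells.append((trait, value))
        if bad_row is not None:
            report.rejected_rows.append((idx, bad_row))
            continue
        if n_missing == len(trait_cols):
            report.empty_rows += 1
            continue
        if not cells:
            # all present cells were range-rejected; the row produced nothing
            report.empty_rows += 1
            continue
        report.producing_rows += 1
        provenance.setdefault(acc, origin)
        for trait, value in cells:
            rows.append((acc, year, trait, value, vtype))

    df = pd.DataFrame(rows, columns=_DF_COLUMNS)
    n_before = len(df)
    dup = df.duplicated(subset=["accession_id", "year", "trait"])
    report.duplicate_records = int(dup.sum())
    if report.duplicate_records:
        logger.warning(
            "%s: %d duplicate (accession, year, trait) records dropped",
            path.name,
            report.duplicate_records,
        )
        df = df.loc[~dup]
    report.records_produced = len(df)
    assert report.records_produced == n_before - report.duplicate_records
    return Dataset(df, growth_habit, provenance, parse_report=report, validate=False)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to wide assay-table layout (deterministic order)."""
    path = Path(path)
    wide = (
        dataset.df.pivot_table(
            index=["accession_id", "year", "value_type"],
            columns="trait",
            values="value",
            aggfunc="first",
        )
        .reset_index()
        .rename_axis(None, axis=1)
    )
    for trait in TRAITS:
        if trait not in wide.columns:
            wide[trait] = np.nan
    wide["Origin"] = [dataset.origin_of(a) for a in wide["accession_id"]]
    wide = wide[["accession_id", "year", *TRAITS, "Origin", "value_type"]]
    wide = wide.rename(
        columns={
            "accession_id": DEFAULT_COLUMN_MAP["accession"],
            "year": DEFAULT_COLUMN_MAP["year"],
            "Origin": DEFAULT_COLUMN_MAP["origin"],
            "value_type": DEFAULT_COLUMN_MAP["value_type"],
        }
    )
    wide = wide.sort_values(
        [DEFAULT_COLUMN_MAP["accession"], DEFAULT_COLUMN_MAP["year"]]
    ).reset_index(drop=True)
    _write_tsv(wide, path)


def write_outputs(fit, report, blues: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write the four per-trait curation outputs.

    ``Var.comp.<TRAIT>.txt`` (variance components, model config echoed as
    comment lines), ``Outliers.<TRAIT>.txt`` (flagged records),
    ``Data.corrected.<TRAIT>.txt`` (outlier-corrected records) and
    ``BLUEs.<TRAIT>.txt``.  Rows are ordered accession ascending then
    year ascending; identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trait = report.trait
    if blues is None or len(blues) == 0:
        raise ValueError("empty BLUE table: upstream fit failed, nothing to write")
    paths: dict[str, Path] = {}

    spec = fit.spec
    comments = [
        f"trait={trait}",
        f"genotype_role={spec.genotype_role}",
        f"heteroscedastic={spec.heteroscedastic}",
        f"min_records_per_year={spec.min_records_per_year}",
        f"rel_tol={spec.rel_tol}",
        f"max_iter={spec.max_iter}",
        f"converged={fit.converged}",
    ]
    vc = fit.varcomp
    vc_rows = [("sigma2_year", "", vc.sigma2_year)]
    if vc.sigma2_G is not None:
        vc_rows.append(("sigma2_G", "", vc.sigma2_G))
    for year in sorted(vc.per_year_error):
        vc_rows.append(("sigma2_error", str(year), vc.per_year_error[year]))
    vc_rows.append(("sigma2_error_mean", "", vc.sigma2_e_mean))
    vc_df = pd.DataFrame(vc_rows, columns=["component", "year", "estimate"])
    p = outdir / f"Var.comp.{trait}.txt"
    _write_tsv(vc_df, p, comments)
    paths["varcomp"] = p

    value_lookup = {
        (r.accession_id, r.year): r.value
        for r in _trait_rows(report.source_df, trait)
    }
    out_rows = [
        {
            "accession_id": key[0],
            "year": key[1],
            "value": value_lookup.get((key[0], key[1]), np.nan),
            "z": z,
            "p": pval,
            "p_holm": p_holm,
        }
        for key, z, pval, p_holm in report.flagged
    ]
    out_df = pd.DataFrame(
        out_rows, columns=["accession_id", "year", "value", "z", "p", "p_holm"]
    )
    p = outdir / f"Outliers.{trait}.txt"
    _write_tsv(out_df, p)
    paths["outliers"] = p

    corrected = report.corrected_df.sort_values(["accession_id", "year"]).reset_index(
        drop=True
    )
    p = outdir / f"Data.corrected.{trait}.txt"
    _write_tsv(corrected[["accession_id", "year", "value"]], p)
    paths["corrected"] = p

    blues = blues.sort_values("accession_id").reset_index(drop=True)
    p = outdir / f"BLUEs.{trait}.txt"
    _write_tsv(blues, p)
    paths["blues"] = p
    return paths


def _trait_rows(df: pd.DataFrame, trait: str):
    sub = df[df["trait"] == trait]
    for row in sub.itertuples(index=False):
        yield row
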