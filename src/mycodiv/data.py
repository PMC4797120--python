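"""Data model and I/O for colonization-frequency survey matrices.

A culturable-endophyte survey records, for each fungal species and each
combination of season, sampling site and host tissue, the percentage of
incubated tissue segments from which that species was cultured (the
colonization frequency, CF).  This module holds the in-memory containers
for such surveys -- a species-by-cell CF matrix, per-group isolate-count
vectors -- and converts between percent CF and integer isolate counts
given the segment design of the study.

Canonical storage is long format (``species, season, site, tissue, cf``);
wide files with one ``season.site.tissue`` column per cell are converted
on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "SEASONS",
    "SITES",
    "TISSUES",
    "FACTORS",
    "SpeciesCode",
    "SegmentDesign",
    "AbundanceVector",
    "CFMatrix",
    "read_cf_matrix",
    "write_cf_matrix",
    "cf_to_counts",
    "counts_to_cf",
    "marginalize",
    "presence_absence",
    "present_species",
    "fixture_path",
    "load_season_fixture",
    "load_survey",
]

SEASONS = ("winter", "summer", "rainy")
SITES = (1, 2, 3, 4, 5, 6)
TISSUES = ("leaf", "stem", "petiole")
FACTORS = ("season", "site", "tissue")

#: strings treated as "species not isolated" when reading files
_ABSENT = {"", "-", "--", "–", "—", "nd", "na"}


class CFParseError(ValueError):
    """Malformed survey file (bad header, bad cell key, non-numeric CF)."""


class CFValidationError(ValueError):
    """Structurally valid file whose values violate CF constraints."""


@dataclass(frozen=True)
class SpeciesCode:
    """Identifier for one fungal taxon in a survey.

    ``code`` is the isolate code used as row label in the CF tables;
    the binomial and coarse taxonomic class are optional metadata.
    """

    code: str
    taxon_name: str | None = None
    taxon_class: str | None = None  # ascomycete | basidiomycete | zygomycete | unknown

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("species code must be nonempty")


@dataclass(frozen=True)
class SegmentDesign:
    """Sampling effort behind one (season, site, tissue) cell.

    The survey incubates ``segments_per_replicate`` tissue segments in each
    of ``replicates_per_cell`` replicate samples, so one cell rests on
    ``n_total`` segments.  Defaults (45 x 3 = 135) match the grain of the
    printed CF values, where the smallest nonzero CF is 0.74 = 1/135.
    """

    segments_per_replicate: int = 45
    replicates_per_cell: int = 3

    def __post_init__(self) -> None:
        if self.segments_per_replicate < 1 or self.replicates_per_cell < 1:
            raise ValueError("segment design requires positive counts")

    @property
    def n_total(self) -> int:
        return self.segments_per_replicate * self.replicates_per_cell


@dataclass
class AbundanceVector:
    """Nonnegative integer isolate counts per species for one grouping."""

    counts: dict[str, int]
    label: str = ""

    def __post_init__(self) -> None:
        for sp, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for {sp!r} must be a nonnegative integer, got {c}")
            self.counts[sp] = int(c)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def nonzero(self) -> dict[str, int]:
        return {sp: c for sp, c in self.counts.items() if c > 0}

    def values(self) -> list[int]:
        return list(self.counts.values())


@dataclass
class CFMatrix:
    """Species x (season, site, tissue) percent colonization frequencies.

    ``frame`` is the canonical long table with columns
    ``species, season, site, tissue, cf``; every listed (species, cell)
    pair is explicit, with exact 0 for "not isolated".  Species order is
    preserved from the source file.
    """

    frame: pd.DataFrame
    species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = ["species", "season", "site", "tissue", "cf"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise CFParseError(f"long CF table is missing columns {missing}")
        f = self.frame.loc[:, required].copy()
        f["site"] = f["site"].astype(int)
        f["cf"] = f["cf"].astype(float)
        bad_season = set(f["season"]) - set(SEASONS)
        if bad_season:
            raise CFValidationError(f"unknown season level(s) {sorted(bad_season)}")
        bad_site = set(f["site"]) - set(SITES)
        if bad_site:
            raise CFValidationError(f"site outside 1-6: {sorted(bad_site)}")
        bad_tissue = set(f["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise CFValidationError(f"unknown tissue level(s) {sorted(bad_tissue)}")
        out = f[(f["cf"] < 0) | (f["cf"] > 100)]
        if len(out):
            row = out.iloc[0]
            raise CFValidationError(
                f"CF outside [0, 100] for species {row['species']!r} "
                f"({row['season']}, site {row['site']}, {row['tissue']}): {row['cf']}"
            )
        if not self.species:
            self.species = list(dict.fromkeys(f["species"]))
        self.frame = f

    @property
    def cells(self) -> list[tuple[str, int, str]]:
        """Ordered distinct (season, site, tissue) keys."""
        seen = self.frame[["season", "site", "tissue"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    @property
    def n_species(self) -> int:
        return len(self.species)

    def wide(self) -> pd.DataFrame:
        """Pivot to a species-by-cell table with ``season.site.tissue`` columns."""
        cols = [f"{s}.{i}.{t}" for (s, i, t) in self.cells]
        w = self.frame.assign(
            cell=lambda d: d["season"] + "." + d["site"].astype(str) + "." + d["tissue"]
        ).pivot_table(index="species", columns="cell", values="cf", fill_value=0.0, sort=False)
        w = w.reindex(index=self.species, columns=cols, fill_value=0.0)
        w.columns.name = None
        return w

    def subset_species(self, keep: Iterable[str]) -> "CFMatrix":
        keep = [s for s in self.species if s in set(keep)]
        return CFMatrix(self.frame[self.frame["species"].isin(keep)].copy(), species=keep)


def _parse_cf_value(raw: object, where: str) -> float:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return 0.0
    s = str(raw).strip()
    if s.lower() in _ABSENT:
        return 0.0
    try:
        return float(s)
    except ValueError as exc:
        raise CFParseError(f"non-numeric CF value {s!r} at {where}") from exc


def _parse_wide_column(name: str) -> tuple[str, int, str]:
    parts = name.split(".")
    if len(parts) != 3:
        raise CFParseError(
            f"malformed wide header column {name!r}: expected 'season.site.tissue'"
        )
    season, site_s, tissue = parts
    if season not in SEASONS:
        raise CFParseError(f"malformed wide header column {name!r}: unknown season {season!r}")
    try:
        site = int(site_s)
    except ValueError:
        raise CFParseError(f"malformed wide header column {name!r}: site must be an integer")
    if tissue not in TISSUES:
        raise CFParseError(f"malformed wide header column {name!r}: unknown tissue {tissue!r}")
    return season, site, tissue


def read_cf_matrix(path: str | Path, dialect: str = "wide") -> CFMatrix:
    """Read a CF survey table.

    ``wide`` files have a ``species`` column plus one column per
    (season, site, tissue) cell named ``season.site.tissue``; ``long``
    files have columns ``species, season, site, tissue, cf``.  Dashes and
    blanks denote "not isolated" and become exact 0.
    """
    path = Path(path)
    if dialect not in {"wide", "long"}:
        raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "long":
        required = ["species", "season", "site", "tissue", "cf"]
        missing = [c for c in required if c not in raw.columns]
        if missing:
            raise CFParseError(f"{path.name}: long file missing column(s) {missing}")
        frame = raw.copy()
        frame["cf"] = [
            _parse_cf_value(v, f"row {i + 2}") for i, v in enumerate(raw["cf"])
        ]
        frame["site"] = frame["site"].astype(int)
        return CFMatrix(frame[required])

    if "species" not in raw.columns:
        raise CFParseError(f"{path.name}: wide file must have a 'species' first column")
    cell_cols = [c for c in raw.columns if c != "species"]
    keys = {c: _parse_wide_column(c) for c in cell_cols}
    records = []
    for i, row in raw.iterrows():
        for col in cell_cols:
            season, site, tissue = keys[col]
            cf = _parse_cf_value(row[col], f"row {i + 2}, column {col}")
            records.append((row["species"], season, site, tissue, cf))
    frame = pd.DataFrame(records, columns=["species", "season", "site", "tissue", "cf"])
    return CFMatrix(frame, species=list(dict.fromkeys(raw["species"])))


def write_cf_matrix(cf: CFMatrix, path: str | Path, dialect: str = "long") -> None:
    """Write a CFMatrix in either dialect (UTF-8 CSV, header row)."""
    path = Path(path)
    if dialect == "long":
        cf.frame.to_csv(path, index=False)
    elif dialect == "wide":
        cf.wide().rename_axis("species").reset_index().to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")


def cf_to_counts(cf: CFMatrix, design: SegmentDesign = SegmentDesign()) -> pd.DataFrame:
    """Invert percent CF to integer isolate counts per cell.

    With ``n`` segments behind a cell, CF = count / n * 100, so
    count = round(cf * n / 100).  Entries whose printed CF differs from
    the back-computed count * 100 / n by more than 0.01 percentage points
    are flagged: their CF grain is inconsistent with the stated design
    (printed tables truncate rather than round, so e.g. 1.4 vs 2/135 =
    1.481 flags while 0.74 vs 1/135 = 0.7407 does not).
    """
    n = design.n_total
    frame = cf.frame.copy()
    if (frame["cf"] < 0).any():
        raise CFValidationError("negative CF cannot be converted to counts")
    frame["count"] = (frame["cf"] * n / 100).round().astype(int)
    frame["flagged"] = (frame["cf"] - frame["count"] * 100 / n).abs() > 0.01
    return frame


def counts_to_cf(counts: pd.DataFrame, design: SegmentDesign = SegmentDesign()) -> pd.DataFrame:
    """Back-convert integer counts to percent CF (exact, no truncation)."""
    frame = counts.copy()
    frame["cf"] = frame["count"] * 100 / design.n_total
    return frame


def marginalize(
    data: CFMatrix | pd.DataFrame,
    by: str,
    design: SegmentDesign = SegmentDesign(),
) -> dict[object, AbundanceVector]:
    """Isolate-count vector per level of one factor, summed over the others.

    Accepts either a long count table (from :func:`cf_to_counts` or the
    simulator) or a :class:`CFMatrix`, which is first converted to counts
    under ``design``.  The grand total of isolates is conserved across
    any factor choice.
    """
    if by not in FACTORS:
        raise ValueError(f"unknown factor {by!r}; choose one of {FACTORS}")
    frame = cf_to_counts(data, design) if isinstance(data, CFMatrix) else data
    if "count" not in frame.columns:
        raise ValueError("expected a 'count' value column")
    species_order = list(dict.fromkeys(frame["species"]))
    out: dict[object, AbundanceVector] = {}
    grouped = frame.groupby([by, "species"], sort=False)["count"].sum()
    for level in dict.fromkeys(frame[by]):
        sub = grouped.xs(level, level=0)
        counts = {sp: int(sub.get(sp, 0)) for sp in species_order}
        out[level] = AbundanceVector(counts, label=str(level))
    return out


def presence_absence(cf: CFMatrix, by: str) -> dict[object, set[str]]:
    """Species present (any CF > 0) at each level of one factor."""
    if by not in FACTORS:
        raise ValueError(f"unknown factor {by!r}; choose one of {FACTORS}")
    out: dict[object, set[str]] = {}
    for level, sub in cf.frame.groupby(by, sort=False):
        out[level] = set(sub.loc[sub["cf"] > 0, "species"])
    return out


def present_species(cf: CFMatrix) -> set[str]:
    """Species with any nonzero CF anywhere in the matrix."""
    return set(cf.frame.loc[cf.frame["cf"] > 0, "species"])


# ---------------------------------------------------------------------------
# packaged survey fixtures (one wide CSV per season, as printed)

_SEASON_TABLES = {
    "winter": "table2_winter.csv",
    "summer": "table3_summer.csv",
    "rainy": "table4_rainy.csv",
}


def fixture_path(name: str) -> Path:
    """Absolute path of a packaged reference table (``table2_winter.csv`` ...)."""
    p = resources.files("mycodiv") / "tables" / name
    if not p.is_file():
        raise FileNotFoundError(f"packaged fixture {name!r} not found")
    return Path(str(p))


def load_season_fixture(season: str) -> CFMatrix:
    """CF matrix for one season, as transcribed from the printed survey."""
    if season not in _SEASON_TABLES:
        raise ValueError(f"unknown season {season!r}; choose one of {SEASONS}")
    return read_cf_matrix(fixture_path(_SEASON_TABLES[season]), dialect="wide")


def load_survey() -> CFMatrix:
    """All three seasonal CF matrices stacked into one 24 x 54-cell survey."""
    parts = [load_season_fixture(s) for s in SEASONS]
    frame = pd.concat([p.frame for p in parts], ignore_index=True)
    return CFMatrix(frame, species=parts[0].species)
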