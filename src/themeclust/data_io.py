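"""Data model, CSV readers/writers, country-name canonicalization, and the
packaged cluster-membership reference lists.

The central container is :class:`IndicatorTable`: a countries x indicators
matrix whose columns are partitioned into named themes.  The default theme
layout mirrors the three-theme country typology this package implements:

* ``NAD`` — Nutrition and Diet, 14 dietary-supply indicators;
* ``HAD`` — Health and Disease, 8 disease-burden indicators;
* ``HALE`` — Healthcare and Life Expectancy, 3 access/longevity indicators.

The packaged reference lists (``load_membership_fixture``) transcribe the
published per-theme three-cluster assignments of 168 countries; they are the
ground truth for the set-arithmetic stages (Jaccard matching, Venn
partitioning) and need no external download.
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError, ValidationError

# ---------------------------------------------------------------------------
# Country-name canonicalization
# ---------------------------------------------------------------------------

#: Fixed alias table mapping case-folded, diacritic-stripped variants to the
#: canonical display spelling used by the packaged membership lists.
_ALIASES: dict[str, str] = {
    "czech republic": "Czechia",
    "timor-leste": "East Timor",
    "timor leste": "East Timor",
    "democratic republic of the congo": "Democratic Republic of Congo",
    "dr congo": "Democratic Republic of Congo",
    "congo, dem. rep.": "Democratic Republic of Congo",
    "republic of the congo": "Congo",
    "congo, rep.": "Congo",
    "ivory coast": "Cote d'Ivoire",
    "russian federation": "Russia",
    "viet nam": "Vietnam",
    "lao pdr": "Laos",
    "lao people's democratic republic": "Laos",
    "cabo verde": "Cape Verde",
    "swaziland": "Eswatini",
    "burma": "Myanmar",
    "united states of america": "United States",
    "republic of korea": "South Korea",
    "korea, rep.": "South Korea",
    "syrian arab republic": "Syria",
    "turkiye": "Turkey",
    "macedonia": "North Macedonia",
    "saint vincent & the grenadines": "Saint Vincent and the Grenadines",
    "antigua & barbuda": "Antigua and Barbuda",
    "trinidad & tobago": "Trinidad and Tobago",
    "bosnia & herzegovina": "Bosnia and Herzegovina",
    "sao tome & principe": "Sao Tome and Principe",
}


def _fold(name: str) -> str:
    """Comparison key: diacritic-stripped, case-folded, straight apostrophes."""
    s = unicodedata.normalize("NFKD", name)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.replace("’", "'").replace("‘", "'").replace("ʼ", "'")
    return " ".join(s.split()).casefold()


def canonicalize_country(raw_name: str) -> str:
    """Return the canonical display form of a country name.

    Trims whitespace, normalizes curly apostrophes and diacritics, strips a
    leading article "the ", and resolves a fixed alias table (e.g. "Czech
    Republic" -> "Czechia").  Idempotent: applying it twice gives the same
    result.

    Raises
    ------
    ValidationError
        If ``raw_name`` is empty or whitespace-only.
    """
    if raw_name is None or not str(raw_name).strip():
        raise ValidationError("country name must be a non-empty string")
    s = " ".join(str(raw_name).split())
    s = s.replace("’", "'").replace("‘", "'").replace("ʼ", "'")
    s = unicodedata.normalize("NFKD", s)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    if s.casefold().startswith("the "):
        s = s[4:]
    return _ALIASES.get(_fold(s), s)


# ---------------------------------------------------------------------------
# Theme layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThemeSpec:
    """A named theme and the ordered indicator columns it owns."""

    name: str
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.variables:
            raise ValidationError(f"theme {self.name!r} has an empty variable list")


#: Per-variable severity direction: +1 means larger values indicate higher
#: risk, -1 means larger values indicate lower risk.  Directions for the
#: disease indicators follow the within-cluster profile of the published
#: typology: alcohol- and BMI-related death shares and neoplasm incidence are
#: affluence-associated (highest in the low-risk clusters), so they carry -1.
DEFAULT_DIRECTIONS: dict[str, int] = {
    # NAD: dietary supply — more is lower-risk, except the carbohydrate share,
    # which rises as diet quality falls.
    "animal protein (g/day)": -1,
    "fruit (kg/year)": -1,
    "vegetables (kg/year)": -1,
    "milk excluding butter (kg/year)": -1,
    "total fat (g/day)": -1,
    "vegetal protein (g/day)": -1,
    "total meat protein (g/day)": -1,
    "egg protein (g/day)": -1,
    "meat (kg/year)": -1,
    "total protein (g/day)": -1,
    "animal caloric intake (kcal/person)": -1,
    "vegetal caloric intake (kcal/person)": -1,
    "fat caloric intake (kcal/person)": -1,
    "carbohydrate share in daily caloric intake (%)": 1,
    # HAD: disease burden.
    "BMI-related deaths share": -1,
    "Alcohol-related deaths": -1,
    "Protein Energy Malnutrition Deaths rate": 1,
    "Anemia prevalence in pregnant women": 1,
    "Neoplasm cases per 100 people": -1,
    "Hypertension prevalence aged 30-79": 1,
    "CVD cancer diabetes CRD mortality age 30-70": 1,
    "DALYs All causes rate": 1,
    # HALE: access and longevity — more is lower-risk.
    "UHC Service Coverage Index": -1,
    "Life expectancy at birth": -1,
    "Health expenditure per capita PPP": -1,
}

DEFAULT_THEMES: tuple[ThemeSpec, ...] = (
    ThemeSpec(
        "NAD",
        (
            "animal protein (g/day)",
            "fruit (kg/year)",
            "vegetables (kg/year)",
            "milk excluding butter (kg/year)",
            "total fat (g/day)",
            "vegetal protein (g/day)",
            "total meat protein (g/day)",
            "egg protein (g/day)",
            "meat (kg/year)",
            "total protein (g/day)",
            "animal caloric intake (kcal/person)",
            "vegetal caloric intake (kcal/person)",
            "fat caloric intake (kcal/person)",
            "carbohydrate share in daily caloric intake (%)",
        ),
    ),
    ThemeSpec(
        "HAD",
        (
            "BMI-related deaths share",
            "Alcohol-related deaths",
            "Protein Energy Malnutrition Deaths rate",
            "Anemia prevalence in pregnant women",
            "Neoplasm cases per 100 people",
            "Hypertension prevalence aged 30-79",
            "CVD cancer diabetes CRD mortality age 30-70",
            "DALYs All causes rate",
        ),
    ),
    ThemeSpec(
        "HALE",
        (
            "UHC Service Coverage Index",
            "Life expectancy at birth",
            "Health expenditure per capita PPP",
        ),
    ),
)


# ---------------------------------------------------------------------------
# IndicatorTable
# ---------------------------------------------------------------------------


@dataclass
class IndicatorTable:
    """Countries x indicators matrix with a theme partition of the columns.

    ``values`` is a pandas DataFrame indexed by canonical country name; cells
    may be NaN (missing).  Every column belongs to exactly one theme.
    """

    values: pd.DataFrame
    themes: tuple[ThemeSpec, ...]

    def __post_init__(self) -> None:
        cols: list[str] = []
        for t in self.themes:
            cols.extend(t.variables)
        if len(set(cols)) != len(cols):
            raise ValidationError("theme variable lists overlap")
        missing = [c for c in cols if c not in self.values.columns]
        if missing:
            raise SchemaError(f"table is missing declared columns: {missing}")
        extra = [c for c in self.values.columns if c not in cols]
        if extra:
            raise ValidationError(f"columns not covered by any theme: {extra}")
        if self.values.index.has_duplicates:
            dupes = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValidationError(f"duplicate countries after canonicalization: {dupes}")

    @property
    def countries(self) -> list[str]:
        return list(self.values.index)

    def theme(self, name: str) -> ThemeSpec:
        for t in self.themes:
            if t.name == name:
                return t
        raise ValidationError(f"unknown theme {name!r}")

    def theme_matrix(self, name: str) -> pd.DataFrame:
        """The sub-table holding one theme's columns, in declared order."""
        return self.values.loc[:, list(self.theme(name).variables)]


def read_indicator_table(path: str | Path, themes: Sequence[ThemeSpec]) -> IndicatorTable:
    """Read a countries x indicators CSV into a validated :class:`IndicatorTable`.

    The file must be UTF-8 with a header row whose first column is
    ``country``; remaining columns are indicator names.  Blank and
    non-numeric cells parse as missing.  Duplicate countries (after
    canonicalization) are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "country":
        raise SchemaError(f"first column must be 'country', found {df.columns[0]!r}")
    declared: list[str] = [v for t in themes for v in t.variables]
    absent = [c for c in declared if c not in df.columns]
    if absent:
        raise SchemaError(f"input CSV is missing declared columns: {absent}")
    countries = [canonicalize_country(c) for c in df["country"]]
    values = df.loc[:, declared].apply(pd.to_numeric, errors="coerce")
    values.index = pd.Index(countries, name="country")
    return IndicatorTable(values=values, themes=tuple(themes))


# ---------------------------------------------------------------------------
# Packaged membership fixture
# ---------------------------------------------------------------------------

#: Published per-theme cluster sizes, used as a transcription checksum.
_EXPECTED_SIZES: dict[str, tuple[int, int, int]] = {
    "NAD": (61, 42, 65),
    "HAD": (45, 69, 54),
    "HALE": (27, 88, 53),
}


@dataclass(frozen=True)
class MembershipFixture:
    """Per-theme mapping country -> cluster label in {1, 2, 3} over a shared
    168-country universe, transcribed from the published typology."""

    assignments: Mapping[str, Mapping[str, int]]

    def cluster(self, theme: str, label: int) -> frozenset[str]:
        """The membership set of one cluster within one theme."""
        return frozenset(c for c, k in self.assignments[theme].items() if k == label)

    def sizes(self, theme: str) -> tuple[int, ...]:
        labels = sorted(set(self.assignments[theme].values()))
        return tuple(len(self.cluster(theme, k)) for k in labels)

    @property
    def universe(self) -> frozenset[str]:
        first = next(iter(self.assignments.values()))
        return frozenset(first)


def load_membership_fixture() -> MembershipFixture:
    """Load the packaged per-theme cluster membership lists.

    Validates the transcription against the published cluster sizes and the
    shared-universe invariant; a mismatch raises :class:`IntegrityError`.
    """
    assignments: dict[str, dict[str, int]] = {}
    for theme in ("NAD", "HAD", "HALE"):
        fname = f"memberships_{theme.lower()}.csv"
        with resources.files("themeclust.data").joinpath(fname).open("r", encoding="utf-8") as fh:
            df = pd.read_csv(fh)
        mapping = {canonicalize_country(r.country): int(r.cluster) for r in df.itertuples()}
        if len(mapping) != len(df):
            raise IntegrityError(f"{theme}: duplicate countries in fixture")
        sizes = tuple(sum(1 for v in mapping.values() if v == k) for k in (1, 2, 3))
        if sizes != _EXPECTED_SIZES[theme]:
            raise IntegrityError(
                f"{theme}: cluster sizes {sizes} != expected {_EXPECTED_SIZES[theme]}"
            )
        assignments[theme] = mapping
    universes = {t: frozenset(a) for t, a in assignments.items()}
    if not (universes["NAD"] == universes["HAD"] == universes["HALE"]):
        raise IntegrityError("fixture themes do not cover the same country universe")
    if len(universes["NAD"]) != 168:
        raise IntegrityError(f"fixture universe has {len(universes['NAD'])} countries, expected 168")
    return MembershipFixture(assignments=assignments)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_assignments(models: Mapping[str, Mapping[str, int]], path: str | Path,
                      risk_rank: Mapping[str, Mapping[int, int]] | None = None) -> None:
    """Write per-theme cluster assignments to CSV.

    Columns: country, theme, cluster, risk_rank.  Countries are sorted
    canonically and themes alphabetically for a deterministic byte stream.
    ``risk_rank`` maps theme -> cluster label -> rank (1 = lowest risk); when
    omitted the cluster label doubles as the rank (labels already
    risk-ordered).
    """
    rows = []
    for theme in sorted(models):
        for country in sorted(models[theme]):
            k = models[theme][country]
            rank = risk_rank[theme][k] if risk_rank is not None else k
            rows.append((country, theme, k, rank))
    out = pd.DataFrame(rows, columns=["country", "theme", "cluster", "risk_rank"])
    out.to_csv(path, index=False)


def read_assignments(path: str | Path) -> dict[str, dict[str, int]]:
    df = pd.read_csv(path)
    result: dict[str, dict[str, int]] = {}
    for r in df.itertuples():
        result.setdefault(r.theme, {})[r.country] = int(r.cluster)
    return result


def write_similarity(matrices: Iterable, path: str | Path) -> None:
    """Write pairwise cluster Jaccard matrices as a long-format CSV."""
    rows = []
    for m in matrices:
        a, b = m.theme_pair
        for i in range(m.values.shape[0]):
            for j in range(m.values.shape[1]):
                rows.append((a, i + 1, b, j + 1, float(m.values[i, j])))
    out = pd.DataFrame(rows, columns=["themeA", "clusterA", "themeB", "clusterB", "jaccard"])
    out.to_csv(path, index=False, float_format="%.6f")


def write_regions(partition, path: str | Path) -> None:
    """Write the 7-region Venn decomposition as JSON.

    Every region key appears even when its country list is empty, so the
    schema is stable across inputs.
    """
    payload = {
        "set_names": list(partition.set_names),
        "union_size": partition.union_size,
        "regions": {k: sorted(v) for k, v in partition.regions.items()},
        "percentages": partition.percentages(),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")


def write_contributions(rows: Iterable, path: str | Path) -> None:
    """Write the per-variable contribution table (robust R^2, Kruskal-Wallis
    H, p, normality flag) as CSV."""
    df = pd.DataFrame([r.__dict__ for r in rows])
    df.to_csv(path, index=False, float_format="%.6g")
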