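"""Assemble "all names" and "basionyms" analysis datasets from a raw name table.

The raw table holds one row per published name (accepted species, synonyms,
infraspecifics) with its publication year, an APG-IV-remappable family, a set
of phytogeographic domains, and up to three per-source basionym-year
assignments.  Genus/section-rank and non-native rows are dropped on load;
years resolve primary-field-first with a fallback field; discordant basionym
votes are settled by majority rule, falling back to the earliest voted year
(flagged ``conflict``) when all three sources disagree — the basionym is by
definition the earliest name.

Two datasets come out: *basionyms* (one earliest year per accepted species —
tracks genuine additions to the inventory) and *all names* (every name's
year — tracks total nomenclatural activity).  A species recorded in k domains
contributes to all k domain strata, so domain strata overlap by design.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FAMILY_REMAP",
    "SchemaError",
    "UnresolvedBasionymError",
    "NameDatasets",
    "load_names",
    "remap_family",
    "resolve_basionym_year",
    "build_datasets",
]

# APG IV high-level family remapping (legacy name -> accepted family)
FAMILY_REMAP = {
    "Alliaceae": "Amaryllidaceae",
    "Asclepiadaceae": "Apocynaceae",
    "Avicenniaceae": "Acanthaceae",
    "Caesalpiniaceae": "Fabaceae",
    "Leguminosae": "Fabaceae",
    "Mimosaceae": "Fabaceae",
    "Buddlejaceae": "Scrophulariaceae",
    "Callitrichaceae": "Plantaginaceae",
    "Myrsinaceae": "Primulaceae",
    "Sterculiaceae": "Malvaceae",
}

MANDATORY_COLUMNS = (
    "name_id",
    "scientific_name",
    "rank",
    "status",
    "accepted_id",
    "family",
    "year_primary",
)

VOTE_COLUMNS = ("basionym_year_flora", "basionym_year_tropicos", "basionym_year_wcvp")

EXCLUDED_RANKS = frozenset({"genus", "section"})


class SchemaError(ValueError):
    """A mandatory input column is missing."""


class UnresolvedBasionymError(ValueError):
    """All per-source basionym votes for a species are missing."""


def remap_family(family_raw: str) -> str:
    """Map a legacy family name onto its APG IV family (unknowns pass through)."""
    if not isinstance(family_raw, str):
        return family_raw
    return FAMILY_REMAP.get(family_raw.strip(), family_raw.strip())


def resolve_basionym_year(votes) -> tuple[int, str]:
    """Settle up-to-three per-source basionym-year votes.

    Returns ``(year, flag)`` with flag one of ``unanimous`` (all present
    votes equal), ``majority`` (two of three agree), ``conflict`` (all
    disagree; the earliest year wins, since a basionym is the earliest name).
    """
    present = [int(v) for v in votes if v is not None and not pd.isna(v)]
    if not present:
        raise UnresolvedBasionymError("all basionym votes are missing")
    counts = Counter(present)
    year, top = counts.most_common(1)[0]
    if top == len(present):
        return year, "unanimous"
    if top >= 2:
        return year, "majority"
    return min(present), "conflict"


def _coerce_year(value):
    try:
        if pd.isna(value) or value == "":
            return np.nan
        return float(int(float(value)))
    except (TypeError, ValueError):
        return None  # sentinel: unparseable


def load_names(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load a delimited name table and apply the cleaning protocol.

    Comma- vs tab-separation is auto-detected from the extension (.tsv/.tab
    -> tab).  Cleaning: genus/section-rank rows and non-native rows are
    excluded; the family is remapped to APG IV; the year resolves from the
    primary field, else the fallback field, else the row is flagged
    ``year_missing``.  Unparseable years raise a row-level warning and flag
    the record.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, encoding="utf-8")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if "year_fallback" not in df.columns:
        df["year_fallback"] = np.nan
    if "native" in df.columns:
        native = df["native"].astype(str).str.lower().isin({"true", "1", "yes", "t"})
        df = df[native]
    df = df[~df["rank"].str.lower().isin(EXCLUDED_RANKS)].copy()

    df["family"] = df["family"].map(remap_family)

    primary = df["year_primary"].map(_coerce_year)
    fallback = df["year_fallback"].map(_coerce_year)
    bad = [i for i, (p, f) in enumerate(zip(primary, fallback)) if p is None or f is None]
    if bad:
        warnings.warn(f"{len(bad)} row(s) with unparseable year flagged", stacklevel=2)
    primary = primary.map(lambda v: np.nan if v is None else v)
    fallback = fallback.map(lambda v: np.nan if v is None else v)
    df["resolved_year"] = primary.fillna(fallback)
    df["year_missing"] = df["resolved_year"].isna()
    df = df.reset_index(drop=True)
    return df


def _split_domains(value) -> list[str]:
    if not isinstance(value, str) or not value.strip():
        return []
    return [d.strip() for d in value.split("|") if d.strip()]


@dataclass
class NameDatasets:
    """The two analysis datasets plus the per-species entry table.

    ``species`` has one row per accepted species (basionym year, family,
    domains, habit); ``names`` has one row per name, joined to the strata of
    its accepted species.
    """

    species: pd.DataFrame
    names: pd.DataFrame
    conflicts: pd.DataFrame

    def _strata_of(self, df: pd.DataFrame, by: str | None) -> pd.DataFrame:
        if by is None:
            out = df.copy()
            out["stratum"] = "all"
            return out
        if by == "domain":
            out = df.copy()
            out["stratum"] = out["domains"].map(_split_domains)
            out = out.explode("stratum").dropna(subset=["stratum"])
            return out
        if by in {"family", "habit"}:
            out = df.copy()
            out["stratum"] = out[by]
            return out.dropna(subset=["stratum"])
        raise ValueError(f"unknown stratification {by!r}")

    def basionym_years(self, by: str | None = None) -> dict[str, np.ndarray]:
        """Stratum -> basionym years (one per accepted species)."""
        df = self._strata_of(self.species, by)
        return {
            k: g["basionym_year"].to_numpy(dtype=int)
            for k, g in df.groupby("stratum", sort=True)
        }

    def all_name_years(self, by: str | None = None) -> dict[str, np.ndarray]:
        """Stratum -> publication years of every name (accepted + synonyms +
        infraspecifics), attributed to the strata of the accepted species."""
        df = self._strata_of(self.names.dropna(subset=["resolved_year"]), by)
        return {
            k: g["resolved_year"].to_numpy(dtype=int)
            for k, g in df.groupby("stratum", sort=True)
        }


def build_datasets(records: pd.DataFrame) -> NameDatasets:
    """Build the basionyms and all-names datasets from loaded records.

    Species entries are defined by species-rank accepted rows; the basionym
    year comes from the majority rule over per-source votes when any vote is
    present, else from the row's resolved year.  Synonym and infraspecific
    rows inherit the domains/family/habit of their accepted species for
    stratification.
    """
    df = records.copy()
    acc = df[(df["status"].str.lower() == "accepted") & (df["rank"].str.lower() == "species")]
    entries = []
    conflict_rows = []
    for _, row in acc.iterrows():
        votes = [row.get(c) for c in VOTE_COLUMNS if c in row.index]
        votes = [v for v in votes if v is not None and not pd.isna(v)]
        if votes:
            year, flag = resolve_basionym_year(votes)
        elif not pd.isna(row["resolved_year"]):
            year, flag = int(row["resolved_year"]), "resolved"
        else:
            continue  # no year information at all; excluded from curves
        entries.append(
            {
                "accepted_id": row["accepted_id"],
                "family": row["family"],
                "basionym_year": year,
                "basionym_flag": flag,
                "domains": row.get("domains", ""),
                "habit": row.get("habit", ""),
            }
        )
        if flag == "conflict":
            conflict_rows.append({"accepted_id": row["accepted_id"], "votes": votes})
    species = pd.DataFrame(
        entries,
        columns=["accepted_id", "family", "basionym_year", "basionym_flag", "domains", "habit"],
    ).drop_duplicates(subset="accepted_id").reset_index(drop=True)

    lookup = species.set_index("accepted_id")
    names = df.copy()
    names["family"] = names["accepted_id"].map(lookup["family"]).fillna(names["family"])
    for col in ("domains", "habit"):
        if col in names.columns:
            names[col] = names["accepted_id"].map(lookup[col]).fillna(names[col])
        else:
            names[col] = names["accepted_id"].map(lookup[col])
    conflicts = pd.DataFrame(conflict_rows, columns=["accepted_id", "votes"])
    return NameDatasets(species=species, names=names, conflicts=conflicts)
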