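"""Name-table loading, family remapping, basionym majority rule and dataset assembly."""

import io

import numpy as np
import pandas as pd
import pytest

from floragap.nomenclature import (
    SchemaError,
    UnresolvedBasionymError,
    build_datasets,
    load_names,
    remap_family,
    resolve_basionym_year,
)
from floragap.synthetic_data import SyntheticConfig, generate_name_table

HEADER = (
    "name_id,scientific_name,authorship,rank,status,accepted_id,family,"
    "year_primary,year_fallback,basionym_year_flora,basionym_year_tropicos,"
    "basionym_year_wcvp,domains,habit,native"
)


def _write(tmp_path, *rows):
    path = tmp_path / "names.csv"
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


def test_genus_and_section_rows_excluded(tmp_path):
    path = _write(
        tmp_path,
        "g1,Genus,L.,genus,accepted,g1,Fabaceae,1800,,,,,Amazonia,tree,True",
        "x1,Genus sect. Two,L.,section,accepted,x1,Fabaceae,1810,,,,,Amazonia,tree,True",
        "s1,Genus alpha,L.,species,accepted,s1,Fabaceae,1820,,,,,Amazonia,tree,True",
    )
    df = load_names(path)
    assert list(df["name_id"]) == ["s1"]


def test_nonnative_rows_excluded(tmp_path):
    path = _write(
        tmp_path,
        "s1,Genus alpha,L.,species,accepted,s1,Fabaceae,1820,,,,,Amazonia,tree,True",
        "s2,Genus beta,L.,species,accepted,s2,Fabaceae,1830,,,,,Amazonia,tree,False",
    )
    assert list(load_names(path)["name_id"]) == ["s1"]


def test_fallback_year_used_when_primary_missing(tmp_path):
    path = _write(
        tmp_path,
        "s1,Genus alpha,L.,species,accepted,s1,Fabaceae,,1855,,,,Amazonia,tree,True",
    )
    df = load_names(path)
    assert df.loc[0, "resolved_year"] == 1855
    assert not df.loc[0, "year_missing"]


def test_empty_file_with_header_is_empty_frame(tmp_path):
    path = _write(tmp_path)
    df = load_names(path)
    assert len(df) == 0


def test_missing_mandatory_column_names_the_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("name_id,rank\nx,species\n")
    with pytest.raises(SchemaError, match="status"):
        load_names(path)


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Caesalpiniaceae", "Fabaceae"),
        ("Leguminosae", "Fabaceae"),
        ("Mimosaceae", "Fabaceae"),
        ("Myrsinaceae", "Primulaceae"),
        ("Sterculiaceae", "Malvaceae"),
        ("Alliaceae", "Amaryllidaceae"),
        ("Bromeliaceae", "Bromeliaceae"),
    ],
)
def test_family_remap(raw, expected):
    assert remap_family(raw) == expected


@pytest.mark.parametrize(
    "votes,year,flag",
    [
        ((1820, 1820, 1835), 1820, "majority"),
        ((1820, 1820, 1820), 1820, "unanimous"),
        ((1800, 1810, 1820), 1800, "conflict"),  # earliest-year fallback = min()
        ((1900, np.nan, 1900), 1900, "unanimous"),
        ((1900,), 1900, "unanimous"),
    ],
)
def test_resolve_basionym_year(votes, year, flag):
    assert resolve_basionym_year(votes) == (year, flag)


def test_all_votes_missing_raises():
    with pytest.raises(UnresolvedBasionymError):
        resolve_basionym_year((np.nan, None, np.nan))


def test_species_with_synonyms_counts(tmp_path):
    path = _write(
        tmp_path,
        "s1,Genus alpha,L.,species,accepted,s1,Fabaceae,1820,,1820,1820,1820,Amazonia,tree,True",
        "s1b,Genus beta,Mart.,species,synonym,s1,Fabaceae,1850,,,,,Amazonia,tree,True",
        "s1c,Genus gamma,Zucc.,species,synonym,s1,Fabaceae,1870,,,,,Amazonia,tree,True",
    )
    ds = build_datasets(load_names(path))
    assert len(ds.all_name_years()["all"]) == 3
    assert len(ds.basionym_years()["all"]) == 1


def test_multidomain_species_counts_in_every_domain(tmp_path):
    path = _write(
        tmp_path,
        "s1,Genus alpha,L.,species,accepted,s1,Fabaceae,1820,,,,,Amazonia|Cerrado,tree,True",
    )
    ds = build_datasets(load_names(path))
    by_domain = ds.basionym_years("domain")
    assert set(by_domain) == {"Amazonia", "Cerrado"}
    assert all(len(v) == 1 for v in by_domain.values())


def test_synthetic_without_synonyms_all_names_equals_basionyms():
    cfg = SyntheticConfig(seed=17, n_strata=1, true_asymptote=120,
                          synonym_rate=0.0, discordance_rate=0.0,
                          infraspecific_rate=0.0)
    table = generate_name_table(cfg)
    ds = build_datasets(_roundtrip(table.table))
    assert sorted(ds.all_name_years()["all"]) == sorted(ds.basionym_years()["all"])


def test_basionym_total_equals_distinct_accepted(name_table, tmp_path):
    df = _roundtrip(name_table.table)
    ds = build_datasets(df)
    n_accepted = df[
        (df["status"] == "accepted") & (df["rank"] == "species")
    ]["accepted_id"].nunique()
    assert len(ds.species) == n_accepted
    assert sum(len(v) for v in ds.basionym_years("domain").values()) == n_accepted


def test_stratum_and_partition_invariants(name_table):
    ds = build_datasets(_roundtrip(name_table.table))
    all_names = ds.all_name_years("domain")
    basio = ds.basionym_years("domain")
    for stratum in basio:
        assert len(basio[stratum]) <= len(all_names[stratum])
    # families partition species: family-stratum counts sum to the total
    by_family = ds.basionym_years("family")
    assert sum(len(v) for v in by_family.values()) == len(ds.species)


def test_build_datasets_order_independent(name_table):
    df = _roundtrip(name_table.table)
    shuffled = df.sample(frac=1.0, random_state=4).reset_index(drop=True)
    a = build_datasets(df).basionym_years("domain")
    b = build_datasets(shuffled).basionym_years("domain")
    assert {k: sorted(v) for k, v in a.items()} == {k: sorted(v) for k, v in b.items()}


def _roundtrip(table: pd.DataFrame) -> pd.DataFrame:
    """Pass the in-memory table through the CSV loader (the public entry)."""
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "names.csv"
        table.to_csv(path, index=False)
        return load_names(path)
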