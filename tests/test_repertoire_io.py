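import numpy as np
import pandas as pd
import pytest
from helpers import make_repertoire

from tcrscreen import (
    ClonotypeRecord,
    CohortManifest,
    FeatureMatrix,
    ManifestEntry,
    Repertoire,
    clonotype_key,
    read_clonotype_table,
    read_matrix,
    write_matrix,
)
from tcrscreen.repertoire_io import ConfigurationError, RepertoireError


@pytest.mark.parametrize(
    "cdr3,v,j,resolution,expected",
    [
        ("CASSLGGNTEAFF", "TRBV12-3*01", "TRBJ1-1*01", "family", "CASSLGGNTEAFF_TRBV12_TRBJ1-1"),
        ("CASSYSDTGELFF", "TRBV6", "TRBJ2-2", "family", "CASSYSDTGELFF_TRBV6_TRBJ2-2"),
        ("CASSF", "TRBV12-3", "TRBJ1-3", "gene", "CASSF_TRBV12-3_TRBJ1-3"),
        ("CASSF", "TRBV12-3*02", "TRBJ1-3*01", "gene", "CASSF_TRBV12-3_TRBJ1-3"),
    ],
)
def test_clonotype_key_canonicalization(cdr3, v, j, resolution, expected):
    rec = ClonotypeRecord(cdr3, v, j, 1)
    assert clonotype_key(rec, resolution) == expected


def test_clonotype_key_idempotent_on_canonical_triples():
    rec = ClonotypeRecord("CASSLGGNTEAFF", "TRBV12", "TRBJ1-1", 3)
    key = clonotype_key(rec)
    cdr3, v, j = key.split("_")
    assert clonotype_key(ClonotypeRecord(cdr3, v, j, 3)) == key


def test_unparseable_gene_label_used_verbatim():
    rec = ClonotypeRecord("CASSF", "unresolved", "TRBJ1-1", 1)
    assert clonotype_key(rec) == "CASSF_unresolved_TRBJ1-1"


def test_duplicate_keys_aggregate_by_summing_counts():
    # same family-level identity through different alleles
    records = [
        ClonotypeRecord("CASSF", "TRBV12-3*01", "TRBJ1-1*01", 5),
        ClonotypeRecord("CASSF", "TRBV12-4", "TRBJ1-1", 7),
        ClonotypeRecord("CAWF", "TRBV6", "TRBJ2-2", 1),
    ]
    rep = Repertoire.from_records("s1", "case", records)
    assert rep.richness == 2
    assert rep.records["CASSF_TRBV12_TRBJ1-1"].count == 12
    assert rep.total_count == 13  # aggregation conserves total count


def _write_airr(path, rows):
    pd.DataFrame(
        rows, columns=["junction_aa", "v_call", "j_call", "duplicate_count", "productive"]
    ).to_csv(path, sep="\t", index=False)


def _write_immunoseq(path, rows):
    pd.DataFrame(rows, columns=["aminoAcid", "vGeneName", "jGeneName", "count"]).to_csv(
        path, sep="\t", index=False
    )


def test_dialect_equivalence(tmp_path):
    base = [
        ("CASSLGGNTEAFF", "TRBV12-3*01", "TRBJ1-1*01", 4),
        ("CASSYSDTGELFF", "TRBV6-1", "TRBJ2-2*01", 2),
        ("CASSLGGNTEAFF", "TRBV12-4", "TRBJ1-1", 3),  # merges with the first
    ]
    _write_airr(tmp_path / "a.tsv", [(c, v, j, n, "T") for c, v, j, n in base])
    _write_immunoseq(tmp_path / "i.tsv", base)
    rep_a = read_clonotype_table(tmp_path / "a.tsv", dialect="airr", sample_id="s")
    rep_i = read_clonotype_table(tmp_path / "i.tsv", dialect="immunoseq", sample_id="s")
    assert rep_a.records == rep_i.records
    assert rep_a.richness == 2
    assert rep_a.records["CASSLGGNTEAFF_TRBV12_TRBJ1-1"].count == 7


def test_productive_filter_drops_stop_codons_and_reports(tmp_path):
    rows = [
        ("CASSF", "TRBV1", "TRBJ1-1", 2, "T"),
        ("CAS*F", "TRBV1", "TRBJ1-1", 5, "T"),  # stop codon in junction
        ("CAWGF", "TRBV2", "TRBJ1-2", 1, "F"),  # flagged non-productive
    ]
    _write_airr(tmp_path / "a.tsv", rows)
    rep = read_clonotype_table(tmp_path / "a.tsv", dialect="airr")
    assert rep.richness == 1
    assert rep.load_report["dropped_nonproductive"] == 2
    assert rep.load_report["rows_kept"] == 1
    # the filter can be disabled; the stop-codon row still fails CDR3 validation
    rep2 = read_clonotype_table(tmp_path / "a.tsv", dialect="airr", productive_only=False)
    assert rep2.richness == 2
    assert rep2.load_report["dropped_invalid_cdr3"] == 1


def test_missing_column_names_the_column(tmp_path):
    pd.DataFrame({"junction_aa": ["CASSF"], "v_call": ["TRBV1"]}).to_csv(
        tmp_path / "bad.tsv", sep="\t", index=False
    )
    with pytest.raises(ConfigurationError, match="j_call"):
        read_clonotype_table(tmp_path / "bad.tsv", dialect="airr")


def test_empty_after_filtering_raises(tmp_path):
    _write_airr(tmp_path / "a.tsv", [("CAS*F", "TRBV1", "TRBJ1-1", 1, "T")])
    with pytest.raises(RepertoireError):
        read_clonotype_table(tmp_path / "a.tsv", dialect="airr")


@pytest.mark.parametrize(
    "values,names",
    [
        (np.array([[1.5, 2.0, -0.25], [0.0, 3.125, 4.5]]), ["f1", "f2", "f3"]),
        (np.array([[0.0, 1.0], [1.0, 0.0]]), ["k1", "k2"]),
        (np.empty((2, 0)), []),
    ],
)
def test_matrix_round_trip(tmp_path, values, names):
    m = FeatureMatrix(["s1", "s2"], names, values, labels=["case", "control"])
    write_matrix(m, tmp_path / "m.tsv")
    assert read_matrix(tmp_path / "m.tsv") == m


def test_binary_matrix_writes_only_binary_tokens(tmp_path):
    m = FeatureMatrix(["s1", "s2"], ["k1", "k2"], np.array([[0.0, 1.0], [1.0, 1.0]]))
    write_matrix(m, tmp_path / "m.tsv")
    lines = (tmp_path / "m.tsv").read_text().splitlines()
    cells = [tok for line in lines[1:] for tok in line.split("\t")[1:]]
    assert set(cells) <= {"0", "1"}


def test_manifest_requires_unique_ids_and_both_train_phenotypes():
    e = lambda i, ph, sp: ManifestEntry(i, f"{i}.tsv", ph, sp)
    CohortManifest([e("a", "case", "train"), e("b", "control", "train")])
    with pytest.raises(ConfigurationError):
        CohortManifest([e("a", "case", "train"), e("a", "control", "train")])
    with pytest.raises(ConfigurationError):
        CohortManifest([e("a", "case", "train"), e("b", "case", "train")])


def test_aggregation_conserves_total_count(rng):
    counts = rng.integers(1, 50, size=30)
    rep = make_repertoire(counts)
    assert rep.total_count == counts.sum()
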