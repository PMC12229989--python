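import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hypermhc import seq_io
from hypermhc.errors import (
    InvalidAffinity,
    InvalidScore,
    InvalidSequence,
    MissingFolds,
    UnknownAllele,
)
from hypermhc.seq_io import (
    BindingRecord,
    Dataset,
    MHCAllele,
    filter_lomo_alleles,
    inverse_log50k,
    label_from_affinity,
    log50k_transform,
    read_allele_table,
    read_binding_table,
    split_folds,
    split_lomo,
    write_allele_table,
    write_binding_table,
)


class TestLog50kTransform:
    @pytest.mark.parametrize(
        "nM, expected",
        [(1.0, 1.0), (50000.0, 0.0), (1e6, 0.0), (0.5, 1.0)],
    )
    def test_anchor_points_and_clamping(self, nM, expected):
        assert log50k_transform(nM) == pytest.approx(expected)

    def test_500nM_maps_to_binder_threshold(self):
        # the conventional binder cutoff is the image of 500 nM
        assert round(log50k_transform(500.0), 3) == 0.426

    @pytest.mark.parametrize("bad", [0.0, -5.0, float("nan"), float("inf")])
    def test_rejects_nonpositive_or_nonfinite(self, bad):
        with pytest.raises(InvalidAffinity):
            log50k_transform(bad)

    @given(st.floats(min_value=1.001, max_value=49999.0), st.floats(min_value=1.001, max_value=49999.0))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_inside_range(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert log50k_transform(lo) > log50k_transform(hi)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(derandomize=True, max_examples=50)
    def test_inverse_round_trip(self, score):
        assert log50k_transform(inverse_log50k(score)) == pytest.approx(score, abs=1e-12)

    def test_inverse_endpoints(self):
        assert inverse_log50k(1.0) == pytest.approx(1.0)
        assert inverse_log50k(0.0) == pytest.approx(50000.0)
        with pytest.raises(InvalidScore):
            inverse_log50k(1.5)


class TestBinderLabel:
    @pytest.mark.parametrize("score, label", [(0.5, 1), (0.426, 0), (0.0, 0), (1.0, 1)])
    def test_strict_threshold(self, score, label):
        assert label_from_affinity(score) == label

    def test_label_flips_once_near_500nM(self):
        # scan a 1-nM grid: a single binder->nonbinder flip at the
        # affinity whose image crosses the (rounded) 0.426 cutoff
        labels = [
            label_from_affinity(log50k_transform(float(nM))) for nM in range(490, 511)
        ]
        assert labels[0] == 1 and labels[-1] == 0
        flips = [i for i in range(1, len(labels)) if labels[i] != labels[i - 1]]
        assert len(flips) == 1
        flip_nM = 490 + flips[0]
        assert flip_nM == math.floor(inverse_log50k(0.426)) + 1

    def test_out_of_range_score(self):
        with pytest.raises(InvalidScore):
            label_from_affinity(1.2)


class TestRecordsAndSequences:
    def test_noncanonical_residue_rejected(self):
        with pytest.raises(InvalidSequence):
            BindingRecord("A", "ACDB", affinity_norm=0.5)

    def test_record_needs_some_target(self):
        with pytest.raises(InvalidAffinity):
            BindingRecord("A", "ACDEFGHIK")

    def test_dataset_resolves_alleles(self, allele):
        rec = BindingRecord(allele.name, "ACDEFGHIK", affinity_norm=0.5)
        ds = Dataset(alleles={allele.name: allele}, records=[rec])
        assert ds.allele_of(rec) is allele
        with pytest.raises(UnknownAllele):
            Dataset(alleles={}, records=[rec])


class TestTables:
    def test_binding_table_round_trip(self, small_dataset, tmp_path):
        path = tmp_path / "table.tsv"
        write_binding_table(small_dataset, path)
        back = read_binding_table(path, small_dataset.alleles, dialect="generic_tsv")
        assert len(back) == len(small_dataset)
        for a, b in zip(small_dataset.records, back.records):
            assert (a.peptide, a.allele_name, a.label, a.fold) == (
                b.peptide,
                b.allele_name,
                b.label,
                b.fold,
            )
            assert a.affinity_norm == pytest.approx(b.affinity_norm, abs=1e-6)

    def test_bd2016_dialect_transforms_nM(self, allele, tmp_path):
        path = tmp_path / "bd.txt"
        path.write_text(
            f"ACDEFGHIK 500 {allele.name} 0\n"
            f"ACDEFGHIKL 1 {allele.name} 1\n"
            f"ACDEFGHIKLM 50000 {allele.name} 2\n"
        )
        ds = read_binding_table(path, {allele.name: allele})
        assert len(ds) == 3
        assert round(ds.records[0].affinity_norm, 3) == 0.426
        assert ds.records[0].label == 0  # 0.426 is not above 0.426
        assert ds.records[1].affinity_norm == pytest.approx(1.0)
        assert ds.records[1].label == 1
        assert [r.fold for r in ds.records] == [0, 1, 2]

    def test_malformed_rows_reported_with_line_numbers(self, allele, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text(
            f"ACDEFGHIK 500 {allele.name}\n"
            "ACDB 10 NOPE\n"
            f"ACDEFGHIKX 10 {allele.name}\n".replace("X", "B")
        )
        ds, issues = read_binding_table(path, {allele.name: allele}, collect_errors=True)
        assert len(ds) == 1
        assert sorted(i.lineno for i in issues) == [2, 3]

    def test_unknown_allele_raises_without_collect(self, allele, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("ACDEFGHIK 500 NOPE\n")
        with pytest.raises(UnknownAllele):
            read_binding_table(path, {allele.name: allele})

    def test_allele_table_tsv_and_fasta(self, allele, tmp_path):
        tsv = tmp_path / "alleles.tsv"
        write_allele_table({allele.name: allele}, tsv)
        assert read_allele_table(tsv)[allele.name] == allele
        fasta = tmp_path / "alleles.fasta"
        fasta.write_text(f">{allele.name}\n{allele.pseudo_sequence}\n")
        assert read_allele_table(fasta)[allele.name] == allele


class TestSplits:
    def test_lomo_partition(self, small_dataset):
        names = sorted({r.allele_name for r in small_dataset.records})
        total = 0
        for name in names:
            train, test = split_lomo(small_dataset, name)
            assert all(r.allele_name == name for r in test.records)
            assert all(r.allele_name != name for r in train.records)
            assert len(train) + len(test) == len(small_dataset)
            total += len(test)
        assert total == len(small_dataset)  # test sets partition the data

    def test_lomo_unknown_or_empty_allele(self, small_dataset, allele):
        with pytest.raises(UnknownAllele):
            split_lomo(small_dataset, "NOPE")
        ds = Dataset(
            alleles={**small_dataset.alleles, allele.name: allele},
            records=small_dataset.records,
        )
        with pytest.raises(UnknownAllele):
            split_lomo(ds, allele.name)  # allele present but recordless

    def test_filter_lomo_boundaries(self, allele):
        other = MHCAllele("OTHER", allele.pseudo_sequence)
        alleles = {allele.name: allele, other.name: other}
        records = []
        # allele: 41 observations, exactly 3 binders -> kept
        for i in range(41):
            records.append(
                BindingRecord(allele.name, "ACDEFGHIK", affinity_norm=0.9 if i < 3 else 0.1)
            )
        # other: 40 observations, 10 binders -> dropped (needs strictly > 40)
        for i in range(40):
            records.append(
                BindingRecord(other.name, "ACDEFGHIK", affinity_norm=0.9 if i < 10 else 0.1)
            )
        ds = Dataset(alleles=alleles, records=records)
        assert filter_lomo_alleles(ds) == [allele.name]
        assert filter_lomo_alleles(Dataset(alleles=alleles, records=[])) == []

    def test_split_folds_requires_folds(self, allele):
        rec = BindingRecord(allele.name, "ACDEFGHIK", affinity_norm=0.5)
        ds = Dataset(alleles={allele.name: allele}, records=[rec])
        with pytest.raises(MissingFolds):
            split_folds(ds)
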