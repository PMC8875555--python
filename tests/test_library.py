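"""Library reading, standardisation, filtering and representative selection."""

import numpy as np
import pytest

import dualscreen as ds
from dualscreen.library import molecular_weight, standardize_smiles, to_nM

from conftest import SULFA_CL, SULFA_OET, SULFA_OME


def write_table(path, rows, header="molecule_id,smiles,target_id,potency_type,potency_value,potency_unit"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadLibrary:
    def test_unparseable_rows_skipped_and_counted(self, tmp_path):
        p = tmp_path / "lib.csv"
        write_table(p, [
            "m1,CCO,T1,Ki,100,nM",
            "m2,xx((bad,T1,Ki,100,nM",
            "m3,c1ccccc1,T1,IC50,2,uM",
        ])
        records, report = ds.read_library(p)
        assert len(records) == 2
        assert report.n_skipped == 1 and report.skipped_ids == ["m2"]

    def test_micromolar_converted_to_nM(self, tmp_path):
        p = tmp_path / "lib.csv"
        write_table(p, ["m1,CCO,T1,IC50,0.5,uM"])
        records, _ = ds.read_library(p)
        assert records[0].potency_nM == pytest.approx(500.0)
        assert records[0].potency_type == "IC50"

    def test_salt_stripping_keeps_largest_fragment(self, tmp_path):
        p = tmp_path / "lib.csv"
        write_table(p, ["m1,[Na+].[O-]C(=O)c1ccccc1,T1,Ki,10,nM"])
        records, _ = ds.read_library(p)
        assert "Na" not in records[0].smiles
        assert "c1cc" in records[0].smiles

    def test_duplicate_ids_merge_to_minimum_potency(self, tmp_path):
        p = tmp_path / "lib.csv"
        write_table(p, ["m1,CCO,T1,Ki,300,nM", "m1,CCO,T1,IC50,100,nM"])
        records, report = ds.read_library(p)
        assert len(records) == 1
        assert records[0].potency_nM == pytest.approx(100.0)
        assert report.n_merged_duplicates == 1

    def test_sdf_round_trip_gives_canonical_smiles(self, tmp_path):
        from rdkit import Chem

        smiles = ["CCO", "c1ccccc1", "CC(=O)O", "CCN", "C1CCCCC1"]
        sdf = tmp_path / "lib.sdf"
        with Chem.SDWriter(str(sdf)) as w:
            for i, s in enumerate(smiles):
                mol = Chem.MolFromSmiles(s)
                mol.SetProp("_Name", f"m{i}")
                w.write(mol)
        records, report = ds.read_library(sdf, format="sdf")
        assert len(records) == 5 and report.n_skipped == 0
        expected = {Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in smiles}
        assert {r.smiles for r in records} == expected

    def test_missing_file_and_missing_column(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ds.read_library(tmp_path / "absent.csv")
        p = tmp_path / "bad.csv"
        p.write_text("molecule_id,structure\nm1,CCO\n")
        with pytest.raises(ValueError, match="column"):
            ds.read_library(p)

    def test_all_rows_unparseable_raises(self, tmp_path):
        p = tmp_path / "lib.csv"
        write_table(p, ["m1,((((,T1,Ki,1,nM"])
        with pytest.raises(ValueError, match="no parseable"):
            ds.read_library(p)


class TestUnitConversion:
    @pytest.mark.parametrize("value,unit,expected", [
        (0.5, "uM", 500.0), (1.0, "M", 1e9), (250.0, "nM", 250.0), (2.0, "mM", 2e6),
    ])
    def test_to_nM(self, value, unit, expected):
        assert to_nM(value, unit) == pytest.approx(expected)

    def test_round_trip_preserves_value(self):
        rng = np.random.default_rng(0)
        for v in rng.uniform(0.1, 1e6, size=50):
            assert to_nM(v / 1e3, "uM") == pytest.approx(v, rel=1e-12)


class TestFilterLibrary:
    def rec(self, mid, smiles, pot):
        return ds.MoleculeRecord(molecule_id=mid, smiles=smiles, potency_nM=pot,
                                 potency_type="Ki")

    def test_inside_both_cutoffs_retained(self):
        r = self.rec("m1", "CCO", 100.0)  # MW 46, well inside
        assert ds.filter_library([r]) == [r]

    def test_mw_boundary_is_strict(self):
        benzene = self.rec("m1", "c1ccccc1", 100.0)
        mw = molecular_weight("c1ccccc1")
        cfg_excl = ds.CurationConfig(mw_max=mw - 1e-6)
        cfg_incl = ds.CurationConfig(mw_max=mw + 1e-6)
        assert ds.filter_library([benzene], cfg_excl) == []
        assert ds.filter_library([benzene], cfg_incl) == [benzene]

    def test_potency_boundary_is_strict(self):
        records = [self.rec(f"m{i}", "CCO", p) for i, p in enumerate([450.0, 500.0, 550.0])]
        kept = ds.filter_library(records)
        assert [r.potency_nM for r in kept] == [450.0]

    def test_unannotated_potency_excluded(self):
        r = ds.MoleculeRecord(molecule_id="m1", smiles="CCO")
        assert ds.filter_library([r]) == []

    def test_idempotent(self):
        records = [self.rec(f"m{i}", "CCO", p) for i, p in enumerate([10.0, 499.0, 600.0])]
        once = ds.filter_library(records)
        assert ds.filter_library(once) == once

    def test_order_preserved(self):
        records = [self.rec(f"m{i}", "CCO", p) for i, p in enumerate([400.0, 300.0, 200.0])]
        kept = ds.filter_library(records)
        assert [r.molecule_id for r in kept] == ["m0", "m1", "m2"]


class TestSelectRepresentatives:
    def rec(self, mid, smiles, pot):
        return ds.MoleculeRecord(molecule_id=mid, smiles=smiles, potency_nM=pot,
                                 potency_type="Ki")

    def test_similar_pair_collapses_to_most_potent(self):
        # OME/OET are one cluster at TC 0.6 (TC ~ 0.607); CL is apart
        assert ds.tanimoto(ds.fingerprint(SULFA_OME), ds.fingerprint(SULFA_OET)) >= 0.6
        assert ds.tanimoto(ds.fingerprint(SULFA_OME), ds.fingerprint(SULFA_CL)) < 0.6
        records = [
            self.rec("a", SULFA_OME, 100.0),
            self.rec("b", SULFA_OET, 50.0),
            self.rec("c", SULFA_CL, 200.0),
        ]
        reps = ds.select_representative_actives(records)
        assert {r.molecule_id for r in reps} == {"b", "c"}
        assert all(r.role == "active" for r in reps)

    def test_singleton_returns_itself(self):
        r = self.rec("only", SULFA_CL, 42.0)
        reps = ds.select_representative_actives([r])
        assert len(reps) == 1 and reps[0].molecule_id == "only"

    def test_potency_tie_broken_by_lexicographic_id(self):
        records = [
            self.rec("zz", SULFA_OME, 100.0),
            self.rec("aa", SULFA_OET, 100.0),
        ]
        reps = ds.select_representative_actives(records)
        assert [r.molecule_id for r in reps] == ["aa"]

    def test_representatives_are_subset_and_dissimilar(self, small_benchmark):
        actives, _, _ = small_benchmark
        subset = actives[:25]
        cfg = ds.CurationConfig(cluster_tc_cutoff=0.6)
        reps = ds.select_representative_actives(subset, cfg)
        ids = {r.molecule_id for r in subset}
        assert all(r.molecule_id in ids for r in reps)
        # distinct-cluster representatives were split by the oracle partition
        fps = ds.fingerprints([r.smiles for r in subset])
        clusters = ds.butina_cluster(fps, 0.6)
        assert len(reps) == len(clusters)

    def test_missing_potency_raises(self):
        with pytest.raises(ValueError):
            ds.select_representative_actives(
                [ds.MoleculeRecord(molecule_id="x", smiles="CCO")]
            )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ds.select_representative_actives([])
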