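"""Dataset assembly, cross-validation, model selection, screening, external validation."""

import numpy as np
import pytest

import dualscreen as ds
from dualscreen.screen import SIMPLICITY_ORDER

from conftest import PYRIDINE, SULFA_CL, SULFA_OET, SULFA_OME, SULFA_XYL


class TestAssembleDataset:
    def test_shapes_and_labels(self, small_benchmark):
        actives, background, _ = small_benchmark
        inactives = [ds.MoleculeRecord(molecule_id=r.molecule_id, smiles=r.smiles,
                                       role="inactive") for r in background[:40]]
        data = ds.assemble_dataset(actives[:10], inactives, "ECFP4", seed=0)
        assert data.X.shape == (50, 1024)
        assert data.y.sum() == 10
        assert len(data.ids) == 50

    def test_two_row_minimal_case(self):
        a = [ds.MoleculeRecord(molecule_id="a", smiles="CCO", role="active")]
        i = [ds.MoleculeRecord(molecule_id="b", smiles="CCC", role="inactive")]
        data = ds.assemble_dataset(a, i, "MACCS")
        assert data.X.shape == (2, 166)

    def test_duplicate_id_across_classes_raises(self):
        a = [ds.MoleculeRecord(molecule_id="x", smiles="CCO", role="active")]
        i = [ds.MoleculeRecord(molecule_id="x", smiles="CCC", role="inactive")]
        with pytest.raises(ValueError, match="both classes"):
            ds.assemble_dataset(a, i)

    def test_shuffle_deterministic_under_seed(self, small_benchmark):
        actives, background, _ = small_benchmark
        inactives = [ds.MoleculeRecord(molecule_id=r.molecule_id, smiles=r.smiles)
                     for r in background[:20]]
        d1 = ds.assemble_dataset(actives[:5], inactives, seed=4)
        d2 = ds.assemble_dataset(actives[:5], inactives, seed=4)
        assert d1.ids == d2.ids and d1.data_hash() == d2.data_hash()


class TestCrossValidate:
    def test_separable_benchmark_high_mcc(self, trained_separable):
        _, dataset, _, _ = trained_separable
        spec = ds.ModelSpec(algorithm="Logit", seed=3)
        report = ds.cross_validate(dataset, spec, k=5, runs=2)
        assert len(report.folds) == 10
        assert report.mean("mcc") >= 0.95
        assert report.mean("auc") >= 0.99

    def test_permuted_labels_give_null_mcc(self, trained_separable):
        _, dataset, _, _ = trained_separable
        from dualscreen.screen import Dataset

        rng = np.random.default_rng(0)
        y_perm = rng.permutation(dataset.y)
        null = Dataset(X=dataset.X, y=y_perm, ids=dataset.ids, fingerprint_kind="ECFP4")
        spec = ds.ModelSpec(algorithm="Logit", seed=3)
        report = ds.cross_validate(null, spec, k=5, runs=2)
        assert abs(report.mean("mcc")) <= 3 * max(report.sd("mcc"), 0.05)

    def test_same_seed_reproduces_report(self, trained_separable):
        _, dataset, _, _ = trained_separable
        spec = ds.ModelSpec(algorithm="DT", seed=9)
        r1 = ds.cross_validate(dataset, spec, k=5, runs=1)
        r2 = ds.cross_validate(dataset, spec, k=5, runs=1)
        assert [f.mcc for f in r1.folds] == [f.mcc for f in r2.folds]

    def test_class_too_small_for_folds_raises(self):
        a = [ds.MoleculeRecord(molecule_id=f"a{i}", smiles="CCO") for i in range(2)]
        i_ = [ds.MoleculeRecord(molecule_id=f"i{j}", smiles="CCC") for j in range(9)]
        # duplicate smiles are fine for shape purposes; ids are unique
        data = ds.assemble_dataset(a, i_)
        with pytest.raises(ValueError, match="stratified"):
            ds.cross_validate(data, ds.ModelSpec(), k=5)


def _report_with_mcc(algorithm, mcc):
    spec = ds.ModelSpec(algorithm=algorithm)
    fold = ds.MetricSet(tp=1, tn=1, fp=0, fn=0, acc=1.0, mcc=mcc, auc=None)
    return ds.CVReport(model_spec=spec, folds=[fold, fold])


class TestSelectModel:
    def test_highest_mean_mcc_wins(self):
        # mirrors a Logit-vs-MLP comparison where MLP edges out on MCC
        best = ds.select_model([_report_with_mcc("Logit", 0.863),
                                _report_with_mcc("MLP", 0.883)])
        assert best.algorithm == "MLP"

    def test_exact_tie_goes_to_simpler_model(self):
        best = ds.select_model([_report_with_mcc("MLP", 0.9),
                                _report_with_mcc("Logit", 0.9)])
        assert best.algorithm == "Logit"
        assert SIMPLICITY_ORDER.index("Logit") < SIMPLICITY_ORDER.index("MLP")

    def test_single_report_returned(self):
        best = ds.select_model([_report_with_mcc("RF", 0.5)])
        assert best.algorithm == "RF"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            ds.select_model([])


class TestTrainFinalAndScreen:
    def test_training_actives_score_high(self, trained_separable):
        model, dataset, _, train_act = trained_separable
        p = model.classifier.positive_probability([a.smiles for a in train_act])
        assert p.mean() > 0.5

    def test_same_seed_identical_predictions(self, trained_separable):
        model, dataset, _, train_act = trained_separable
        spec = ds.ModelSpec(algorithm="Logit", seed=3)
        again = ds.train_final(dataset, spec, training_actives=train_act)
        smiles = [a.smiles for a in train_act[:5]]
        assert np.allclose(model.classifier.positive_probability(smiles),
                           again.classifier.positive_probability(smiles))

    def test_manifest_hash_tracks_data(self, trained_separable):
        from dualscreen.screen import Dataset

        model, dataset, _, _ = trained_separable
        X2 = dataset.X.copy()
        X2[0, 0] ^= 1
        other = Dataset(X=X2, y=dataset.y, ids=dataset.ids, fingerprint_kind="ECFP4")
        spec = ds.ModelSpec(algorithm="Logit", seed=3)
        m2 = ds.train_final(other, spec)
        assert m2.manifest["data_hash"] != model.manifest["data_hash"]

    def test_threshold_zero_returns_whole_library(self, trained_separable, small_benchmark):
        model, _, _, _ = trained_separable
        _, background, _ = small_benchmark
        lib = background[:50]
        results = ds.screen_library(model, lib, p_threshold=0.0)
        assert len(results) == 50

    def test_threshold_one_near_empty(self, trained_separable, small_benchmark):
        model, _, _, _ = trained_separable
        _, background, _ = small_benchmark
        results = ds.screen_library(model, background[:100], p_threshold=1.0)
        assert len(results) <= 2

    def test_results_sorted_by_probability_desc(self, trained_separable, small_benchmark):
        model, _, _, _ = trained_separable
        actives, background, _ = small_benchmark
        lib = actives[60:70] + background[:50]
        results = ds.screen_library(model, lib, p_threshold=0.0)
        probs = [r.probability for r in results]
        assert probs == sorted(probs, reverse=True)

    def test_planted_actives_recovered(self, trained_separable, small_benchmark):
        model, _, _, _ = trained_separable
        actives, background, _ = small_benchmark
        planted = actives[60:80]
        lib = planted + background[:300]
        hits = {r.molecule_id for r in ds.screen_library(model, lib, 0.5)}
        recall = len(hits & {a.molecule_id for a in planted}) / len(planted)
        assert recall >= 0.8

    def test_nearest_active_annotation_is_a_training_active(self, trained_separable, small_benchmark):
        model, _, _, train_act = trained_separable
        actives, _, _ = small_benchmark
        results = ds.screen_library(model, actives[60:65], p_threshold=0.0)
        train_ids = {a.molecule_id for a in train_act}
        for r in results:
            assert r.nearest_active_id in train_ids
            assert 0.0 <= r.nearest_active_tc <= 1.0

    def test_empty_library_raises(self, trained_separable):
        model, _, _, _ = trained_separable
        with pytest.raises(ValueError):
            ds.screen_library(model, [])


def _mk_external_fixture():
    """3 training actives; the OME active sits at TC >= 0.6 to the external
    drug (an OET analog); each active carries 4 linked decoys."""
    actives = [
        ds.MoleculeRecord(molecule_id="A1", smiles=SULFA_OME, role="active"),
        ds.MoleculeRecord(molecule_id="A2", smiles=SULFA_CL, role="active"),
        ds.MoleculeRecord(molecule_id="A3", smiles=SULFA_XYL, role="active"),
    ]
    pool = ds.generate_decoy_pool(120, seed=77)
    decoy_set = ds.generate_decoys(actives, pool, n_per_active=4)
    external = [
        ds.MoleculeRecord(molecule_id="DRUG1", smiles=SULFA_OET),
        ds.MoleculeRecord(molecule_id="DRUG2", smiles=PYRIDINE),
    ]
    annotations = {"DRUG1": True, "DRUG2": False}
    return actives, decoy_set, external, annotations


class TestExternalValidation:
    def test_similar_active_and_its_decoys_removed(self):
        actives, decoy_set, external, annotations = _mk_external_fixture()
        # precondition: only A1 crosses the exclusion cutoff
        tcs = [ds.tanimoto(ds.fingerprint(a.smiles), ds.fingerprint(external[0].smiles))
               for a in actives]
        assert tcs[0] >= 0.6 and max(tcs[1:]) < 0.6
        result = ds.external_validation(actives, decoy_set, external, annotations,
                                        model_spec=ds.ModelSpec(seed=1))
        assert result.excluded_active_ids == ["A1"]
        assert set(result.excluded_decoy_ids) == decoy_set.decoy_ids_for("A1")
        assert result.n_actives_retained == 2
        assert result.n_inactives_retained == sum(
            len(v) for k, v in decoy_set.assignments.items() if k != "A1"
        )

    def test_chemically_disjoint_external_changes_nothing(self):
        actives, decoy_set, _, _ = _mk_external_fixture()
        external = [ds.MoleculeRecord(molecule_id="FAR", smiles="CCOC(=O)C1CC1")]
        result = ds.external_validation(actives, decoy_set, external, {"FAR": False},
                                        model_spec=ds.ModelSpec(seed=1))
        assert result.excluded_active_ids == []
        assert result.n_actives_retained == 3

    def test_all_negative_annotations_give_zero_tp(self):
        actives, decoy_set, external, _ = _mk_external_fixture()
        result = ds.external_validation(actives, decoy_set, external,
                                        {e.molecule_id: False for e in external},
                                        model_spec=ds.ModelSpec(seed=1))
        assert result.tp == 0

    def test_exclusion_emptying_actives_raises(self):
        actives, decoy_set, _, _ = _mk_external_fixture()
        external = [ds.MoleculeRecord(molecule_id=f"E{i}", smiles=a.smiles)
                    for i, a in enumerate(actives)]
        with pytest.raises(ValueError, match="every training active"):
            ds.external_validation(actives, decoy_set, external, {},
                                   model_spec=ds.ModelSpec(seed=1))
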