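"""Shared fixtures: small synthetic benchmarks generated at test time."""

import numpy as np
import pytest

import dualscreen as ds

# benzenesulfonamide analogs with known pairwise similarity structure,
# used across the curation / external-validation tests
SULFA_OME = "NS(=O)(=O)c1ccc(OC)cc1"      # TC 0.607 to SULFA_OET (ECFP4)
SULFA_OET = "NS(=O)(=O)c1ccc(OCC)cc1"
SULFA_CL = "NS(=O)(=O)c1ccc(Cl)cc1"       # TC < 0.6 to both of the above
SULFA_XYL = "NS(=O)(=O)c1cc(C)ccc1C"
PYRIDINE = "Cc1ccncc1"
FURAN = "Cc1ccoc1"


@pytest.fixture(scope="session")
def small_benchmark():
    """80 scaffold actives + 700 background, split for train/screen tests."""
    spec = ds.BenchmarkSpec(n_actives=80, n_background=700, seed=7)
    actives, background, truth = ds.generate_screening_benchmark(spec)
    return actives, background, truth


@pytest.fixture(scope="session")
def small_pool():
    return ds.generate_decoy_pool(1200, seed=11)


@pytest.fixture(scope="session")
def trained_separable(small_benchmark, small_pool):
    """Logit/ECFP4 model trained on 30 actives + generated decoys."""
    actives, _, _ = small_benchmark
    train_act = actives[:30]
    decoy_set = ds.generate_decoys(train_act, small_pool, n_per_active=20)
    dataset = ds.assemble_dataset(train_act, decoy_set.all_decoys(), "ECFP4", seed=3)
    spec = ds.ModelSpec(algorithm="Logit", fingerprint_kind="ECFP4", seed=3)
    model = ds.train_final(dataset, spec, training_actives=train_act)
    return model, dataset, decoy_set, train_act


def random_bit_fp(rng, kind="ECFP4", density=0.05):
    n = 1024 if kind.startswith("ECFP") else 166
    bits = (rng.random(n) < density).astype(np.uint8)
    return ds.FingerprintVector(kind=kind, bits=bits)
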