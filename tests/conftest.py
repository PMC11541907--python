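import numpy as np
import pytest

from mrnadecay import synthetic_data as sd


@pytest.fixture(scope="session")
def demo_library():
    """Small default library with barcodes, shared across tests."""
    lib = sd.generate_design_library(sd.default_library_config(scale=0.3), seed=11)
    lib, spike_bc = sd.attach_barcodes(lib, seed=12)
    return lib, spike_bc


@pytest.fixture(scope="session")
def demo_truth(demo_library):
    lib, _ = demo_library
    return sd.generate_truth(lib, sd.TruthParams(), seed=13)


@pytest.fixture(scope="session")
def noise_free_truth(demo_library):
    lib, _ = demo_library
    params = sd.TruthParams(sigma=0.0, m0_sigma=0.0)
    return sd.generate_truth(lib, params, seed=13)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture(scope="session")
def trained_pipeline():
    """Full simulate->fit->featurize->train run shared by the rules and
    acceptance tests (the expensive fixture; built once per session)."""
    from mrnadecay import kinetics as kin
    from mrnadecay.features import build_schema, featurize_library, providers_for_library
    from mrnadecay.model import train_bundle
    from mrnadecay.pipeline import build_dataset

    lib = sd.generate_design_library(sd.default_library_config(1.0), seed=1)
    lib, spike_bc = sd.attach_barcodes(lib, seed=2)
    truth = sd.generate_truth(lib, sd.TruthParams(), seed=3)
    table = sd.simulate_counts(truth, depth=2000 * len(lib), seed=4)
    fits = kin.fit_decay_table(kin.normalize(table))
    kept, qc = kin.apply_qc(fits, table)
    schema = build_schema()
    providers = providers_for_library(lib)
    X = featurize_library(lib, providers, schema)
    dataset = build_dataset(lib, table, kept, X, schema, split_seed=5)
    bundle = train_bundle(dataset, seed=6)
    return {
        "library": lib,
        "truth": truth,
        "table": table,
        "fits": kept,
        "qc": qc,
        "features": X,
        "schema": schema,
        "providers": providers,
        "dataset": dataset,
        "bundle": bundle,
    }
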