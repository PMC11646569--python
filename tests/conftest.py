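import numpy as np
import pytest

from dihedralkd.dihedral import build_backbone
from dihedralkd.evaluation import evaluate
from dihedralkd.kd_model import BindingDistillationModel, DistillConfig
from dihedralkd.synthetic import SimConfig, simulate_dataset


@pytest.fixture
def helix_chain():
    """12-residue alpha-helical backbone (phi=-57, psi=-47)."""
    l = 12
    return build_backbone("ACDEFGHIKLMN"[:l], [-57.0] * (l - 2), [-47.0] * (l - 2))


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-signal dataset for fast unit-level checks."""
    return simulate_dataset(SimConfig(n_pairs=400, angular_noise_sd=20.0, seed=11))


def fit_and_score(seed: int, permute_labels: bool = False,
                  n_pairs: int = 2000, noise_sd: float = 20.0,
                  epochs: int = 20):
    """One full study run: simulate, (optionally permute), fit, evaluate.

    Returns (results, report, dataset, test_probs).
    """
    ds = simulate_dataset(SimConfig(n_pairs=n_pairs, angular_noise_sd=noise_sd,
                                    seed=seed))
    x_train, y_train = ds.paired_inputs("train")
    x_test, _ = ds.paired_inputs("test")
    if permute_labels:
        y_train = np.random.default_rng(seed).permutation(y_train)
    model = BindingDistillationModel(
        x_train, y_train, distill_config=DistillConfig(epochs=epochs, seed=seed)
    )
    results = model.fit()
    probs = results.predict(x_test)
    report = evaluate(probs, ds.test, {r.peptide for r in ds.train},
                      k_subsets=10, seed=seed)
    return results, report, ds, probs


@pytest.fixture(scope="session")
def signal_runs():
    """Five seed-controlled planted-signal training runs (shared: slow)."""
    return {seed: fit_and_score(seed) for seed in range(5)}


@pytest.fixture(scope="session")
def permuted_runs():
    """Label-permuted control runs over the same five seeds."""
    return {seed: fit_and_score(seed, permute_labels=True) for seed in range(5)}
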