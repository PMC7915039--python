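import numpy as np
import pytest

from grasplearn import classifier, labeling, synth

CORPUS_SEED = 42


@pytest.fixture(scope="session")
def default_corpus():
    """One subject's glove corpus at default (2 % of plateau) noise."""
    return synth.generate_training_corpus("S01", seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_corpus):
    return labeling.assemble_dataset(default_corpus, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def trained_model(default_dataset):
    """Subject-specific grasp detector trained on the default corpus."""
    return classifier.train_ann(
        default_dataset, classifier.TrainConfig(seed=CORPUS_SEED))


@pytest.fixture(scope="session")
def default_report(trained_model, default_dataset):
    return classifier.evaluate(trained_model, default_dataset)


def make_xor_dataset(seed: int, reps: int = 50) -> labeling.LabeledDataset:
    """The classic non-linearly-separable 2-bit parity problem,
    duplicated so the 70/15/15 split sees every corner in every split."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 1, 1, 0], dtype=np.uint8)
    Xr = np.tile(X, (reps, 1))
    yr = np.tile(y, reps)
    n = len(yr)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    split = np.empty(n, dtype="U5")
    n_tr = int(round(0.7 * n))
    n_va = int(round(0.15 * n))
    split[order[:n_tr]] = "train"
    split[order[n_tr:n_tr + n_va]] = "val"
    split[order[n_tr + n_va:]] = "test"
    return labeling.LabeledDataset(
        features=Xr, labels=yr, split=split,
        trial_id=np.zeros(n, dtype=int), frame_idx=np.arange(n),
        grip=np.full(n, "pinch"), protocol=np.full(n, "hold"),
        tol=0.10, activity_floor=0.05, seed=seed)
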