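import numpy as np
import pytest

from patchaudit import GeneratorParams, generate_dataset, split_train_test


@pytest.fixture(scope="session")
def small_dataset():
    """60 confounded images at the default working resolution."""
    return generate_dataset(GeneratorParams(n_benign=40, n_malignant=20, seed=3))


@pytest.fixture(scope="session")
def patched_images(small_dataset):
    return [im for im in small_dataset if im.has_patch]


@pytest.fixture(scope="session")
def plain_images(small_dataset):
    return [im for im in small_dataset if not im.has_patch]


@pytest.fixture(scope="session")
def trained_classifier():
    """Reference classifier fitted on a small confounded training set."""
    from patchaudit import ReferenceClassifier

    ds = generate_dataset(GeneratorParams(n_benign=150, n_malignant=150, seed=7))
    train, _ = split_train_test(ds, 0.8, seed=7)
    return ReferenceClassifier().fit(train)


class ConstantClassifier:
    """Contract-conforming classifier that ignores pixels entirely."""

    def __init__(self, p_malignant: float = 0.3):
        self.p = p_malignant

    def predict_proba(self, images):
        from patchaudit import PredictionRecord

        out = []
        for i, im in enumerate(images):
            pid = im.id if hasattr(im, "id") else str(i)
            out.append(
                PredictionRecord(id=pid, p_malignant=self.p, p_benign=1 - self.p)
            )
        return out


@pytest.fixture
def constant_classifier():
    return ConstantClassifier()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
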