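"""Shared fixtures: study-scale dataset, reference detectors, mock models.

Expensive artifacts (the 150-image study dataset, the trained CNN) are
session-scoped so the whole suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from camaudit.models import DetectionModel, template_detector, train_small_cnn
from camaudit.synthetic import DatasetSpec, generate_dataset

STUDY_SEED = 7
LESION_RADIUS = 8


@pytest.fixture(scope="session")
def study_dataset():
    """The study-design dataset: 150 images, half with one lesion."""
    return generate_dataset(
        DatasetSpec(n_images=150, lesion_fraction=0.5, seed=STUDY_SEED)
    )


@pytest.fixture(scope="session")
def lesion_images(study_dataset):
    return [img for img in study_dataset if img.lesion_present]


@pytest.fixture(scope="session")
def subset30(study_dataset):
    """Balanced 30-image subset for the heavier fidelity checks."""
    present = [i for i in study_dataset if i.lesion_present][:15]
    absent = [i for i in study_dataset if not i.lesion_present][:15]
    return present + absent


@pytest.fixture(scope="session")
def template_det():
    return template_detector(LESION_RADIUS)


@pytest.fixture(scope="session")
def train_set():
    return generate_dataset(DatasetSpec(n_images=100, seed=21))


@pytest.fixture(scope="session")
def trained_cnn(train_set):
    return train_small_cnn(train_set, epochs=50, seed=3)


class StaticModel(DetectionModel):
    """Minimal contract implementation around a fixed activation stack.

    The score is a linear functional of the channel means
    (``score = sum_c coef_c * mean(A_c)``), which gives Ablation CAM a
    closed-form expected weight per channel.
    """

    def __init__(self, acts: np.ndarray, coefs=None, ablated=frozenset()):
        self.acts = np.asarray(acts, dtype=float)
        n_ch = self.acts.shape[0]
        self.coefs = (
            np.ones(n_ch) if coefs is None else np.asarray(coefs, dtype=float)
        )
        self._ablated = ablated
        self.layer_names = ("feat",)
        self.cam_layer = "feat"

    def _current(self):
        acts = self.acts.copy()
        for layer, ch in self._ablated:
            acts[ch] = 0.0
        return acts

    def score(self, image):
        acts = self._current()
        return float(self.coefs @ acts.mean(axis=(1, 2))), None

    def activations(self, image, layer):
        assert layer == "feat"
        return self._current()

    def with_randomized_layers(self, layers, seed):
        rng = np.random.default_rng(seed)
        return StaticModel(
            rng.random(self.acts.shape), self.coefs, self._ablated
        )

    def with_ablated_channel(self, layer, channel):
        return StaticModel(
            self.acts, self.coefs, self._ablated | {(layer, channel)}
        )


@pytest.fixture(scope="session")
def static_model_factory():
    # stateless class handle, safe to share across tests and hypothesis runs
    return StaticModel
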