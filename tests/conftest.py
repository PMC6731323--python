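"""Shared fixtures. The expensive fixtures (full-scale training, the large
evaluation slides) are session-scoped and built once; cheap unit fixtures
are rebuilt per test where mutation matters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ki67net as k

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from ki67net.synthetic import benchmark_slide_spec as training_slide_spec
from ki67net.synthetic import hotspot_benchmark_spec as hotspot_slide_spec


def balanced_subset(ps: k.PatchSet, n_total: int, seed: int) -> k.PatchSet:
    """Strictly class-balanced subsample (per-class count limited by the
    rarest class)."""
    rng = np.random.default_rng(seed)
    classes = np.unique(ps.labels)
    counts = [int((ps.labels == c).sum()) for c in classes]
    per = min(n_total // len(classes), min(counts))
    sel = [
        rng.permutation(np.flatnonzero(ps.labels == c))[:per] for c in classes
    ]
    order = rng.permutation(np.concatenate(sel))
    return ps.subset(order)


# ------------------------------------------------------------------ #
# cheap fixtures


@pytest.fixture(scope="session")
def small_slide():
    """512x512 demo slide + ground truth for cheap pipeline tests."""
    return k.generate_pseudo_slide(k.demo_slide_spec(512, 512, seed=3))


@pytest.fixture(scope="session")
def separable_patches():
    """Colour-separable fixture: noisy pure-blue (non-tumour) vs
    pure-brown (tumour) patches, 200 each."""
    rng = np.random.default_rng(42)
    n = 200
    X = np.empty((2 * n, 64, 64, 3), np.uint8)
    y = np.empty(2 * n, dtype="<U16")
    blue = np.array([120.0, 110.0, 190.0])
    brown = np.array([160.0, 120.0, 80.0])
    for i in range(2 * n):
        base = blue if i % 2 == 0 else brown
        y[i] = "non-tumour" if i % 2 == 0 else "tumour"
        X[i] = np.clip(base + rng.normal(0, 30, (64, 64, 3)), 0, 255)
    return X, y


@pytest.fixture(scope="session")
def separable_model(separable_patches):
    """Classifier trained briefly on the colour-separable fixture."""
    X, y = separable_patches
    model = k.PatchCNNClassifier(epochs=3, random_state=0).fit(X[:300], y[:300])
    return model, X[300:], y[300:]


# ------------------------------------------------------------------ #
# heavy session fixtures (only built when a test requests them)

ACCEPT_SEED = 20260924


@pytest.fixture(scope="session")
def training_patches():
    """2,000 class-balanced tumour/non-tumour patches from a synthetic
    training slide (64x64, stride 32, purity 0.9)."""
    slide, gt = k.generate_pseudo_slide(training_slide_spec(ACCEPT_SEED))
    ps = k.extract_labelled_patches(
        slide, gt.annotation_set, k.TileGrid(64, 32), purity=0.9
    )
    infi = k.extract_labelled_patches(
        slide, gt.annotation_set, k.TileGrid(64, 32), purity=0.9, task="infiltrate"
    )
    return balanced_subset(ps, 2000, seed=ACCEPT_SEED), infi


@pytest.fixture(scope="session")
def trained_model(training_patches):
    """The tumour classifier trained at the published configuration
    (lr 0.001, momentum 0.9, 15 epochs, batch 25, dropout 0.5) on 1,600
    patches, with the remaining 400 held out."""
    ps, _ = training_patches
    train, hold = ps.subset(np.arange(400, len(ps))), ps.subset(np.arange(400))
    model = k.PatchCNNClassifier(epochs=15, random_state=1).fit(
        train.patches, train.labels
    )
    return model, hold


@pytest.fixture(scope="session")
def infiltrate_model(training_patches):
    """The infiltrate classifier: identical architecture, infiltrate /
    non-infiltrate labels, briefly trained (the task is easy)."""
    _, infi = training_patches
    ps = balanced_subset(infi, 600, seed=ACCEPT_SEED + 1)
    return k.PatchCNNClassifier(epochs=4, random_state=2).fit(ps.patches, ps.labels)


@pytest.fixture(scope="session")
def eval_slide():
    """Independent 2048x2048 slide (different seed from training) for
    end-to-end segmentation evaluation."""
    return k.generate_pseudo_slide(training_slide_spec(ACCEPT_SEED + 17))


@pytest.fixture(scope="session")
def hotspot_scene():
    """1024x1024 tumour slide, ambient Ki67 fraction 0.05, with one
    hotspot planted at fraction 0.5."""
    slide, gt = k.generate_pseudo_slide(hotspot_slide_spec(ACCEPT_SEED + 5))
    centre = (512, 512)
    slide2, gt2 = k.plant_hotspot(slide, gt, centre, 160, 0.5, rng_seed=9)
    return slide2, gt2, centre
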