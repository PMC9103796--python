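"""Shared fixtures.

The 17-scene study set and the experiments that run on it are expensive,
so they are built once per session and shared; everything is generated
programmatically from fixed seeds.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from hsskin.classify import ModelConfig, REDUCED_CONFIG
from hsskin.evaluate import (
    prepare_scene_sets,
    run_leave_one_out,
    run_slice_half_experiment,
)
from hsskin.scenes import make_dataset

STUDY_SEED = 42
N_SCENES = 17
OUTLIER_SCENE = 3
# desk-scale per-side sample counts for the CNN experiments
N_LESION_EXP = 50
N_HEALTHY_EXP = 20

#: Very small architecture for structure-only runs (many retrainings).
TINY_CONFIG = ModelConfig(
    conv3d_blocks=((2, (3, 3, 7), (2, 2, 2), (2, 2, 2)),),
    conv2d_blocks=((2, (3, 3), (2, 2), (2, 2)),),
    dense_units=(16,),
    batch_size=128,
    epochs=1,
)

#: Small architecture trained long enough to learn separable toys.
FAST_CONFIG = ModelConfig(
    conv3d_blocks=((4, (3, 3, 7), (2, 2, 2), (2, 2, 2)),),
    conv2d_blocks=((4, (3, 3), (2, 2), (2, 2)),),
    dense_units=(16,),
    batch_size=32,
    epochs=6,
)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """17 synthetic lesion scenes (one with a scene-unique lesion),
    processed through the full raw pipeline and windowed at desk-scale
    sample counts.  Measurements are dropped after processing; stacks and
    masks are kept for re-sampling at other counts."""
    dataset = make_dataset(N_SCENES, seed=STUDY_SEED, outlier_scenes=(OUTLIER_SCENE,))
    sets = prepare_scene_sets(
        dataset,
        n_lesion=N_LESION_EXP,
        n_healthy=N_HEALTHY_EXP,
        seed=STUDY_SEED,
        keep_stacks=True,
    )
    gts = [gt for _, gt in dataset]
    lesion_classes = [gt.lesion_class for gt in gts]
    del dataset
    return SimpleNamespace(
        sets=sets,
        gts=gts,
        lesion_classes=lesion_classes,
        outlier_scene=OUTLIER_SCENE,
        seed=STUDY_SEED,
    )


@pytest.fixture(scope="session")
def slice_half(study):
    """The slice-half experiment at the reduced desk-scale architecture."""
    return run_slice_half_experiment(study.sets, REDUCED_CONFIG, seed=study.seed)


@pytest.fixture(scope="session")
def loo_all(study, slice_half):
    """All 17 leave-one-out folds at the tiny structural configuration."""
    return run_leave_one_out(
        study.sets, TINY_CONFIG, seed=study.seed, slice_half=slice_half
    )


@pytest.fixture(scope="session")
def loo_outlier(study, slice_half):
    """One reduced-architecture fold holding out the scene-unique lesion."""
    return run_leave_one_out(
        study.sets,
        REDUCED_CONFIG,
        seed=study.seed,
        folds=[study.outlier_scene],
        slice_half=slice_half,
        groups={study.outlier_scene: "unique"},
    )


def make_toy_subcubes(n=120, seed=0, n_classes=3):
    """Separable toy sub-cube set: class identity encoded in channel means."""
    from hsskin.preprocess import SubCubeSet, PROV_ORIGINAL

    rng = np.random.default_rng(seed)
    cubes = rng.normal(0.5, 0.05, size=(n, 30, 30, 34)).astype(np.float32)
    labels = rng.integers(0, n_classes, n)
    for i in range(n):
        cubes[i, :, :, int(labels[i]) * 10] += 0.4
    return SubCubeSet(
        cubes=cubes,
        labels=labels.astype(np.int64),
        scene_ids=np.zeros(n, dtype=np.int64),
        provenance=np.full(n, PROV_ORIGINAL, dtype=np.int8),
    )
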