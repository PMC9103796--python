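"""Two-branch convolutional pixel classifier.

Each sampled pixel is classified from its 30 x 30 x 34 window: the 33
albedo channels go through a 3-D convolutional branch (the window treated
as a single-channel volume over rows x cols x bands), the depth channel
through a 2-D branch; both branch outputs are flattened, concatenated and
passed through dense layers to a 3-way softmax (0 healthy, 1 intradermal
nevus, 2 basal cell carcinoma).  Training uses Adam at its default
parameters with categorical cross-entropy, fully seeded.

The published architecture figure fixes only the block structure (3-D and
2-D conv/LeakyReLU/max-pool branches, concatenated, dense head); filter
counts, kernel and dense sizes, epochs and batch size are this package's
choices, kept small enough to train on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocess import FeatureStack, SubCubeSet, extract_windows

__all__ = [
    "ModelConfig",
    "PredictionMap",
    "REDUCED_CONFIG",
    "build_model",
    "train",
    "predict_pixels",
    "classify_image",
]

N_CLASSES = 3


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyper-parameters.

    conv3d_blocks / conv2d_blocks are lists of (filters, kernel, pool) with
    an optional fourth element, the convolution stride (first block only);
    each block is conv -> LeakyReLU -> max-pool (an all-ones pool is
    skipped).  ``use_depth_branch=False`` drops the 2-D branch (ablation:
    spectra only).
    """

    conv3d_blocks: tuple = ((8, (3, 3, 7), (2, 2, 2)), (16, (3, 3, 5), (2, 2, 2)))
    conv2d_blocks: tuple = ((8, (3, 3), (2, 2)), (16, (3, 3), (2, 2)))
    dense_units: tuple = (64, 16)
    leaky_slope: float = 0.1
    n_classes: int = N_CLASSES
    batch_size: int = 32
    epochs: int = 20
    learning_rate: float = 1e-3
    seed: int = 0
    use_depth_branch: bool = True
    window: int = 30
    n_bands: int = 33

    def __post_init__(self):
        if len(self.conv3d_blocks) < 1:
            raise ValueError("the 3-D branch needs at least one block")
        if self.use_depth_branch and len(self.conv2d_blocks) < 1:
            raise ValueError("the 2-D branch needs at least one block")
        if self.n_classes != 3:
            raise ValueError("the classifier is a fixed 3-class model")


#: Smaller architecture for desk-scale experiments (single CPU): strided
#: first convolutions stand in for the first conv + pool pair.
REDUCED_CONFIG = ModelConfig(
    conv3d_blocks=(
        (4, (3, 3, 7), (2, 2, 2), (2, 2, 2)),
        (8, (3, 3, 5), (1, 1, 1)),
    ),
    conv2d_blocks=((4, (3, 3), (2, 2), (2, 2)), (8, (3, 3), (1, 1))),
    dense_units=(32,),
    batch_size=64,
    epochs=8,
)


@dataclass
class PredictionMap:
    """Class and per-class confidence grids assembled from tiled windows."""

    class_map: np.ndarray  # (gh, gw) argmax labels
    confidence_maps: np.ndarray  # (gh, gw, 3) probabilities, rows sum to 1
    step: int = 5


@dataclass
class TrainedModel:
    """A built network plus the configuration that produced it."""

    net: nn.TwoBranchNet
    config: ModelConfig
    history: dict = field(default_factory=dict)


def _build_branch(ndim, in_shape, blocks, slope, rng):
    """Stack conv/LeakyReLU/pool blocks, validating shapes as we go."""
    layers = []
    shape = in_shape  # (*spatial, channels)
    for bi, block in enumerate(blocks):
        filters, kernel, pool = block[:3]
        stride = block[3] if len(block) > 3 else None
        name = f"{ndim}d block {bi}"
        conv = nn.Conv(
            ndim, shape[-1], filters, kernel, rng, name=name, first=bi == 0,
            stride=stride,
        )
        shape = conv.out_shape(shape)
        layers += [conv, nn.LeakyReLU(slope)]
        if any(p > 1 for p in pool):
            pool_layer = nn.MaxPool(pool, name=name)
            shape = pool_layer.out_shape(shape)
            layers.append(pool_layer)
    layers.append(nn.Flatten())
    return nn.Sequential(layers), int(np.prod(shape))


def build_model(config: ModelConfig) -> TrainedModel:
    """Construct the untrained two-branch network from a configuration.

    Identical seeds give identical initial weights.  Raises when a conv
    kernel or pool would collapse a dimension below 1, naming the block.
    """
    rng = np.random.default_rng(config.seed)
    w = config.window
    branch3d, n3 = _build_branch(
        3, (w, w, config.n_bands, 1), config.conv3d_blocks, config.leaky_slope, rng
    )
    if config.use_depth_branch:
        branch2d, n2 = _build_branch(
            2, (w, w, 1), config.conv2d_blocks, config.leaky_slope, rng
        )
    else:
        branch2d, n2 = nn.Sequential([nn.Flatten()]), 0

    head_layers = []
    n_in = n3 + (n2 if config.use_depth_branch else 0)
    for units in config.dense_units:
        head_layers += [nn.Dense(n_in, units, rng), nn.LeakyReLU(config.leaky_slope)]
        n_in = units
    head_layers.append(nn.Dense(n_in, config.n_classes, rng))
    head = nn.Sequential(head_layers)
    net = nn.TwoBranchNet(branch3d, branch2d, head, n3, n2)
    if not config.use_depth_branch:
        # depth branch disabled: zero-length features from an empty flatten
        net._split = n3
    return TrainedModel(net=net, config=config)


def _split_inputs(cubes: np.ndarray, config: ModelConfig):
    """(n, 30, 30, 34) windows -> (3-D volume input, 2-D depth input)."""
    x3d = cubes[..., : config.n_bands, None].astype(np.float32, copy=False)
    if config.use_depth_branch:
        x2d = cubes[..., config.n_bands :].astype(np.float32, copy=False)
    else:
        x2d = np.zeros((cubes.shape[0], 0), dtype=np.float32)
    return x3d, x2d


def train(
    model: TrainedModel,
    train_set: SubCubeSet,
    val_set: SubCubeSet | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Train with Adam (default parameters) and categorical cross-entropy.

    Shuffling and updates are seeded by the model config; the same data and
    seed always give the same final weights.  History records per-epoch
    mean training loss and accuracy (and validation accuracy if given).
    """
    cfg = model.config
    labels = np.asarray(train_set.labels)
    if labels.min() < 0 or labels.max() >= cfg.n_classes:
        raise ValueError(
            f"labels must be in 0..{cfg.n_classes - 1}, got range "
            f"[{labels.min()}, {labels.max()}]"
        )
    net = model.net
    opt = nn.Adam(net, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(train_set)
    history = {"loss": [], "accuracy": [], "val_accuracy": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = _split_inputs(train_set.cubes[idx], cfg)
            yb = labels[idx]
            logits = net.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy_grad(logits, yb)
            net.backward(dlogits)
            opt.step()
            losses.append(loss * idx.size)
            hits += int((logits.argmax(axis=1) == yb).sum())
        history["loss"].append(float(np.sum(losses) / n))
        history["accuracy"].append(hits / n)
        if val_set is not None and len(val_set):
            vl, _ = predict_pixels(model, val_set)
            history["val_accuracy"].append(
                float((vl == np.asarray(val_set.labels)).mean())
            )
        if verbose:
            msg = (
                f"epoch {epoch + 1}/{cfg.epochs} loss {history['loss'][-1]:.4f} "
                f"acc {history['accuracy'][-1]:.3f}"
            )
            if history["val_accuracy"]:
                msg += f" val_acc {history['val_accuracy'][-1]:.3f}"
            print(msg)
    model.history = history
    return model


def predict_pixels(model: TrainedModel, sset: SubCubeSet, batch_size: int = 256):
    """Labels and 3-way probabilities for every cube in the set.

    Probabilities per cube sum to 1; the label is the argmax (numpy argmax
    breaks ties toward the lower class index).
    """
    cfg = model.config
    if sset.cubes.shape[1:] != (cfg.window, cfg.window, cfg.n_bands + 1):
        raise ValueError(
            f"cube shape {sset.cubes.shape[1:]} does not match model input "
            f"({cfg.window}, {cfg.window}, {cfg.n_bands + 1})"
        )
    probs = np.empty((len(sset), cfg.n_classes), dtype=np.float32)
    for start in range(0, len(sset), batch_size):
        xb = _split_inputs(sset.cubes[start : start + batch_size], cfg)
        probs[start : start + batch_size] = nn.softmax(model.net.forward(xb))
    return probs.argmax(axis=1), probs


def classify_image(model: TrainedModel, stack: FeatureStack, step: int = 5) -> PredictionMap:
    """Tile a whole feature stack and assemble class/confidence grids.

    The grid has floor((H - 30) / step) + 1 by floor((W - 30) / step) + 1
    sites; each carries the prediction for the window anchored there.
    """
    sset = extract_windows(stack, pixels=None, window=model.config.window, step=step)
    labels, probs = predict_pixels(model, sset)
    gh, gw = sset.grid_shape
    return PredictionMap(
        class_map=labels.reshape(gh, gw),
        confidence_maps=probs.reshape(gh, gw, model.config.n_classes),
        step=step,
    )
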