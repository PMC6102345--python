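"""VGG-style audio classification CNN and per-layer activation time series.

The network takes a 96 x 64 log-mel patch (960 ms of audio) and staggers
3 x 3 convolutions with non-overlapping 2 x 2 max pooling, doubling channel
counts 64 -> 128 -> 256 -> 512, followed by a 4096-unit fully connected
layer, a 128-unit embedding, and a 4923-way prediction layer.  Only six
layers are analyzed downstream (dimensionality permitting): Pool2, Pool3,
Conv4, Pool4, FC1 and Embed.

The analysis pipeline is weight-agnostic: it operates on the activations of
whatever network is supplied.  The default is a reproducible seeded random
(He-scaled Gaussian) initialization with zero biases; trained weights can be
dropped in from an ``.npz`` file whose array shapes are validated layer by
layer.

Forward passes run in float32 through im2col + matrix multiplication, so a
whole batch of analysis windows is a handful of BLAS calls per layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .features import MEL_HOP_S, N_MELS, compute_mel_spectrogram
from .scene import AudioScene

#: Network input patch: 96 mel frames (960 ms) x 64 bands.
INPUT_FRAMES = 96
INPUT_BANDS = N_MELS

#: The six analyzed layers, shallow to deep.
ANALYZED_LAYERS = ("Pool2", "Pool3", "Conv4", "Pool4", "FC1", "Embed")

#: Flattened output widths of the analyzed layers for a 96 x 64 input.
LAYER_WIDTHS = {
    "Pool2": 49_152,   # 24 x 16 x 128
    "Pool3": 24_576,   # 12 x 8 x 256
    "Conv4": 49_152,   # 12 x 8 x 512
    "Pool4": 12_288,   # 6 x 4 x 512
    "FC1": 4_096,
    "Embed": 128,
}

N_CLASSES = 4923

#: Layer name -> weight array shape (kernels are HWIO; FC are in x out).
_WEIGHT_SHAPES = {
    "Conv1": (3, 3, 1, 64),
    "Conv2": (3, 3, 64, 128),
    "Conv3": (3, 3, 128, 256),
    "Conv4": (3, 3, 256, 512),
    "FC1": (6 * 4 * 512, 4096),
    "Embed": (4096, 128),
    "Predict": (128, N_CLASSES),
}


@dataclass
class CNNConfig:
    """Weight source and seed for the fixed Table-style architecture."""

    weight_source: str = "seeded_random"  # or "file"
    seed: int = 0
    weight_file: str | None = None

    def __post_init__(self) -> None:
        if self.weight_source not in ("seeded_random", "file"):
            raise ValueError("weight_source must be 'seeded_random' or 'file'")
        if self.weight_source == "file" and not self.weight_file:
            raise ValueError("weight_source='file' requires weight_file")


@dataclass
class LayerActivationSeries:
    """Per-layer activation vectors over analysis windows.

    ``frames`` is time x flattened-units; ``times`` holds the window END
    time of each frame, so the activation at time t depends only on audio
    up to t.
    """

    layer_name: str
    frames: np.ndarray
    frame_rate: float
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.layer_name not in ANALYZED_LAYERS:
            raise ValueError(f"unknown layer {self.layer_name!r}")
        if self.frames.shape[1] != LAYER_WIDTHS[self.layer_name]:
            raise ValueError(
                f"{self.layer_name}: flattened width {self.frames.shape[1]} != "
                f"{LAYER_WIDTHS[self.layer_name]}")
        if self.times is None:
            self.times = np.arange(self.frames.shape[0]) / self.frame_rate


def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _conv2d_relu(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution + ReLU. x: (B,H,W,Cin), w: (3,3,Cin,Cout)."""
    b, h, wd, cin = x.shape
    cout = w.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    # patches: (B, H, W, Cin, 3, 3) -> (B*H*W, 3*3*Cin) matching w's (3,3,Cin) order
    v = sliding_window_view(xp, (3, 3), axis=(1, 2))
    v = v.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * wd, 9 * cin)
    out = v @ w.reshape(9 * cin, cout)
    np.maximum(out, 0.0, out=out)
    return out.reshape(b, h, wd, cout)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    b, h, w, c = x.shape
    return x.reshape(b, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


class AudioCNN:
    """The fixed-architecture network; holds weights and runs forward passes."""

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        if self.config.weight_source == "seeded_random":
            rng = np.random.default_rng(self.config.seed)
            self.weights = {name: _he_init(rng, shape)
                            for name, shape in _WEIGHT_SHAPES.items()}
        else:
            self.weights = self._load_weights(self.config.weight_file)
        self.biases = {name: np.zeros(shape[-1], dtype=np.float32)
                       for name, shape in _WEIGHT_SHAPES.items()}

    @staticmethod
    def _load_weights(path: str) -> dict[str, np.ndarray]:
        archive = np.load(path)
        weights = {}
        for name, shape in _WEIGHT_SHAPES.items():
            if name not in archive:
                raise ValueError(f"weight file missing array for layer {name}")
            arr = np.asarray(archive[name], dtype=np.float32)
            if arr.shape != shape:
                raise ValueError(
                    f"layer {name}: weight shape {arr.shape} != expected {shape}")
            weights[name] = arr
        return weights

    def forward(self, patches: np.ndarray, chunk: int = 16) -> dict[str, np.ndarray]:
        """Forward a batch of 96 x 64 input patches.

        Returns flattened activations of the six analyzed layers, each
        (batch, width).  Accepts a single patch (96, 64) or a batch
        (B, 96, 64).
        """
        x = np.asarray(patches, dtype=np.float32)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1:] != (INPUT_FRAMES, INPUT_BANDS):
            raise ValueError(
                f"input patches must be {INPUT_FRAMES} x {INPUT_BANDS}, got {x.shape[1:]}")
        outs = {name: [] for name in ANALYZED_LAYERS}
        for start in range(0, x.shape[0], chunk):
            part = self._forward_chunk(x[start:start + chunk])
            for name in ANALYZED_LAYERS:
                outs[name].append(part[name])
        result = {name: np.concatenate(v, axis=0) for name, v in outs.items()}
        if single:
            result = {name: v[0] for name, v in result.items()}
        return result

    def _forward_chunk(self, x: np.ndarray) -> dict[str, np.ndarray]:
        b = x.shape[0]
        w = self.weights
        h = x[..., None]                                   # (B, 96, 64, 1)
        h = _maxpool2(_conv2d_relu(h, w["Conv1"]))         # Pool1: 48 x 32 x 64
        h = _maxpool2(_conv2d_relu(h, w["Conv2"]))         # Pool2: 24 x 16 x 128
        pool2 = h.reshape(b, -1)
        h = _maxpool2(_conv2d_relu(h, w["Conv3"]))         # Pool3: 12 x 8 x 256
        pool3 = h.reshape(b, -1)
        h = _conv2d_relu(h, w["Conv4"])                    # Conv4: 12 x 8 x 512
        conv4 = h.reshape(b, -1)
        h = _maxpool2(h)                                   # Pool4: 6 x 4 x 512
        pool4 = h.reshape(b, -1)
        fc1 = np.maximum(pool4 @ w["FC1"] + self.biases["FC1"], 0.0)
        embed = np.maximum(fc1 @ w["Embed"] + self.biases["Embed"], 0.0)
        return {"Pool2": pool2, "Pool3": pool3, "Conv4": conv4,
                "Pool4": pool4, "FC1": fc1, "Embed": embed}

    def predict_logits(self, patches: np.ndarray) -> np.ndarray:
        """Raw prediction-layer outputs (width 4923); not used in analysis."""
        embed = self.forward(patches)["Embed"]
        embed = np.atleast_2d(embed)
        return embed @ self.weights["Predict"] + self.biases["Predict"]


def build_network(config: CNNConfig | None = None) -> AudioCNN:
    """Instantiate the network from a config (seeded random or weight file)."""
    return AudioCNN(config)


def activation_timeseries(network: AudioCNN, scene: AudioScene,
                          hop_s: float = 0.1) -> dict[str, LayerActivationSeries]:
    """Slide 960 ms windows over a scene and collect per-layer activations.

    The scene's mel spectrogram is computed once; the network is applied to
    each 96-frame patch advanced by ``hop_s``.  Frame timestamps are window
    END times.
    """
    mel = compute_mel_spectrogram(scene).values
    hop_frames = int(round(hop_s / MEL_HOP_S))
    if hop_frames < 1:
        raise ValueError("hop too small for the mel frame rate")
    if mel.shape[0] < INPUT_FRAMES:
        raise ValueError("scene shorter than one 960 ms analysis window")
    starts = np.arange(0, mel.shape[0] - INPUT_FRAMES + 1, hop_frames)
    patches = np.stack([mel[s:s + INPUT_FRAMES] for s in starts])
    acts = network.forward(patches)
    times = (starts + INPUT_FRAMES) * MEL_HOP_S
    rate = 1.0 / hop_s
    return {name: LayerActivationSeries(layer_name=name, frames=acts[name],
                                        frame_rate=rate, times=times)
            for name in ANALYZED_LAYERS}
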