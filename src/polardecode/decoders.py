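"""The six angle-regression decoders: three CNN families and LSTM hybrids.

ShallowConvNet, DeepConvNet and EEGNet follow their canonical published
layouts (temporal then spatial filtering; five stacked convolutions;
temporal + depthwise + separable blocks respectively), with the
classification softmax replaced by a single linear output unit for
regression.  Kernel and pooling lengths are expressed at the pipeline's
100 Hz window rate and are clamped (and logged) when the remaining time
axis is shorter than the canonical length.  Each family has a hybrid
variant in which the flatten/dense head is replaced by two stacked
64-unit LSTM layers reading the preserved time axis of the final
convolutional feature map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn

logger = logging.getLogger(__name__)

FAMILY_FILTERS = {"shallow": 40, "deep": 25, "eegnet": 8}


@dataclass
class DecoderSpec:
    """Architecture + hyperparameter description of one decoder."""

    family: str = "eegnet"
    use_lstm: bool = False
    first_layer_filters: int | None = None
    lstm_units: int = 64
    lstm_layers: int = 2
    dropout: float = 0.2
    input_shape: tuple[int, int] = (32, 100)  # channels x samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILY_FILTERS:
            raise ValueError(f"unknown decoder family {self.family!r}; "
                             f"choose from {sorted(FAMILY_FILTERS)}")
        if self.first_layer_filters is None:
            self.first_layer_filters = FAMILY_FILTERS[self.family]

    @property
    def name(self) -> str:
        return self.family + ("_lstm" if self.use_lstm else "")

    def to_json(self) -> str:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        return json.dumps(d)

    @classmethod
    def from_json(cls, payload: str) -> "DecoderSpec":
        d = json.loads(payload)
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


class AsFeatureMap(nn.Layer):
    """(B, channels, samples) -> (B, channels, samples, 1)."""

    def forward(self, x, training=False):
        return np.asarray(x, dtype=nn.DTYPE)[..., None]

    def backward(self, grad):
        return grad[..., 0]


def _clamp(k: int, available: int, what: str) -> int:
    if k > available:
        logger.info("%s length %d clamped to %d (input too short)", what, k, available)
        return max(1, available)
    return k


def _shallow_stack(spec: DecoderSpec) -> tuple[list[nn.Layer], tuple[int, int, int]]:
    n_ch, n_t = spec.input_shape
    f = spec.first_layer_filters
    k_time = _clamp(10, n_t, "shallow temporal kernel")     # 0.1 s at 100 Hz
    w = n_t - k_time + 1
    pool = _clamp(30, w, "shallow pooling")                 # 0.3 s
    stride = 6                                              # 0.06 s
    layers: list[nn.Layer] = [
        AsFeatureMap(),
        nn.Conv2d(1, f, (1, k_time)),
        nn.Conv2d(f, f, (n_ch, 1), bias=False),
        nn.BatchNorm(f),
        nn.Square(),
        nn.AvgPoolW(pool, stride),
        nn.SafeLog(),
        nn.Dropout(spec.dropout),
    ]
    w_out = (w - pool) // stride + 1
    return layers, (1, w_out, f)


def _deep_stack(spec: DecoderSpec) -> tuple[list[nn.Layer], tuple[int, int, int]]:
    n_ch, n_t = spec.input_shape
    f = spec.first_layer_filters
    layers: list[nn.Layer] = [AsFeatureMap()]
    w = n_t
    k = _clamp(5, w, "deep temporal kernel")
    layers += [nn.Conv2d(1, f, (1, k)),
               nn.Conv2d(f, f, (n_ch, 1), bias=False),
               nn.BatchNorm(f), nn.ELU(), nn.MaxPoolW(2)]
    w = (w - k + 1) // 2
    filters = f
    for mult in (2, 4, 8):
        nxt = spec.first_layer_filters * mult
        k = _clamp(5, w, "deep temporal kernel")
        layers += [nn.Dropout(spec.dropout),
                   nn.Conv2d(filters, nxt, (1, k)),
                   nn.BatchNorm(nxt), nn.ELU(), nn.MaxPoolW(2)]
        w = (w - k + 1) // 2
        filters = nxt
    return layers, (1, w, filters)


def _eegnet_stack(spec: DecoderSpec) -> tuple[list[nn.Layer], tuple[int, int, int]]:
    n_ch, n_t = spec.input_shape
    f = spec.first_layer_filters
    depth_mult = 2
    k_temp = _clamp(50, n_t, "eegnet temporal kernel")      # half the rate
    # temporal + depthwise-spatial stage fused into one exact-equivalent
    # layer (the batch norm between them is provably inert; see nn docs)
    layers: list[nn.Layer] = [
        nn.FusedTemporalSpatial(n_ch, f, depth_mult, k_temp),
        nn.BatchNorm(f * depth_mult),
        nn.ELU(),
        nn.AvgPoolW(4),
        nn.Dropout(spec.dropout),
    ]
    w = n_t // 4
    k_sep = _clamp(16, w, "eegnet separable kernel")
    layers += [
        nn.DepthwiseConv2d(f * depth_mult, 1, (1, k_sep), padding="same"),
        nn.Conv2d(f * depth_mult, f * depth_mult, (1, 1), bias=False),
        nn.BatchNorm(f * depth_mult),
        nn.ELU(),
        nn.AvgPoolW(8),
        nn.Dropout(spec.dropout),
    ]
    w = w // 8
    return layers, (1, w, f * depth_mult)


_STACKS = {"shallow": _shallow_stack, "deep": _deep_stack, "eegnet": _eegnet_stack}


def attach_lstm(conv_layers: list[nn.Layer], out_shape: tuple[int, int, int],
                spec: DecoderSpec) -> list[nn.Layer]:
    """Replace the flatten/dense head with two stacked LSTM layers.

    The final feature map's time axis (width) becomes the sequence axis;
    all remaining spatial/filter dimensions are flattened per step.  The
    first LSTM returns its full sequence, the second only its final
    state, which feeds the linear output unit.
    """
    h, w, c = out_shape
    if w < 2:
        raise ValueError(
            f"temporal axis collapsed to length {w} before the LSTM head; "
            "reduce pooling in the convolutional stack"
        )
    feat = h * c
    layers = list(conv_layers) + [nn.ToSequence()]
    in_f = feat
    for i in range(spec.lstm_layers):
        last = i == spec.lstm_layers - 1
        layers.append(nn.LSTM(in_f, spec.lstm_units, return_sequences=not last))
        if not last:
            layers.append(nn.Dropout(spec.dropout))
        in_f = spec.lstm_units
    layers.append(nn.Dense(spec.lstm_units, 1))
    return layers


def build_decoder(spec: DecoderSpec) -> nn.Sequential:
    """Construct one of the six decoders as an untrained model."""
    stack_fn = _STACKS[spec.family]
    conv_layers, out_shape = stack_fn(spec)
    if spec.use_lstm:
        layers = attach_lstm(conv_layers, out_shape, spec)
    else:
        h, w, c = out_shape
        layers = conv_layers + [nn.Flatten(), nn.Dense(h * w * c, 1)]
    return nn.Sequential(layers, seed=spec.seed)


def conv_output_shape(spec: DecoderSpec) -> tuple[int, int, int]:
    """(height, width, features) of the final convolutional feature map."""
    return _STACKS[spec.family](spec)[1]


def all_specs(use_lstm_variants: bool = True, **overrides) -> list[DecoderSpec]:
    """The six standard decoder specifications."""
    specs = []
    for family in ("eegnet", "deep", "shallow"):
        specs.append(DecoderSpec(family=family, use_lstm=False, **overrides))
        if use_lstm_variants:
            specs.append(DecoderSpec(family=family, use_lstm=True, **overrides))
    return specs
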