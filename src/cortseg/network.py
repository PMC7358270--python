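"""The 3-level valid-padding 3D U-Net ("3D U-Net minus").

The architecture is declared by :class:`UNetMinusSpec`, from which everything
else is derived: the per-layer shape trace (:func:`trace_shapes`), the spatial
context of one output voxel (:func:`receptive_field`), the exact trainable
parameter count (:func:`count_parameters`) and the runnable numpy model
(:func:`build_model`).

Design of the default spec
--------------------------
The analysis path applies five unpadded 3x3x3 convolutions (32, 64, 64, 128,
128 filters), with 2x2x2 max pooling after the second and fourth; the fifth
conv plus a 128->256 expansion form the bottleneck.  The synthesis path uses
2x2x2 stride-2 transposed convolutions that HALVE channels (256->128,
128->64), so that after concatenating the center-cropped encoder features the
channel count equals the paired encoder stage; two unpadded convs follow each
up-sampling, and a final 1x1x1 projection yields single-channel lesion logits
(sigmoid probability of "any lesion").  No normalization layers are used, only
ReLU activations.  Because every convolution is valid, an 88^3 input shrinks
to a 48^3 output: the margin is a constant 40 voxels for any feasible input.

With these choices the network has 3,703,777 trainable parameters
(weights + biases), under a 3.8 M budget; channel-preserving up-convolutions
would exceed it.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Tuple

import numpy as np
import yaml

from . import _nn

#: input side minus output side, constant for every feasible input.
MARGIN = 40

#: smallest input side that keeps every intermediate side >= 1.
MIN_INPUT_SIDE = 44


class InfeasibleInputError(ValueError):
    """Input side incompatible with the valid-padding layer arithmetic."""


@dataclasses.dataclass(frozen=True)
class UNetMinusSpec:
    """Declarative description of the 3-level valid-padding 3D U-Net.

    ``encoder_filters`` are the five analysis-path convolutions in order
    (the fifth being the bottleneck's first conv); ``bottleneck_expand`` is
    the bottleneck's second conv; ``decoder_filters`` are the four
    synthesis-path convolutions; the final layer is a 1x1x1 projection to
    ``out_channels``.
    """

    in_channels: int = 2
    resolution_levels: int = 3
    encoder_filters: Tuple[int, ...] = (32, 64, 64, 128, 128)
    bottleneck_expand: int = 256
    decoder_filters: Tuple[int, ...] = (128, 128, 64, 64)
    out_channels: int = 1
    conv_kernel: int = 3
    pool: int = 2
    upconv_kernel: int = 2

    def __post_init__(self):
        if len(self.encoder_filters) != 5 or len(self.decoder_filters) != 4:
            raise ValueError("expected 5 encoder and 4 decoder convolution widths")
        if self.resolution_levels != 3:
            raise ValueError("this architecture family has exactly 3 resolution levels")

    def scaled(self, factor: int) -> "UNetMinusSpec":
        """Return a copy with every filter count divided by ``factor``.

        Used for desk-scale experiments; the layer geometry (and hence the
        shape arithmetic and receptive field) is unchanged.
        """
        return dataclasses.replace(
            self,
            encoder_filters=tuple(max(1, f // factor) for f in self.encoder_filters),
            bottleneck_expand=max(1, self.bottleneck_expand // factor),
            decoder_filters=tuple(max(1, f // factor) for f in self.decoder_filters),
        )

    def layer_plan(self) -> List[Tuple[str, str, int, int, int]]:
        """Ordered parametrized layers as (name, kind, c_in, c_out, kernel)."""
        f1, f2, f3, f4, f5 = self.encoder_filters
        b = self.bottleneck_expand
        d1, d2, d3, d4 = self.decoder_filters
        k = self.conv_kernel
        u = self.upconv_kernel
        return [
            ("enc1", "conv", self.in_channels, f1, k),
            ("enc2", "conv", f1, f2, k),
            ("enc3", "conv", f2, f3, k),
            ("enc4", "conv", f3, f4, k),
            ("enc5", "conv", f4, f5, k),
            ("bott", "conv", f5, b, k),
            ("up1", "upconv", b, d1, u),
            ("dec1", "conv", d1 + f4, d1, k),
            ("dec2", "conv", d1, d2, k),
            ("up2", "upconv", d2, d3, u),
            ("dec3", "conv", d3 + f2, d3, k),
            ("dec4", "conv", d3, d4, k),
            ("out", "conv", d4, self.out_channels, 1),
        ]

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["encoder_filters"] = list(d["encoder_filters"])
        d["decoder_filters"] = list(d["decoder_filters"])
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "UNetMinusSpec":
        d = yaml.safe_load(text)
        d["encoder_filters"] = tuple(d["encoder_filters"])
        d["decoder_filters"] = tuple(d["decoder_filters"])
        return cls(**d)


@dataclasses.dataclass
class ShapeTrace:
    """Per-layer spatial bookkeeping for one input side length.

    ``records`` holds (layer name, input side, output side, output channels)
    for every layer, pooling and up-sampling included.
    """

    records: List[Tuple[str, int, int, int]]
    input_side: int
    output_side: int

    def __str__(self):
        lines = [f"{'layer':<8}{'in':>6}{'out':>6}{'ch':>6}"]
        for name, si, so, ch in self.records:
            lines.append(f"{name:<8}{si:>6}{so:>6}{ch:>6}")
        lines.append(f"input {self.input_side} -> output {self.output_side}")
        return "\n".join(lines)


def trace_shapes(spec: UNetMinusSpec, input_side: int) -> ShapeTrace:
    """Propagate a cubic input side through every layer.

    Raises :class:`InfeasibleInputError` naming the failing layer if a side
    entering a pooling layer is odd or any side would drop below 1.
    Feasible sides are exactly the multiples of 4 that are >= 44.
    """
    f1, f2, f3, f4, f5 = spec.encoder_filters
    b = spec.bottleneck_expand
    d1, d2, d3, d4 = spec.decoder_filters
    shrink = spec.conv_kernel - 1

    records = []
    s = int(input_side)

    def conv(name, ch, delta=shrink):
        nonlocal s
        out = s - delta
        if out < 1:
            raise InfeasibleInputError(f"side {s} too small at layer {name}")
        records.append((name, s, out, ch))
        s = out

    def pool(name, ch):
        nonlocal s
        if s % 2:
            raise InfeasibleInputError(f"odd side {s} at pooling layer {name}")
        records.append((name, s, s // 2, ch))
        s //= 2

    def up(name, ch):
        nonlocal s
        records.append((name, s, s * 2, ch))
        s *= 2

    conv("enc1", f1)
    conv("enc2", f2)
    pool("pool1", f2)
    conv("enc3", f3)
    conv("enc4", f4)
    pool("pool2", f4)
    conv("enc5", f5)
    conv("bott", b)
    up("up1", d1)
    conv("dec1", d1)
    conv("dec2", d2)
    up("up2", d3)
    conv("dec3", d3)
    conv("dec4", d4)
    conv("out", spec.out_channels, delta=0)
    return ShapeTrace(records=records, input_side=int(input_side), output_side=s)


def feasible_input_sides(lo: int, hi: int) -> List[int]:
    """All input sides in [lo, hi] accepted by :func:`trace_shapes`."""
    out = []
    for s in range(lo, hi + 1):
        try:
            trace_shapes(UNetMinusSpec(), s)
        except InfeasibleInputError:
            continue
        out.append(s)
    return out


def min_input_side_for(max_dim: int) -> int:
    """Smallest feasible input side whose output covers ``max_dim`` voxels."""
    s = max(MIN_INPUT_SIDE, max_dim + MARGIN)
    while True:
        try:
            trace_shapes(UNetMinusSpec(), s)
            return s
        except InfeasibleInputError:
            s += 1


def receptive_field(spec: UNetMinusSpec) -> int:
    """Side length of the input region influencing one output voxel.

    The network's pooling stages are exactly compensated by its up-sampling
    stages, so it is an overall stride-1, translation-equivariant map and
    every output voxel depends on a contiguous input window of fixed width:
    input_side = output_side - 1 + rf, i.e. rf = input_side - output_side + 1.
    (Naive additive layer-by-layer accounting overestimates this, because a
    stride-2 transposed convolution grows dependency windows sub-additively.)
    The identity is evaluated from the layer-by-layer trace and cross-checked
    at a second, independent input side.
    """
    sides = [MIN_INPUT_SIDE, MIN_INPUT_SIDE + 8]
    rfs = []
    for s in sides:
        tr = trace_shapes(spec, s)
        rfs.append(tr.input_side - tr.output_side + 1)
    if rfs[0] != rfs[1]:
        raise AssertionError(f"receptive field not constant across inputs: {rfs}")
    return rfs[0]


def count_parameters(spec: UNetMinusSpec) -> int:
    """Total trainable parameters: sum of (kernel_volume * c_in + 1) * c_out."""
    total = 0
    for _name, _kind, ci, co, k in spec.layer_plan():
        total += (k ** 3 * ci + 1) * co
    return total


class UNet3D:
    """Runnable numpy instantiation of a :class:`UNetMinusSpec`.

    Operates on a single sample (channels-first, no batch axis); the training
    loop iterates over the batch.  ``forward`` accepts any feasible cubic
    input side and returns logits of side ``input_side - 40``.
    """

    def __init__(self, spec: UNetMinusSpec, init_seed: int = 0):
        self.spec = spec
        self.init_seed = int(init_seed)
        rng = np.random.default_rng(np.random.SeedSequence(self.init_seed))
        self.params = {}
        for name, kind, ci, co, k in spec.layer_plan():
            fan_in = ci * k ** 3
            bound = np.sqrt(6.0 / fan_in)  # He-uniform, fan-in
            if kind == "conv":
                shape = (co, ci, k, k, k)
            else:  # upconv
                shape = (ci, co, k, k, k)
            self.params[name + "_w"] = rng.uniform(-bound, bound, size=shape).astype(np.float32)
            self.params[name + "_b"] = np.zeros(co, dtype=np.float32)

    # -- parameter bookkeeping -------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def state_copy(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k in self.params:
            self.params[k][...] = state[k]

    def astype(self, dtype) -> "UNet3D":
        """Cast all parameters in place (float64 for gradient verification)."""
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)
        return self

    def kernel_names(self) -> List[str]:
        """Names of convolution-kernel parameters (L2 applies to these only)."""
        return [k for k in self.params if k.endswith("_w")]

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, cache: Optional[dict] = None) -> np.ndarray:
        """Map a (in_channels, s, s, s) patch to (out_channels, s-40, ...) logits."""
        trace_shapes(self.spec, x.shape[1])  # raises if infeasible
        p = self.params
        c = cache if cache is not None else None

        def keep(**kw):
            if c is not None:
                c.update(kw)

        x = np.ascontiguousarray(x, dtype=self.params["enc1_w"].dtype)
        e1a = _nn.relu(_nn.conv3d(x, p["enc1_w"], p["enc1_b"]))
        e1b = _nn.relu(_nn.conv3d(e1a, p["enc2_w"], p["enc2_b"]))
        p1, i1 = _nn.maxpool2(e1b)
        e2a = _nn.relu(_nn.conv3d(p1, p["enc3_w"], p["enc3_b"]))
        e2b = _nn.relu(_nn.conv3d(e2a, p["enc4_w"], p["enc4_b"]))
        p2, i2 = _nn.maxpool2(e2b)
        b1 = _nn.relu(_nn.conv3d(p2, p["enc5_w"], p["enc5_b"]))
        b2 = _nn.relu(_nn.conv3d(b1, p["bott_w"], p["bott_b"]))
        u1 = _nn.relu(_nn.upconv2(b2, p["up1_w"], p["up1_b"]))
        s1 = _nn.center_crop(e2b, u1.shape[1])
        cat1 = np.concatenate([u1, s1], axis=0)
        d1a = _nn.relu(_nn.conv3d(cat1, p["dec1_w"], p["dec1_b"]))
        d1b = _nn.relu(_nn.conv3d(d1a, p["dec2_w"], p["dec2_b"]))
        u2 = _nn.relu(_nn.upconv2(d1b, p["up2_w"], p["up2_b"]))
        s2 = _nn.center_crop(e1b, u2.shape[1])
        cat2 = np.concatenate([u2, s2], axis=0)
        d2a = _nn.relu(_nn.conv3d(cat2, p["dec3_w"], p["dec3_b"]))
        d2b = _nn.relu(_nn.conv3d(d2a, p["dec4_w"], p["dec4_b"]))
        logits = _nn.conv3d(d2b, p["out_w"], p["out_b"])  # no activation
        keep(x=x, e1a=e1a, e1b=e1b, p1=p1, i1=i1, e2a=e2a, e2b=e2b, p2=p2, i2=i2,
             b1=b1, b2=b2, u1=u1, cat1=cat1, d1a=d1a, d1b=d1b, u2=u2, cat2=cat2,
             d2a=d2a, d2b=d2b)
        return logits

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict:
        """Backpropagate; returns gradients keyed like ``self.params``."""
        p = self.params
        c = cache
        g = {}

        dd2b, g["out_w"], g["out_b"] = _nn.conv3d_backward(c["d2b"], p["out_w"], dlogits)
        dd2b = _nn.relu_backward(dd2b, c["d2b"])
        dd2a, g["dec4_w"], g["dec4_b"] = _nn.conv3d_backward(c["d2a"], p["dec4_w"], dd2b)
        dd2a = _nn.relu_backward(dd2a, c["d2a"])
        dcat2, g["dec3_w"], g["dec3_b"] = _nn.conv3d_backward(c["cat2"], p["dec3_w"], dd2a)
        n_u2 = c["u2"].shape[0]
        du2 = _nn.relu_backward(dcat2[:n_u2], c["u2"])
        ds2 = dcat2[n_u2:]
        dd1b, g["up2_w"], g["up2_b"] = _nn.upconv2_backward(c["d1b"], p["up2_w"], du2)
        dd1b = _nn.relu_backward(dd1b, c["d1b"])
        dd1a, g["dec2_w"], g["dec2_b"] = _nn.conv3d_backward(c["d1a"], p["dec2_w"], dd1b)
        dd1a = _nn.relu_backward(dd1a, c["d1a"])
        dcat1, g["dec1_w"], g["dec1_b"] = _nn.conv3d_backward(c["cat1"], p["dec1_w"], dd1a)
        n_u1 = c["u1"].shape[0]
        du1 = _nn.relu_backward(dcat1[:n_u1], c["u1"])
        ds1 = dcat1[n_u1:]
        db2, g["up1_w"], g["up1_b"] = _nn.upconv2_backward(c["b2"], p["up1_w"], du1)
        db2 = _nn.relu_backward(db2, c["b2"])
        db1, g["bott_w"], g["bott_b"] = _nn.conv3d_backward(c["b1"], p["bott_w"], db2)
        db1 = _nn.relu_backward(db1, c["b1"])
        dp2, g["enc5_w"], g["enc5_b"] = _nn.conv3d_backward(c["p2"], p["enc5_w"], db1)
        de2b = _nn.maxpool2_backward(dp2, c["i2"], c["e2b"].shape)
        de2b = _add_center(de2b, ds1)
        de2b = _nn.relu_backward(de2b, c["e2b"])
        de2a, g["enc4_w"], g["enc4_b"] = _nn.conv3d_backward(c["e2a"], p["enc4_w"], de2b)
        de2a = _nn.relu_backward(de2a, c["e2a"])
        dp1, g["enc3_w"], g["enc3_b"] = _nn.conv3d_backward(c["p1"], p["enc3_w"], de2a)
        de1b = _nn.maxpool2_backward(dp1, c["i1"], c["e1b"].shape)
        de1b = _add_center(de1b, ds2)
        de1b = _nn.relu_backward(de1b, c["e1b"])
        de1a, g["enc2_w"], g["enc2_b"] = _nn.conv3d_backward(c["e1a"], p["enc2_w"], de1b)
        de1a = _nn.relu_backward(de1a, c["e1a"])
        _, g["enc1_w"], g["enc1_b"] = _nn.conv3d_backward(c["x"], p["enc1_w"], de1a)
        return g

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, spec_yaml=np.array(self.spec.to_yaml()),
                 init_seed=np.array(self.init_seed), **self.params)

    @classmethod
    def load(cls, path) -> "UNet3D":
        with np.load(path, allow_pickle=False) as z:
            spec = UNetMinusSpec.from_yaml(str(z["spec_yaml"]))
            model = cls(spec, init_seed=int(z["init_seed"]))
            for k in model.params:
                model.params[k][...] = z[k]
        return model


def _add_center(big: np.ndarray, grad_crop: np.ndarray) -> np.ndarray:
    """Accumulate a skip-connection gradient back into the cropped region."""
    s, t = big.shape[1], grad_crop.shape[1]
    m = (s - t) // 2
    if m == 0:
        big += grad_crop
    else:
        big[:, m:s - m, m:s - m, m:s - m] += grad_crop
    return big


def build_model(spec: UNetMinusSpec, init_seed: int = 0) -> UNet3D:
    """Instantiate the network with seeded He-uniform weights.

    The built model's trainable-parameter count always equals
    :func:`count_parameters` of its spec (asserted here).
    """
    model = UNet3D(spec, init_seed=init_seed)
    expected = count_parameters(spec)
    if model.n_parameters != expected:
        raise AssertionError(
            f"built model has {model.n_parameters} parameters, spec counts {expected}")
    return model
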