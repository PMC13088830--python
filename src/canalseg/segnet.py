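"""Nested-U segmentation network on 2D axial slices.

The architecture is a two-level U: an outer encoder–decoder whose every
stage is itself a small residual U-block (RSU). An RSU of height ``h``
downsamples ``h - 1`` times internally, applies a dilated bottom
convolution, and decodes back with skip concatenations, adding the result
to a 1-conv projection of its input. The deepest outer stages use a
dilation-only RSU variant (no pooling) so receptive fields grow without
losing resolution. Each decoder stage (and the bridge) emits a side
probability map; side maps are upsampled to full resolution and fused by a
1x1 convolution into the final output. Training supervises the fused map
and every side map (deep supervision).

Two presets are provided: ``tiny`` (3 outer stages, < 1e6 parameters, the
configuration every test and experiment here runs) and ``full`` (6 outer
stages with the published channel schedule of the original salient-object
network). Both expose the same interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .volume import Volume3D

__all__ = ["NetConfig", "SegModel", "build_model", "predict_volume",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetConfig:
    """Structural description of a nested-U network.

    ``stages`` lists the outer encoder stages top-down as tuples
    ``(rsu_height, c_in, c_mid, c_out)``; a height of 0 denotes the
    dilation-only RSU variant. The decoder mirrors the encoder. The final
    entry acts as the bridge (deepest stage).
    """

    variant: str = "tiny"
    in_channels: int = 1
    out_channels: int = 1
    stages: tuple = ()
    side_supervision: bool = True

    @staticmethod
    def tiny() -> "NetConfig":
        return NetConfig(
            variant="tiny",
            stages=(
                (3, 1, 4, 8),
                (3, 8, 8, 16),
                (0, 16, 8, 16),  # bridge, dilation-only
            ),
        )

    @staticmethod
    def full() -> "NetConfig":
        return NetConfig(
            variant="full",
            stages=(
                (7, 1, 32, 64),
                (6, 64, 32, 128),
                (5, 128, 64, 256),
                (4, 256, 128, 512),
                (0, 512, 256, 512),
                (0, 512, 256, 512),  # bridge
            ),
        )

    def validate(self) -> None:
        if len(self.stages) < 3:
            raise ValueError("nested-U needs at least 3 outer stages")
        for h, cin, cmid, cout in self.stages:
            if min(cin, cmid, cout) < 1:
                raise ValueError("channel widths must be positive")
            if h != 0 and h < 2:
                raise ValueError("RSU height must be 0 (dilated variant) or >= 2")

    @property
    def divisor(self) -> int:
        """Slice extents must be divisible by this (outer + inner pooling)."""
        self.validate()
        worst = 1
        for level, (h, *_rest) in enumerate(self.stages):
            inner = 2 ** max(h - 2, 0) if h else 1
            worst = max(worst, 2**level * inner)
        # decoder mirrors encoder; the bridge sits at level len-1
        return worst


class _RSU:
    """Residual U-block: pool-based inner U of the given height."""

    def __init__(self, height, cin, cmid, cout, rng):
        self.height = height
        self.convin = nn.ConvBlock(cin, cout, rng=rng)
        self.enc = [nn.ConvBlock(cout, cmid, rng=rng)]
        self.enc += [nn.ConvBlock(cmid, cmid, rng=rng) for _ in range(height - 2)]
        self.pools = [nn.MaxPool2() for _ in range(height - 2)]
        self.bottom = nn.ConvBlock(cmid, cmid, dilation=2, rng=rng)
        self.dec = [nn.ConvBlock(2 * cmid, cmid, rng=rng) for _ in range(height - 2)]
        self.decfinal = nn.ConvBlock(2 * cmid, cout, rng=rng)
        self.ups = [nn.Up2() for _ in range(height - 2)]
        self.cmid = cmid

    def params(self):
        ps = self.convin.params() + self.bottom.params() + self.decfinal.params()
        for m in self.enc + self.dec:
            ps += m.params()
        return ps

    def forward(self, x):
        xin = self.convin.forward(x)
        e = [self.enc[0].forward(xin)]
        for i in range(1, self.height - 1):
            e.append(self.enc[i].forward(self.pools[i - 1].forward(e[-1])))
        h = self.bottom.forward(e[-1])
        for i in range(self.height - 2, 0, -1):
            h = self.dec[i - 1].forward(np.concatenate([h, e[i]], axis=1))
            h = self.ups[i - 1].forward(h)
        out = self.decfinal.forward(np.concatenate([h, e[0]], axis=1))
        return out + xin

    def run_backward(self, gy):
        H = self.height
        g_xin_res = gy  # residual branch
        g = self.decfinal.backward(gy)
        g_h = g[:, : self.cmid]
        g_e = [None] * (H - 1)
        g_e[0] = g[:, self.cmid:]
        for i in range(1, H - 1):
            # iterate decoder levels from shallow (1) to deep (H-2)
            g_h = self.ups[i - 1].backward(g_h)
            g = self.dec[i - 1].backward(g_h)
            g_h = g[:, : self.cmid]
            g_e[i] = g[:, self.cmid:]
        g_e[H - 2] = g_e[H - 2] + self.bottom.backward(g_h)
        # encoder chain, deepest first
        g_prev = None
        for i in range(H - 2, 0, -1):
            gi = g_e[i] if g_prev is None else g_e[i] + g_prev
            g_prev = self.pools[i - 1].backward(self.enc[i].backward(gi))
        g0 = g_e[0] if g_prev is None else g_e[0] + g_prev
        g_xin = self.enc[0].backward(g0) + g_xin_res
        return self.convin.backward(g_xin)


class _RSUF:
    """Dilation-only residual U-block (no pooling; dilations 1, 2, 4, back)."""

    def __init__(self, cin, cmid, cout, rng):
        self.convin = nn.ConvBlock(cin, cout, rng=rng)
        self.e1 = nn.ConvBlock(cout, cmid, dilation=1, rng=rng)
        self.e2 = nn.ConvBlock(cmid, cmid, dilation=2, rng=rng)
        self.e3 = nn.ConvBlock(cmid, cmid, dilation=4, rng=rng)
        self.d2 = nn.ConvBlock(2 * cmid, cmid, dilation=2, rng=rng)
        self.d1 = nn.ConvBlock(2 * cmid, cout, dilation=1, rng=rng)
        self.cmid = cmid

    def params(self):
        ps = []
        for m in (self.convin, self.e1, self.e2, self.e3, self.d2, self.d1):
            ps += m.params()
        return ps

    def forward(self, x):
        xin = self.convin.forward(x)
        h1 = self.e1.forward(xin)
        h2 = self.e2.forward(h1)
        h3 = self.e3.forward(h2)
        hd2 = self.d2.forward(np.concatenate([h3, h2], axis=1))
        out = self.d1.forward(np.concatenate([hd2, h1], axis=1))
        return out + xin

    def run_backward(self, gy):
        g = self.d1.backward(gy)
        g_hd2, g_h1 = g[:, : self.cmid], g[:, self.cmid:]
        g = self.d2.backward(g_hd2)
        g_h3, g_h2 = g[:, : self.cmid], g[:, self.cmid:]
        g_h2 = g_h2 + self.e3.backward(g_h3)
        g_h1 = g_h1 + self.e2.backward(g_h2)
        g_xin = self.e1.backward(g_h1) + gy
        return self.convin.backward(g_xin)


class _NestedU:
    """Outer encoder–decoder of residual U-blocks with deep supervision."""

    def __init__(self, config: NetConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        st = config.stages
        n = len(st)

        def make(spec):
            h, cin, cmid, cout = spec
            if h == 0:
                return _RSUF(cin, cmid, cout, rng)
            return _RSU(h, cin, cmid, cout, rng)

        self.encoders = [make(s) for s in st]
        self.pools = [nn.MaxPool2() for _ in range(n - 1)]
        # decoder stage i (for i = n-2 .. 0) consumes cat(up(deeper), enc_i out)
        self.decoders = []
        self.ups = []
        for i in range(n - 2, -1, -1):
            h_i, _, cmid_i, cout_i = st[i]
            deeper_channels = st[i + 1][3] if i == n - 2 else self._dec_out(i + 1)
            cin = st[i][3] + deeper_channels
            self.decoders.append(make((h_i, cin, cmid_i, cout_i)))
            self.ups.append(nn.Up2())
        self.decoders = self.decoders[::-1]  # index by level i
        self.ups = self.ups[::-1]
        # side heads: bridge + every decoder level
        self.side = [nn.Conv2d(st[-1][3], 1, 3, rng=rng)]
        self.side += [nn.Conv2d(self._dec_out(i), 1, 3, rng=rng) for i in range(n - 1)]
        self.fuse = nn.Conv2d(len(self.side), 1, 1, rng=rng)
        self.n = n

    def _dec_out(self, i):
        return self.config.stages[i][3]

    def params(self):
        ps = []
        for m in self.encoders + self.decoders + self.side + [self.fuse]:
            ps += m.params()
        return ps

    def forward(self, x):
        n = self.n
        e = []
        h = x
        for i, enc in enumerate(self.encoders):
            h = enc.forward(h)
            e.append(h)
            if i < n - 1:
                h = self.pools[i].forward(h)
        # e[n-1] is the bridge output at level n-1
        d = [None] * (n - 1)
        h = e[n - 1]
        for i in range(n - 2, -1, -1):
            h = self.ups[i].forward(h)
            h = self.decoders[i].forward(np.concatenate([h, e[i]], axis=1))
            d[i] = h
        logits = []
        s = self.side[0].forward(e[n - 1])
        logits.append(nn.upsample_to(s, 2 ** (n - 1)))
        for i in range(n - 1):
            s = self.side[i + 1].forward(d[i])
            logits.append(nn.upsample_to(s, 2**i))
        fused = self.fuse.forward(np.concatenate(logits, axis=1))
        return fused, logits

    def run_backward(self, g_fused, g_sides):
        n = self.n
        g_cat = self.fuse.backward(g_fused)
        g_logits = [g_cat[:, i : i + 1] + g_sides[i] for i in range(len(self.side))]
        # route side gradients back through their upsampling + side convs
        g_bridge_extra = self.side[0].backward(
            nn.downsum_from(g_logits[0], 2 ** (n - 1))
        )
        g_d = [self.side[i + 1].backward(nn.downsum_from(g_logits[i + 1], 2**i))
               for i in range(n - 1)]
        # decoder chain: level 0 is last computed, so start there
        g_e = [None] * n
        g_up = None
        for i in range(0, n - 1):
            gi = g_d[i] if g_up is None else g_d[i] + g_up
            g = self.decoders[i].run_backward(gi)
            cdeep = g.shape[1] - self.config.stages[i][3]
            g_deep, g_skip = g[:, :cdeep], g[:, cdeep:]
            g_e[i] = g_skip
            g_up = self.ups[i].backward(g_deep)
        g_e[n - 1] = g_up + g_bridge_extra
        # encoder chain, deepest first
        g_next = None
        for i in range(n - 1, -1, -1):
            gi = g_e[i] if g_next is None else g_e[i] + g_next
            g_in = self.encoders[i].run_backward(gi)
            g_next = self.pools[i - 1].backward(g_in) if i > 0 else g_in
        return g_next


class SegModel:
    """A nested-U network plus the config that built it (checkpointable)."""

    def __init__(self, config: NetConfig, seed: int = 0):
        config.validate()
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.net = _NestedU(config, rng)

    def params(self):
        return self.net.params()

    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def forward(self, slices: np.ndarray):
        """Logits for a batch of slices (N, 1, H, W) -> (fused, side list)."""
        return self.net.forward(slices.astype(np.float32))

    def predict_slices(self, slices: np.ndarray) -> np.ndarray:
        """Fused probability maps in [0, 1] for a batch of slices."""
        fused, _ = self.forward(slices)
        return nn.sigmoid(fused)

    def state_arrays(self):
        return [p.v for p in self.params()]

    def load_state_arrays(self, arrays):
        own = self.params()
        if len(arrays) != len(own):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(own, arrays):
            if p.v.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.v[...] = a


def build_model(config: NetConfig, seed: int = 0) -> SegModel:
    """Construct a seeded nested-U model from a config."""
    return SegModel(config, seed)


def predict_volume(model: SegModel, vol: Volume3D, batch: int = 8) -> Volume3D:
    """Slice-wise probability prediction on a whole volume.

    The volume is min–max normalized to [0, 1] (flat volumes map to 0),
    each axial slice is padded to the network's divisibility requirement,
    passed through the network independently, and the fused sigmoid output
    is cropped back onto the input grid.
    """
    data = vol.data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    norm = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    nz, ny, nx = norm.shape
    div = model.config.divisor
    py = (-ny) % div
    px = (-nx) % div
    padded = np.pad(norm, ((0, 0), (0, py), (0, px)))
    probs = np.empty_like(padded)
    for start in range(0, nz, batch):
        sl = padded[start : start + batch][:, None]  # (n,1,H,W)
        probs[start : start + batch] = model.predict_slices(sl)[:, 0]
    out = probs[:, :ny, :nx]
    return Volume3D(out.astype(np.float32), vol.voxel_size.copy(), vol.origin.copy())


def save_checkpoint(model: SegModel, path) -> None:
    """Serialized weights (.npz) plus a JSON config sidecar."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".ckpt.npz"), **arrays)
    sidecar = {
        "variant": model.config.variant,
        "in_channels": model.config.in_channels,
        "out_channels": model.config.out_channels,
        "stages": [list(s) for s in model.config.stages],
        "side_supervision": model.config.side_supervision,
        "seed": model.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> SegModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = NetConfig(
        variant=sidecar["variant"],
        in_channels=sidecar["in_channels"],
        out_channels=sidecar["out_channels"],
        stages=tuple(tuple(s) for s in sidecar["stages"]),
        side_supervision=sidecar["side_supervision"],
    )
    model = SegModel(config, seed=sidecar.get("seed", 0))
    with np.load(path.with_suffix(".ckpt.npz")) as z:
        model.load_state_arrays([z[f"p{i}"] for i in range(len(z.files))])
    return model
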