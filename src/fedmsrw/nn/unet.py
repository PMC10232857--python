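"""Small configurable 3-D encoder–decoder segmentation network.

The network maps an (N, C, D, H, W) patch to voxelwise lesion
probabilities of the same spatial shape.  Besides the forward/backward
contract it owns the *parameter partition* used by federated
normalization-preserving aggregation: every batch-norm affine parameter
and running statistic belongs to the client-local set (theta^bn), every
remaining parameter to the shared set (theta^r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm3d, Conv3d, MaxPool3d, ReLU, Sigmoid, Upsample3d

__all__ = [
    "NetworkConfig",
    "ParameterPartition",
    "UNet3D",
    "build_network",
    "partition_parameters",
    "assemble_client_parameters",
]

#: initial bias of the output head; a negative value starts predicted
#: probabilities low (~0.12), which stabilises soft-Dice training on
#: sparse lesion targets
_HEAD_BIAS_INIT = -2.0


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs.

    in_channels: input image channels (1 for single-sequence FLAIR-like data).
    depth: number of pooling levels; input patch axes must be divisible
        by ``2**depth``.
    base_channels: channels at the top level; doubled per level.
    norm: "batch" (default) or "none".
    """

    in_channels: int = 1
    depth: int = 3
    base_channels: int = 8
    norm: str = "batch"

    def __post_init__(self):
        if self.in_channels < 1 or self.depth < 1 or self.base_channels < 1:
            raise ValueError("in_channels, depth and base_channels must be >= 1")
        if self.norm not in ("batch", "none"):
            raise ValueError(f"unknown norm kind {self.norm!r}")


@dataclass(frozen=True)
class ParameterPartition:
    """Named bipartition of the network state: theta^bn vs theta^r."""

    bn_names: tuple[str, ...]
    rest_names: tuple[str, ...]

    @property
    def all_names(self) -> tuple[str, ...]:
        return self.bn_names + self.rest_names


class _ConvBlock:
    """conv(3x3x3) -> [batch norm] -> ReLU."""

    def __init__(self, cin: int, cout: int, norm: str, rng: np.random.Generator):
        self.conv = Conv3d(cin, cout, 3, rng)
        self.bn = BatchNorm3d(cout) if norm == "batch" else None
        self.relu = ReLU()

    def forward(self, x, training):
        x = self.conv.forward(x, training)
        if self.bn is not None:
            x = self.bn.forward(x, training)
        return self.relu.forward(x, training)

    def backward(self, dy):
        dy = self.relu.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)

    def named_layers(self):
        yield "conv", self.conv
        if self.bn is not None:
            yield "bn", self.bn


class UNet3D:
    """Encoder–decoder with skip connections and a sigmoid head.

    Built by :func:`build_network`; parameters are exposed as flat
    name->array maps so federated aggregation can treat the model as a
    named parameter container.
    """

    def __init__(self, config: NetworkConfig, rng_seed: int):
        self.config = config
        rng = np.random.default_rng(rng_seed)
        ch = [config.base_channels * 2**l for l in range(config.depth + 1)]
        self.enc = []
        cin = config.in_channels
        for l in range(config.depth):
            self.enc.append(_ConvBlock(cin, ch[l], config.norm, rng))
            cin = ch[l]
        self.pools = [MaxPool3d() for _ in range(config.depth)]
        self.bottleneck = _ConvBlock(ch[config.depth - 1], ch[config.depth],
                                     config.norm, rng)
        self.ups = [Upsample3d() for _ in range(config.depth)]
        self.dec = []
        for l in reversed(range(config.depth)):
            self.dec.append(_ConvBlock(ch[l + 1] + ch[l], ch[l], config.norm, rng))
        self.head = Conv3d(ch[0], 1, 1, rng)
        self.head.params["bias"][:] = _HEAD_BIAS_INIT
        self.sigmoid = Sigmoid()

    # -- named state ------------------------------------------------------

    def _named_layers(self):
        for l, blk in enumerate(self.enc):
            for tag, layer in blk.named_layers():
                yield f"enc{l}.{tag}", layer
        for tag, layer in self.bottleneck.named_layers():
            yield f"bottleneck.{tag}", layer
        for i, blk in enumerate(self.dec):
            l = self.config.depth - 1 - i
            for tag, layer in blk.named_layers():
                yield f"dec{l}.{tag}", layer
        yield "head", self.head

    def named_parameters(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": arr
            for name, layer in self._named_layers()
            for p, arr in layer.params.items()
        }

    def named_buffers(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{b}": arr
            for name, layer in self._named_layers()
            for b, arr in layer.buffers.items()
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        """Copy of all parameters and buffers, keyed by name."""
        out = {}
        for name, layer in self._named_layers():
            for p, arr in layer.params.items():
                out[f"{name}.{p}"] = arr.copy()
            for b, arr in layer.buffers.items():
                out[f"{name}.{b}"] = arr.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        """Assign (copies of) the given named arrays into the network."""
        own = {**self.named_parameters(), **self.named_buffers()}
        unknown = set(state) - set(own)
        if unknown:
            raise KeyError(f"unknown parameter names: {sorted(unknown)}")
        if strict and set(own) - set(state):
            raise KeyError(f"missing parameter names: {sorted(set(own) - set(state))}")
        for name, layer in self._named_layers():
            for p in layer.params:
                full = f"{name}.{p}"
                if full in state:
                    layer.params[p] = np.array(state[full], dtype=np.float32)
            for b in layer.buffers:
                full = f"{name}.{b}"
                if full in state:
                    layer.buffers[b] = np.array(state[full], dtype=np.float32)

    def gradients(self) -> dict[str, np.ndarray]:
        return {
            f"{name}.{p}": g
            for name, layer in self._named_layers()
            for p, g in layer.grads.items()
        }

    # -- compute ----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map (N, C, D, H, W) input to (N, 1, D, H, W) probabilities."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, D, H, W) input, got {x.shape}"
            )
        div = 2**self.config.depth
        for ax, extent in zip("DHW", x.shape[2:]):
            if extent % div:
                raise ValueError(
                    f"axis {ax} extent {extent} not divisible by 2^depth = {div}"
                )
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        x = self.bottleneck.forward(x, training)
        self._skip_channels = []
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = blk.forward(x, training)
        x = self.head.forward(x, training)
        return self.sigmoid.forward(x, training)

    def backward(self, dprob: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate dL/d(probability); returns name->gradient."""
        dy = self.sigmoid.backward(dprob.astype(np.float32))
        dy = self.head.backward(dy)
        dskips = []
        for (c_up, c_skip), up, blk in zip(
            reversed(self._skip_channels), reversed(self.ups), reversed(self.dec)
        ):
            dy = blk.backward(dy)
            dskips.append(dy[:, c_up:])
            dy = up.backward(dy[:, :c_up])
        dy = self.bottleneck.backward(dy)
        for blk, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dy = pool.backward(dy)
            dy = blk.backward(dy + dskip)
        return self.gradients()

    # -- partition --------------------------------------------------------

    def parameter_partition(self) -> ParameterPartition:
        return partition_parameters(
            list(self.named_parameters()) + list(self.named_buffers())
        )


def build_network(config: NetworkConfig, rng_seed: int) -> UNet3D:
    """Deterministically initialise a network from (config, seed)."""
    return UNet3D(config, rng_seed)


def partition_parameters(names) -> ParameterPartition:
    """Split names into normalization-local (theta^bn) and shared (theta^r).

    Accepts a network, a name->array map, or an iterable of names.  A batch
    norm entry is anything under a ``.bn.`` scope — affine weight/bias and
    running mean/variance alike; running statistics are deliberately
    client-local state.
    """
    if isinstance(names, UNet3D):
        names = list(names.named_parameters()) + list(names.named_buffers())
    elif isinstance(names, dict):
        names = list(names)
    names = list(names)
    if any(not isinstance(n, str) for n in names):
        raise TypeError("expected parameter names (strings)")
    bn = tuple(n for n in names if ".bn." in n)
    rest = tuple(n for n in names if ".bn." not in n)
    return ParameterPartition(bn_names=bn, rest_names=rest)


def assemble_client_parameters(
    global_rest: dict[str, np.ndarray],
    client_bn: dict[str, np.ndarray],
    partition: ParameterPartition,
) -> dict[str, np.ndarray]:
    """Compose a client model: shared theta^r + that client's theta^bn.

    The two maps must exactly tile the partition's name universe.
    """
    missing_rest = set(partition.rest_names) - set(global_rest)
    missing_bn = set(partition.bn_names) - set(client_bn)
    extra = (set(global_rest) - set(partition.rest_names)) | (
        set(client_bn) - set(partition.bn_names)
    )
    problems = []
    if missing_rest:
        problems.append(f"missing shared entries: {sorted(missing_rest)}")
    if missing_bn:
        problems.append(f"missing normalization entries: {sorted(missing_bn)}")
    if extra:
        problems.append(f"unexpected entries: {sorted(extra)}")
    if problems:
        raise KeyError("; ".join(problems))
    out = {n: np.array(global_rest[n]) for n in partition.rest_names}
    out.update({n: np.array(client_bn[n]) for n in partition.bn_names})
    return out
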