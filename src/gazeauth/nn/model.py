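"""Two-branch convolutional embedding network.

The 2-D branch (saccade distribution maps, 128x128) stacks four blocks of
[Conv2d 64 filters, kernel 5x5, dilation 1 -> BatchNorm -> ReLU -> 2x2 max
pool].  The 1-D branch (motion-information sequences, 2 channels) stacks
four blocks of [Conv1d 64 filters, kernel 7, dilation 7 -> BatchNorm ->
ReLU -> stride-4 max pool].  Flattened branch outputs are concatenated and
passed through fully connected layers (512 -> 128) and L2-normalized, giving
a 128-dimensional unit embedding.  Either branch can be omitted (MI-only /
SDM-only variants).
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    Conv1d,
    Conv2d,
    Flatten,
    L2Norm,
    Linear,
    MaxPool1d,
    MaxPool2d,
    ReLU,
    Sequential,
)

__all__ = ["EmbeddingNet"]

N_FILTERS = 64
EMBED_DIM = 128


class EmbeddingNet:
    """Embedding model over MI sequences and/or SDM images.

    Parameters
    ----------
    mi_len
        Number of columns of the MI input (2 x mi_len); None disables the
        1-D branch.
    sdm_shape
        Spatial shape of the SDM input; None disables the 2-D branch.
    """

    def __init__(
        self,
        mi_len: int | None = None,
        sdm_shape: tuple[int, int] | None = (128, 128),
        embed_dim: int = EMBED_DIM,
        fc_width: int = 512,
        n_filters: int = N_FILTERS,
        seed: int = 0,
        dtype=np.float32,
    ):
        if mi_len is None and sdm_shape is None:
            raise ValueError("at least one branch (MI or SDM) must be enabled")
        rng = np.random.default_rng(seed)
        self.mi_len = mi_len
        self.sdm_shape = tuple(sdm_shape) if sdm_shape is not None else None
        self.embed_dim = embed_dim
        self.dtype = dtype

        self.branch_1d = None
        self.branch_2d = None
        flat = 0
        if mi_len is not None:
            blocks = []
            cin = 2
            for _ in range(4):
                blocks += [
                    Conv1d(cin, n_filters, kernel=7, dilation=7, rng=rng, dtype=dtype),
                    BatchNorm(n_filters, dtype=dtype),
                    ReLU(),
                    MaxPool1d(4),
                ]
                cin = n_filters
            blocks.append(Flatten())
            self.branch_1d = Sequential(*blocks)
            self._flat_1d = self._probe(self.branch_1d, (1, 2, mi_len))
            if self._flat_1d == 0:
                raise ValueError(f"mi_len={mi_len} too short for 4 stride-4 pools")
            flat += self._flat_1d
        if sdm_shape is not None:
            blocks = []
            cin = 1
            for _ in range(4):
                blocks += [
                    Conv2d(cin, n_filters, kernel=5, dilation=1, rng=rng, dtype=dtype),
                    BatchNorm(n_filters, dtype=dtype),
                    ReLU(),
                    MaxPool2d(2),
                ]
                cin = n_filters
            blocks.append(Flatten())
            self.branch_2d = Sequential(*blocks)
            self._flat_2d = self._probe(self.branch_2d, (1, 1, *self.sdm_shape))
            flat += self._flat_2d

        self.head = Sequential(
            Linear(flat, fc_width, rng=rng, dtype=dtype),
            ReLU(),
            Linear(fc_width, embed_dim, rng=rng, dtype=dtype),
            L2Norm(),
        )

    @staticmethod
    def _probe(branch: Sequential, shape) -> int:
        out = branch.forward(np.zeros(shape, dtype=np.float32), train=True)
        return out.shape[1]

    # -- forward / backward ------------------------------------------------
    def forward(
        self,
        mi: np.ndarray | None = None,
        sdm: np.ndarray | None = None,
        train: bool = True,
    ) -> np.ndarray:
        """Embed a batch; returns (B, embed_dim) unit vectors."""
        parts = []
        if self.branch_1d is not None:
            if mi is None:
                raise ValueError("model was built with an MI branch but mi is None")
            if mi.shape[1:] != (2, self.mi_len):
                raise ValueError(
                    f"MI input shape {mi.shape[1:]} != (2, {self.mi_len})"
                )
            parts.append(self.branch_1d.forward(mi.astype(self.dtype), train=train))
        if self.branch_2d is not None:
            if sdm is None:
                raise ValueError("model was built with an SDM branch but sdm is None")
            if sdm.shape[1:] != (1, *self.sdm_shape):
                raise ValueError(
                    f"SDM input shape {sdm.shape[1:]} != (1, {self.sdm_shape})"
                )
            parts.append(self.branch_2d.forward(sdm.astype(self.dtype), train=train))
        fused = np.concatenate(parts, axis=1) if len(parts) > 1 else parts[0]
        return self.head.forward(fused, train=train)

    def backward(self, dembed: np.ndarray) -> None:
        dfused = self.head.backward(dembed.astype(self.dtype))
        ofs = 0
        if self.branch_1d is not None:
            self.branch_1d.backward(dfused[:, ofs : ofs + self._flat_1d])
            ofs += self._flat_1d
        if self.branch_2d is not None:
            self.branch_2d.backward(dfused[:, ofs : ofs + self._flat_2d])

    def parameters(self):
        out = []
        for branch in (self.branch_1d, self.branch_2d):
            if branch is not None:
                out.extend(branch.parameters())
        out.extend(self.head.parameters())
        return out

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        s = {"head": self.head.state()}
        if self.branch_1d is not None:
            s["branch_1d"] = self.branch_1d.state()
        if self.branch_2d is not None:
            s["branch_2d"] = self.branch_2d.state()
        return _deepcopy_arrays(s)

    def load_state_dict(self, s: dict) -> None:
        self.head.load_state(s["head"])
        if self.branch_1d is not None:
            self.branch_1d.load_state(s["branch_1d"])
        if self.branch_2d is not None:
            self.branch_2d.load_state(s["branch_2d"])

    def spec(self) -> dict:
        """JSON-serializable architecture description."""
        return {
            "mi_len": self.mi_len,
            "sdm_shape": self.sdm_shape,
            "embed_dim": self.embed_dim,
            "n_filters": N_FILTERS,
        }


def _deepcopy_arrays(obj):
    if isinstance(obj, dict):
        return {k: _deepcopy_arrays(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.copy()
    return obj
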