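"""Electrode montage grids and the structural (spatial-adjacency) graph.

Scalp electrodes are laid out on an integer 2-D grid; two electrodes are
structurally connected when they are grid neighbours in any of the eight
directions (Chebyshev distance 1).  The binary adjacency matrix ``A`` is
augmented with self-loops and symmetrically normalised in the spectral
(GCN) fashion::

    A_hat = D_tilde^{-1/2} (A + I) D_tilde^{-1/2}

where ``D_tilde`` is the diagonal degree matrix of ``A + I``.  ``A_hat`` is
symmetric with spectrum in [-1, 1] and the vector of square-root degrees is
a fixed point, which makes repeated neighbourhood averaging numerically
stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "StructuralGraph",
    "available_montages",
    "build_layout",
    "build_adjacency",
    "normalize_adjacency",
]

_LAYOUT_PKG = "migraph.layouts"
DEFAULT_MONTAGE = "bci2a-22"


def available_montages() -> list[str]:
    """Names of the layouts packaged with the library."""
    files = resources.files(_LAYOUT_PKG)
    return sorted(p.name[: -len(".json")] for p in files.iterdir() if p.name.endswith(".json"))


@dataclass(frozen=True)
class ElectrodeLayout:
    """An ordered set of channel names with integer 2-D grid positions."""

    name: str
    channels: tuple[str, ...]
    grid_position: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if set(self.channels) != set(self.grid_position):
            raise ValueError("grid_position keys must match channels")
        cells = list(self.grid_position.values())
        if len(set(cells)) != len(cells):
            raise ValueError("two channels share a grid cell")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, channel: str) -> int:
        return self.channels.index(channel)

    @classmethod
    def from_dict(cls, payload: dict) -> "ElectrodeLayout":
        grid = {ch: (int(r), int(c)) for ch, (r, c) in payload["grid"].items()}
        return cls(name=payload.get("name", "custom"), channels=tuple(grid), grid_position=grid)

    @classmethod
    def from_json(cls, path) -> "ElectrodeLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_layout(montage_name: str = DEFAULT_MONTAGE) -> ElectrodeLayout:
    """Load a packaged montage layout by name.

    Raises
    ------
    ValueError
        If the montage is not packaged; the message lists available names.
    """
    ref = resources.files(_LAYOUT_PKG).joinpath(f"{montage_name}.json")
    if not ref.is_file():
        raise ValueError(
            f"unknown montage {montage_name!r}; available: {', '.join(available_montages())}"
        )
    return ElectrodeLayout.from_dict(json.loads(ref.read_text()))


@dataclass(frozen=True)
class StructuralGraph:
    """Binary adjacency over a montage together with its GCN normalisation.

    Attributes
    ----------
    A : (n, n) binary symmetric matrix, zero diagonal.
    A_tilde : ``A + I``.
    D_tilde : diagonal degree matrix of ``A_tilde``.
    A_hat : ``D_tilde^{-1/2} A_tilde D_tilde^{-1/2}``.
    """

    layout: ElectrodeLayout
    A: np.ndarray
    A_tilde: np.ndarray = field(repr=False)
    D_tilde: np.ndarray = field(repr=False)
    A_hat: np.ndarray = field(repr=False)

    @property
    def channels(self) -> tuple[str, ...]:
        return self.layout.channels

    def neighbors(self, channel: str) -> set[str]:
        i = self.layout.index(channel)
        return {self.channels[j] for j in np.flatnonzero(self.A[i])}

    def to_csv(self, path, which: str = "A_hat") -> None:
        """Export one of the graph matrices as CSV with channel-name headers."""
        import pandas as pd

        mats = {"A": self.A, "A_tilde": self.A_tilde, "D_tilde": self.D_tilde,
                "A_hat": self.A_hat}
        if which not in mats:
            raise ValueError(f"unknown matrix {which!r}; choose from {', '.join(mats)}")
        pd.DataFrame(mats[which], index=self.channels, columns=self.channels).to_csv(path)

    def checksum(self) -> str:
        """Stable digest of A_hat, used to stamp embedded datasets."""
        h = hashlib.sha256()
        h.update(",".join(self.channels).encode())
        h.update(np.ascontiguousarray(self.A_hat, dtype=np.float64).tobytes())
        return h.hexdigest()[:16]


def build_adjacency(layout: ElectrodeLayout) -> StructuralGraph:
    """Build the structural graph of a layout.

    Channels are connected iff their grid cells are at Chebyshev distance 1
    (vertical, horizontal or diagonal neighbours); boundary channels simply
    have fewer neighbours.  Self-connection enters through ``A_tilde``.
    """
    pos = np.array([layout.grid_position[ch] for ch in layout.channels], dtype=int)
    cheb = np.max(np.abs(pos[:, None, :] - pos[None, :, :]), axis=-1)
    A = ((cheb == 1)).astype(np.float64)
    A_hat = normalize_adjacency(A)
    A_tilde = A + np.eye(len(A))
    D_tilde = np.diag(A_tilde.sum(axis=1))
    return StructuralGraph(layout=layout, A=A, A_tilde=A_tilde, D_tilde=D_tilde, A_hat=A_hat)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Spectral (GCN) normalisation of a binary adjacency matrix.

    Returns ``D_tilde^{-1/2} (A + I) D_tilde^{-1/2}`` with ``D_tilde`` the
    degree matrix of ``A + I``; entry (i, j) equals
    ``A_tilde[i, j] / sqrt(D_tilde[i, i] * D_tilde[j, j])``.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if not np.all(np.isin(A, (0.0, 1.0))):
        raise ValueError("adjacency entries must be binary")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency diagonal must be zero (self-loops are added internally)")
    A_tilde = A + np.eye(A.shape[0])
    deg = A_tilde.sum(axis=1)  # >= 1 always
    inv_sqrt = 1.0 / np.sqrt(deg)
    return A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
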