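"""Per-residue feature encoding from high-frequency GNM modes.

Two coding schemes turn mode components into classifier inputs:

* ``single_mode`` — the i-th fastest mode alone; each residue's features are
  that eigenvector's components in a sliding window centred on the residue.
* ``top_m`` — the m fastest modes together; the window is applied to each
  mode and the blocks are concatenated mode-major, i.e. for m = 3, sw = 3 the
  row for residue i reads
  (u1[i-1], u1[i], u1[i+1], u2[i-1], u2[i], u2[i+1], u3[i-1], u3[i], u3[i+1]).

Window offsets are positions in the retained Cα list (robust to residue
numbering gaps); offsets falling outside the chain are zero-padded by
default, or the affected rows dropped with ``edge="drop"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .gnm import ModeSpectrum

__all__ = ["FeatureScheme", "FeatureMatrix", "encode"]


@dataclass(frozen=True)
class FeatureScheme:
    """A feature-coding scheme: which fast modes, and how wide a window.

    Parameters
    ----------
    scheme:
        ``"single_mode"`` (use only the ``mode``-th fastest mode) or
        ``"top_m"`` (concatenate the ``mode`` fastest modes).
    mode:
        Mode rank i (single_mode) or mode count m (top_m); 1–20 in the
        standard grid.
    window:
        Sliding window size sw, an odd integer ≥ 1.
    edge:
        Terminus handling: ``"pad"`` fills out-of-chain window slots with 0,
        ``"drop"`` removes rows whose window is incomplete.
    """

    scheme: Literal["single_mode", "top_m"] = "top_m"
    mode: int = 1
    window: int = 1
    edge: Literal["pad", "drop"] = "pad"

    def __post_init__(self) -> None:
        if self.scheme not in ("single_mode", "top_m"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.mode < 1:
            raise ValueError(f"mode rank/count must be >= 1, got {self.mode}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be a positive odd integer, got {self.window}")
        if self.edge not in ("pad", "drop"):
            raise ValueError(f"edge must be 'pad' or 'drop', got {self.edge!r}")

    @property
    def n_modes(self) -> int:
        """Number of distinct modes entering the feature vector."""
        return 1 if self.scheme == "single_mode" else self.mode

    @property
    def n_features(self) -> int:
        """Feature dimension d = sw (single_mode) or m·sw (top_m)."""
        return self.n_modes * self.window

    def describe(self) -> str:
        tag = "i" if self.scheme == "single_mode" else "m"
        return f"{self.scheme}({tag}={self.mode}, sw={self.window})"


@dataclass(frozen=True)
class FeatureMatrix:
    """N_rows × d feature matrix with the residue indices each row describes."""

    values: np.ndarray
    residue_index: np.ndarray  # positions in the retained Cα list
    scheme: FeatureScheme
    chain_id: str = ""

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def encode(spec: ModeSpectrum, scheme: FeatureScheme, chain_id: str = "") -> FeatureMatrix:
    """Encode per-residue feature vectors from a mode spectrum.

    Raises ``ValueError("insufficient modes ...")`` when the requested mode
    rank or count exceeds the available non-null modes.
    """
    if scheme.scheme == "single_mode":
        ranks = [scheme.mode]
    else:
        ranks = list(range(1, scheme.mode + 1))
    if max(ranks) > spec.n_nonnull:
        raise ValueError(
            f"insufficient modes: scheme needs fast mode {max(ranks)} but only "
            f"{spec.n_nonnull} non-null mode(s) exist"
        )

    n = spec.n
    half = (scheme.window - 1) // 2
    modes = np.column_stack([spec.fast_mode(r) for r in ranks])  # N × n_modes

    # blocks[o] holds every mode shifted by offset o, zero-padded at termini
    block_list = []
    for offset in range(-half, half + 1):
        shifted = np.zeros_like(modes)
        if offset < 0:
            shifted[-offset:, :] = modes[:offset, :]
        elif offset > 0:
            shifted[:-offset, :] = modes[offset:, :]
        else:
            shifted = modes
        block_list.append(shifted)
    # mode-major ordering: all window positions of mode 1, then mode 2, ...
    per_mode = [
        np.column_stack([block[:, k] for block in block_list]) for k in range(len(ranks))
    ]
    x = np.column_stack(per_mode)

    index = np.arange(n)
    if scheme.edge == "drop" and half > 0:
        keep = slice(half, n - half)
        x = x[keep]
        index = index[keep]
    return FeatureMatrix(values=x, residue_index=index, scheme=scheme, chain_id=chain_id)
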