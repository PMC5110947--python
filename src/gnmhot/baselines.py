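"""Threshold baselines for hot-spot identification from GNM fast modes.

Two families of comparison methods predate the classifier approach:

* MSF thresholding — a residue is a hot spot when its normalized fast-mode
  MSF exceeds a threshold, either a constant 0.005 or the length-scaled 6/N.
  Because normalized MSF sums to 1 per mode, 6/N is the stricter rule for
  any chain shorter than 1200 residues, so its prediction set is always a
  subset of the constant rule's on the same profile.
* MSDF scoring — rank residues by how strongly their pair distances
  fluctuate in the fast modes; the published selection rule is not fully
  specified, so this module returns a ranking score and leaves the final
  labeling to a user-chosen quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .gnm import GNMParameters, ModeSpectrum, msdf_matrix, msf_weighted

__all__ = ["ThresholdRule", "msf_threshold_predict", "msdf_score"]


@dataclass(frozen=True)
class ThresholdRule:
    """A hot-spot threshold on normalized MSF.

    ``constant`` uses a fixed value θ (default 0.005); ``length_scaled``
    uses θ = a / N with default a = 6, where N is the chain length.
    """

    kind: Literal["constant", "length_scaled"] = "constant"
    value: float = 0.005
    scale: float = 6.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "length_scaled"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.kind == "constant" and self.value <= 0:
            raise ValueError(f"threshold must be positive, got {self.value}")
        if self.kind == "length_scaled" and self.scale <= 0:
            raise ValueError(f"threshold scale must be positive, got {self.scale}")

    def threshold(self, n_residues: int) -> float:
        if self.kind == "constant":
            return self.value
        return self.scale / n_residues


def msf_threshold_predict(
    spec: ModeSpectrum,
    mode_count: int,
    rule: ThresholdRule,
    params: GNMParameters | None = None,
) -> np.ndarray:
    """Binary hot-spot labels: normalized MSF over the ``mode_count`` fastest
    modes strictly above the rule's threshold."""
    if mode_count < 1:
        raise ValueError(f"mode_count must be >= 1, got {mode_count}")
    msf = msf_weighted(spec, range(1, mode_count + 1), params, normalized=True)
    return (msf > rule.threshold(spec.n)).astype(int)


def msdf_score(
    spec: ModeSpectrum,
    mode_count: int,
    params: GNMParameters | None = None,
    aggregate: Literal["max", "mean"] = "max",
) -> np.ndarray:
    """Per-residue MSDF ranking score over the ``mode_count`` fastest modes.

    Row i of the MSDF matrix is reduced by ``max`` (default) or by the mean
    over partners j ≠ i (the diagonal is structurally zero and excluded).
    """
    if mode_count < 1:
        raise ValueError(f"mode_count must be >= 1, got {mode_count}")
    d = msdf_matrix(spec, range(1, mode_count + 1), params)
    if aggregate == "max":
        return d.max(axis=1)
    if aggregate == "mean":
        return d.sum(axis=1) / (d.shape[0] - 1)
    raise ValueError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
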