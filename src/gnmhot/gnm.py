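"""Gaussian network model: Kirchhoff matrix, normal modes, fluctuation quantities.

The GNM coarse-grains a protein to its Cα trace and connects every residue
pair within a distance cutoff ``R_C`` by an identical harmonic spring.  Under
the isotropic-Gaussian fluctuation assumption the whole model is encoded in
the Kirchhoff (connectivity) matrix Γ — the graph Laplacian of the contact
graph — and residue dynamics follow from its eigendecomposition
Γ = U Λ Uᵀ.  Cross-correlations between residue fluctuations are
⟨ΔRi·ΔRj⟩ = (3 k_B T / γ) [Γ⁺]_ij, where Γ⁺ is the Moore–Penrose
pseudo-inverse restricted to non-null modes.

High-frequency ("fast") modes are the eigenvectors with the *largest*
eigenvalues; they describe localized fluctuations and are the raw material
for hot-spot identification.  Throughout this module a *mode rank* of 1
denotes the fastest mode (largest eigenvalue), rank 2 the second fastest,
and so on — the opposite end of the spectrum from the null (zero-eigenvalue)
modes that encode rigid-body degrees of freedom of connected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import CaChain

logger = logging.getLogger(__name__)

__all__ = [
    "GNMParameters",
    "KirchhoffMatrix",
    "ModeSpectrum",
    "build_kirchhoff",
    "decompose",
    "msf_weighted",
    "correlation_matrix",
    "msdf_matrix",
]


@dataclass(frozen=True)
class GNMParameters:
    """Parameters of a GNM computation.

    Parameters
    ----------
    cutoff:
        Contact cutoff ``R_C`` in Å.  A pair is in contact iff its Cα–Cα
        distance is ≤ cutoff (the boundary counts as contact).
    scale:
        The prefactor ``c = 3 k_B T / γ`` as a single dimensionless
        multiplier.  It cancels in every normalized quantity; default 1.0.
    zero_tol:
        Relative eigenvalue tolerance below which a mode is treated as part
        of the null space, as a fraction of the largest eigenvalue.
    """

    cutoff: float = 7.0
    scale: float = 1.0
    zero_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if self.zero_tol < 0:
            raise ValueError(f"zero_tol must be non-negative, got {self.zero_tol}")


@dataclass(frozen=True)
class KirchhoffMatrix:
    """Symmetric integer Kirchhoff matrix Γ with the cutoff that built it.

    Off-diagonal entries are −1 for contacting pairs and 0 otherwise; the
    diagonal holds the contact degree, so every row sums to zero and Γ is
    positive semidefinite.
    """

    matrix: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"Kirchhoff matrix must be square, got {m.shape}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ModeSpectrum:
    """Eigendecomposition of a Kirchhoff matrix with fast-mode indexing.

    ``eigenvalues`` are sorted ascending and ``eigenvectors[:, k]`` is the
    orthonormal eigenvector of ``eigenvalues[k]``.  ``n_zero`` counts null
    modes, which equals the number of connected components of the contact
    graph.  Fast-mode rank ``r`` (1-based) maps to column ``N - r``.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    params: GNMParameters = field(default_factory=GNMParameters)

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def n_nonnull(self) -> int:
        """Number of modes with strictly positive (non-null) eigenvalue."""
        return self.n - self.n_zero

    def _check_ranks(self, ranks: Iterable[int]) -> np.ndarray:
        ranks = np.asarray(sorted(set(int(r) for r in ranks)), dtype=int)
        if ranks.size == 0:
            raise ValueError("empty mode subset")
        if ranks.min() < 1:
            raise ValueError(f"mode ranks are 1-based, got {ranks.min()}")
        if ranks.max() > self.n_nonnull:
            raise ValueError(
                "zero eigenvalue in mode subset: rank "
                f"{ranks.max()} exceeds the {self.n_nonnull} non-null mode(s)"
            )
        return ranks

    def fast_mode_columns(self, ranks: Iterable[int]) -> np.ndarray:
        """Column indices for fast-mode ranks (1 = largest eigenvalue)."""
        return self.n - self._check_ranks(ranks)

    def fast_mode(self, rank: int) -> np.ndarray:
        """Eigenvector of the ``rank``-th largest eigenvalue (hm1, hm2, ...)."""
        (col,) = self.fast_mode_columns([rank])
        return self.eigenvectors[:, col]

    def fast_eigenvalue(self, rank: int) -> float:
        (col,) = self.fast_mode_columns([rank])
        return float(self.eigenvalues[col])


def build_kirchhoff(chain: CaChain, params: GNMParameters) -> KirchhoffMatrix:
    """Build the Kirchhoff matrix of the Cα contact graph at ``params.cutoff``."""
    coords = chain.coords
    dist = squareform(pdist(coords))
    contacts = (dist <= params.cutoff)
    np.fill_diagonal(contacts, False)
    gamma = -contacts.astype(int)
    np.fill_diagonal(gamma, contacts.sum(axis=1))
    return KirchhoffMatrix(matrix=gamma, cutoff=params.cutoff)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the largest-|component| entry is positive.

    Ties resolve to the lowest index (argmax's first-hit rule).  Eigenvector
    sign is arbitrary in any decomposition; features built from signed mode
    components need a reproducible choice.
    """
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def decompose(k: KirchhoffMatrix, params: GNMParameters) -> ModeSpectrum:
    """Full symmetric eigendecomposition of Γ with deterministic mode signs."""
    try:
        eigenvalues, eigenvectors = np.linalg.eigh(k.matrix.astype(float))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - eigh on PSD rarely fails
        raise RuntimeError(f"eigendecomposition failed for {k.n}x{k.n} Kirchhoff matrix") from exc
    eigenvectors = _fix_signs(eigenvectors)
    lam_max = max(float(eigenvalues[-1]), 1.0)
    tol = params.zero_tol * lam_max
    n_zero = int(np.sum(eigenvalues < tol))

    gaps = np.diff(eigenvalues)
    degenerate = np.sum(np.abs(gaps) < 1e-8 * lam_max)
    if degenerate:
        logger.info("spectrum has %d degenerate eigenvalue pair(s); mode order is by index", degenerate)
    return ModeSpectrum(
        eigenvalues=eigenvalues, eigenvectors=eigenvectors, n_zero=n_zero, params=params
    )


def _subset(spec: ModeSpectrum, mode_ranks: Iterable[int]) -> tuple[np.ndarray, np.ndarray]:
    cols = spec.fast_mode_columns(mode_ranks)
    return spec.eigenvalues[cols], spec.eigenvectors[:, cols]


def msf_weighted(
    spec: ModeSpectrum,
    mode_ranks: Sequence[int],
    params: GNMParameters | None = None,
    normalized: bool = False,
) -> np.ndarray:
    """Mean square fluctuations over a fast-mode subset.

    MSF_i = c · Σ_k λ_k⁻¹ u_ki² / Σ_k λ_k⁻¹ for ranks ``k`` in the subset;
    the normalized profile divides out ``c`` so that each single-mode profile
    sums to 1 over residues.
    """
    params = params or spec.params
    lam, u = _subset(spec, mode_ranks)
    w = 1.0 / lam
    msf = (u**2 @ w) / w.sum()
    return msf if normalized else params.scale * msf


def correlation_matrix(
    spec: ModeSpectrum,
    mode_ranks: Sequence[int],
    params: GNMParameters | None = None,
) -> np.ndarray:
    """Residue cross-correlations C_ij = c · Σ_k λ_k⁻¹ u_ki u_kj over a subset.

    With all non-null modes this is ``c`` times the Moore–Penrose
    pseudo-inverse of Γ.
    """
    params = params or spec.params
    lam, u = _subset(spec, mode_ranks)
    return params.scale * (u / lam) @ u.T


def msdf_matrix(
    spec: ModeSpectrum,
    mode_ranks: Sequence[int],
    params: GNMParameters | None = None,
) -> np.ndarray:
    """Mean square distance fluctuations D_ij = C_ii + C_jj − 2 C_ij.

    Symmetric, zero diagonal, non-negative; D_ij measures how much the i–j
    distance fluctuates under the chosen mode subset.
    """
    c = correlation_matrix(spec, mode_ranks, params)
    d = np.diag(c)
    out = d[:, None] + d[None, :] - 2.0 * c
    np.fill_diagonal(out, 0.0)
    return np.maximum(out, 0.0)
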