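"""Angle-basis model algebra.

A functional-connectivity (FC) matrix is the region-by-region Pearson
correlation of BOLD time series.  The angle-basis model approximates it as the
average over ``N`` bases of per-region sinusoid phases ``theta`` and jitters
``j``::

    rho~_cd = (1/N) * sum_n  j_c^(n) * j_d^(n) * cos(theta_c^(n) - theta_d^(n))

A single basis is what a population of regions oscillating at one common
frequency would produce: two regions perfectly in phase correlate at +1, in
antiphase at -1, and the jitter ``j in [0, 1]`` models a region decorrelating
from everything else (``j = 0`` kills all of its correlations).

This module holds the validated containers and the pure-algebra operations:
reconstruction, residual, loss, half-vectorization, and parameter accounting.
All losses, residuals and feature vectors use strictly off-diagonal entries:
the FC diagonal is identically 1 and carries no information, while the model
diagonal is ``mean_n j_c^2`` which is not constrained to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TWO_PI",
    "FCMatrix",
    "AngleBasis",
    "Decomposition",
    "reconstruct",
    "residual",
    "loss",
    "vectorize",
    "unvectorize",
    "param_count",
]

TWO_PI = 2.0 * np.pi

#: absolute tolerance for symmetry / range validation of FC matrices
VALIDATION_ATOL = 1e-8


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass(frozen=True)
class FCMatrix:
    """A validated R x R functional-connectivity matrix.

    Entries are Pearson correlations: symmetric, in [-1, 1], unit diagonal.
    Inputs asymmetric or out of range by more than ``VALIDATION_ATOL`` are
    rejected; within tolerance they are symmetrized as ``(M + M.T) / 2`` and
    clipped.
    """

    values: np.ndarray
    region_labels: list[str] | None = None

    def __post_init__(self):
        arr = _as_float_array(self.values, "FC matrix")
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"FC matrix must be square, got shape {arr.shape}")
        r = arr.shape[0]
        if r < 2:
            raise ValueError(f"FC matrix needs at least 2 regions, got {r}")
        asym = np.abs(arr - arr.T)
        if asym.max() > VALIDATION_ATOL:
            c, d = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"FC matrix asymmetric beyond tolerance at ({c}, {d}): "
                f"{arr[c, d]!r} vs {arr[d, c]!r}"
            )
        arr = 0.5 * (arr + arr.T)
        out_of_range = np.abs(arr) - 1.0
        if out_of_range.max() > VALIDATION_ATOL:
            c, d = np.unravel_index(np.argmax(out_of_range), arr.shape)
            raise ValueError(
                f"FC entry out of [-1, 1] at ({c}, {d}): {arr[c, d]!r}"
            )
        diag_err = np.abs(np.diag(arr) - 1.0)
        if diag_err.max() > VALIDATION_ATOL:
            c = int(np.argmax(diag_err))
            raise ValueError(f"FC diagonal entry not 1 at region {c}: {arr[c, c]!r}")
        arr = np.clip(arr, -1.0, 1.0)
        np.fill_diagonal(arr, 1.0)
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)
        if self.region_labels is not None:
            labels = [str(x) for x in self.region_labels]
            if len(labels) != r:
                raise ValueError(
                    f"{len(labels)} region labels for {r} regions"
                )
            object.__setattr__(self, "region_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AngleBasis:
    """N bases x R regions of phases (radians, in [0, 2pi)) and jitters ([0, 1])."""

    phases: np.ndarray
    jitters: np.ndarray

    def __post_init__(self):
        phases = _as_float_array(self.phases, "phases")
        jitters = _as_float_array(self.jitters, "jitters")
        if phases.ndim != 2 or jitters.ndim != 2:
            raise ValueError("phases and jitters must be 2-D (n_bases x n_regions)")
        if phases.shape != jitters.shape:
            raise ValueError(
                f"phase/jitter shape mismatch: {phases.shape} vs {jitters.shape}"
            )
        n, r = phases.shape
        if n < 1 or r < 2:
            raise ValueError(f"need n_bases >= 1 and n_regions >= 2, got {phases.shape}")
        if phases.min() < 0.0 or phases.max() >= TWO_PI:
            raise ValueError("phases must lie in [0, 2pi)")
        if jitters.min() < 0.0 or jitters.max() > 1.0:
            raise ValueError("jitters must lie in [0, 1]")
        phases = phases.copy()
        jitters = jitters.copy()
        phases.flags.writeable = False
        jitters.flags.writeable = False
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "jitters", jitters)

    @property
    def n_bases(self) -> int:
        return self.phases.shape[0]

    @property
    def n_regions(self) -> int:
        return self.phases.shape[1]


@dataclass(frozen=True)
class Decomposition:
    """A fitted basis plus its reconstruction, residual and fit diagnostics."""

    basis: AngleBasis
    reconstruction: np.ndarray
    residual: np.ndarray
    final_loss: float
    n_iterations: int
    seed: int
    fc: FCMatrix | None = field(default=None, repr=False, compare=False)

    @property
    def n_regions(self) -> int:
        return self.basis.n_regions

    @property
    def n_bases(self) -> int:
        return self.basis.n_bases


def reconstruct(basis: AngleBasis) -> np.ndarray:
    """Reconstruction rho~ of the angle-basis model.

    rho~_cd = (1/N) sum_n j_c^(n) j_d^(n) cos(theta_c^(n) - theta_d^(n)).
    Exactly symmetric; off-diagonal magnitudes <= 1 for jitters in [0, 1].
    """
    theta = basis.phases
    j = basis.jitters
    # N x R x R phase-difference cosines, jitter outer products, averaged over N
    diff = theta[:, :, None] - theta[:, None, :]
    per_basis = (j[:, :, None] * j[:, None, :]) * np.cos(diff)
    out = per_basis.mean(axis=0)
    return 0.5 * (out + out.T)  # enforce exact symmetry against round-off


def residual(fc: FCMatrix, reconstruction: np.ndarray) -> np.ndarray:
    """Elementwise residual r = rho - rho~.

    Diagonal entries are reported for completeness but are excluded from all
    loss and feature computations downstream.
    """
    recon = np.asarray(reconstruction, dtype=float)
    if recon.shape != fc.values.shape:
        raise ValueError(
            f"shape mismatch: FC {fc.values.shape} vs reconstruction {recon.shape}"
        )
    return fc.values - recon


def loss(fc: FCMatrix, reconstruction: np.ndarray) -> float:
    """RMSE of the residual over the R(R-1) off-diagonal entries."""
    r = residual(fc, reconstruction)
    n = r.shape[0]
    if n < 2:
        raise ValueError("loss needs at least 2 regions")
    off = ~np.eye(n, dtype=bool)
    return float(np.sqrt(np.mean(r[off] ** 2)))


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Strict upper triangle in row-major order: (0,1),(0,2),...,(1,2),...

    The standard feature vector for an R x R connectivity matrix; length
    R(R-1)/2 (34,716 for the 264-region Power atlas).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"vectorize needs a square matrix, got shape {m.shape}")
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def unvectorize(vec: np.ndarray, diagonal: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vectorize`: rebuild the symmetric matrix."""
    v = np.asarray(vec, dtype=float)
    f = v.shape[0]
    r = int(round((1 + np.sqrt(1 + 8 * f)) / 2))
    if r * (r - 1) // 2 != f:
        raise ValueError(f"vector length {f} is not R(R-1)/2 for integer R")
    out = np.full((r, r), 0.0)
    iu = np.triu_indices(r, k=1)
    out[iu] = v
    out = out + out.T
    np.fill_diagonal(out, diagonal)
    return out


def param_count(n_regions: int, n_bases: int) -> int:
    """Number of free parameters: phases + jitters = 2 * R * N."""
    if n_regions < 1 or n_bases < 1:
        raise ValueError("n_regions and n_bases must be positive")
    return 2 * int(n_regions) * int(n_bases)
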