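"""Multi-focus excitation solvers.

Given the forward operator H (M field points x N elements, typically
M << N) and target pressures P at the control points, the minimum-norm
least-squares drive

    U = H^H (H H^H)^-1 P

is the exact interpolant of smallest Euclidean norm.  The iteratively
weighted variant U = W H^H (H W H^H)^-1 P re-solves with a diagonal
weight that is repeatedly divided by the current element amplitudes,
equalising |u_n| across the aperture while remaining an exact interpolant
at every iteration (useful when hardware prefers near-uniform drive).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .propagation import ExcitationVector, PropagationOperator

__all__ = [
    "FocusSet",
    "WeightMatrix",
    "SolveResult",
    "solve_min_norm",
    "solve_weighted",
]

_TIKHONOV_SCALE = 1e-10  # ridge = scale * trace(G)/M when G is ill-conditioned
_COND_LIMIT = 1e12


class IllConditionedWarning(UserWarning):
    """The M x M normal matrix needed Tikhonov regularisation."""


@dataclass
class FocusSet:
    """Control points and their complex target pressures."""

    points: np.ndarray
    target_pressures: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.target_pressures = np.asarray(self.target_pressures, dtype=complex).ravel()
        if len(self.points) != len(self.target_pressures):
            raise ValueError("points and target_pressures lengths differ")
        if len(self.points) < 1:
            raise ValueError("need at least one control point")

    @property
    def m(self) -> int:
        return len(self.points)

    def to_csv(self, path) -> None:
        table = np.column_stack(
            [self.points, np.abs(self.target_pressures), np.angle(self.target_pressures)]
        )
        np.savetxt(
            path,
            table,
            delimiter=",",
            header="x_mm,y_mm,z_mm,amp,phase_rad",
            comments="",
            fmt="%.12g",
        )

    @classmethod
    def from_csv(cls, path) -> "FocusSet":
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(
            points=table[:, :3],
            target_pressures=table[:, 3] * np.exp(1j * table[:, 4]),
        )


@dataclass
class WeightMatrix:
    """Diagonal of the N x N positive weight matrix W."""

    diagonal: np.ndarray

    def __post_init__(self) -> None:
        self.diagonal = np.asarray(self.diagonal, dtype=float).ravel()
        if np.any(self.diagonal <= 0):
            raise ValueError("weights must be strictly positive")


@dataclass
class SolveResult:
    """Excitation with its diagnostics; the residual is always reported."""

    excitation: ExcitationVector
    residual: float               # ||H U - P|| / ||P||
    condition_number: float
    regularized: bool = False
    weights: WeightMatrix | None = None
    converged: bool = True
    iterations: int = 0
    residual_history: list = field(default_factory=list)
    amplitude_spread_history: list = field(default_factory=list)


def _targets_vector(h: PropagationOperator, targets) -> np.ndarray:
    if isinstance(targets, FocusSet):
        if targets.m != h.shape[0]:
            raise ValueError(
                f"operator has {h.shape[0]} field points but focus set has {targets.m}"
            )
        if not np.allclose(targets.points, h.field_points, atol=1e-9):
            raise ValueError("focus-set points do not match the operator field points")
        return targets.target_pressures
    return np.asarray(targets, dtype=complex).ravel()


def _weighted_min_norm(
    hm: np.ndarray, w: np.ndarray, p: np.ndarray
) -> tuple[np.ndarray, float, bool]:
    """U = W H^H (H W H^H)^-1 P with a logged ridge fallback."""
    hw = hm * w[None, :]
    gram = hw @ hm.conj().T
    cond = float(np.linalg.cond(gram))
    regularized = False
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        ridge = _TIKHONOV_SCALE * np.trace(gram).real / len(gram)
        gram = gram + ridge * np.eye(len(gram))
        regularized = True
        warnings.warn(
            f"normal matrix condition {cond:.3g} > {_COND_LIMIT:.0e}; "
            f"applied Tikhonov ridge {ridge:.3g}",
            IllConditionedWarning,
            stacklevel=3,
        )
    coeff = np.linalg.solve(gram, p)
    return hw.conj().T @ coeff, cond, regularized


def _relative_residual(hm: np.ndarray, u: np.ndarray, p: np.ndarray) -> float:
    return float(np.linalg.norm(hm @ u - p) / np.linalg.norm(p))


def solve_min_norm(h: PropagationOperator | np.ndarray, targets) -> SolveResult:
    """Minimum-Euclidean-norm exact interpolant of the control pressures."""
    hm = h.matrix if isinstance(h, PropagationOperator) else np.asarray(h, dtype=complex)
    p = _targets_vector(h, targets) if isinstance(h, PropagationOperator) else np.asarray(
        targets, dtype=complex
    ).ravel()
    u, cond, reg = _weighted_min_norm(hm, np.ones(hm.shape[1]), p)
    return SolveResult(
        excitation=ExcitationVector(u),
        residual=_relative_residual(hm, u, p),
        condition_number=cond,
        regularized=reg,
    )


def solve_weighted(
    h: PropagationOperator | np.ndarray,
    targets,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SolveResult:
    """Iteratively weighted minimum-norm solve with amplitude equalisation.

    Starting from W = I (the plain minimum-norm solution), each iteration
    updates w_n <- w_n / max(|u_n|, eps) and renormalises the weights to
    mean 1, then re-solves.  Every iterate interpolates the targets
    exactly, so only the element-amplitude distribution changes.  Stops
    when the largest relative change of |u_n| drops below ``tol``.
    """
    hm = h.matrix if isinstance(h, PropagationOperator) else np.asarray(h, dtype=complex)
    p = _targets_vector(h, targets) if isinstance(h, PropagationOperator) else np.asarray(
        targets, dtype=complex
    ).ravel()
    n = hm.shape[1]
    w = np.ones(n)
    u, cond, reg = _weighted_min_norm(hm, w, p)
    residuals = [_relative_residual(hm, u, p)]
    spreads = [_amplitude_spread(u)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        amp = np.abs(u)
        floor = 1e-12 * max(amp.max(), 1e-300)
        w = w / np.maximum(amp, floor)
        w = w / w.mean()
        u_new, cond, reg_i = _weighted_min_norm(hm, w, p)
        reg = reg or reg_i
        residuals.append(_relative_residual(hm, u_new, p))
        spreads.append(_amplitude_spread(u_new))
        change = np.max(
            np.abs(np.abs(u_new) - np.abs(u)) / max(np.abs(u).max(), 1e-300)
        )
        u = u_new
        if change < tol:
            converged = True
            break
    return SolveResult(
        excitation=ExcitationVector(u),
        residual=residuals[-1],
        condition_number=cond,
        regularized=reg,
        weights=WeightMatrix(w),
        converged=converged,
        iterations=it,
        residual_history=residuals,
        amplitude_spread_history=spreads,
    )


def _amplitude_spread(u: np.ndarray) -> float:
    amp = np.abs(u)
    active = amp > 1e-12 * amp.max()
    return float(amp[active].max() / amp[active].min())
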