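"""Discretised Rayleigh-Sommerfeld forward model.

Each element is a point source radiating a spherical wave with source
strength proportional to its area, so the pressure at field point ``r_m``
from excitation amplitudes ``u_n`` is

    P(r_m) = (j rho c k / 2 pi) * sum_n u_n * A_n * exp(-j k d_mn) / d_mn,

with ``d_mn = |r_m - r'_n|``.  Complex amplitudes are stored at t = 0 with
the harmonic factor ``exp(+j w t)`` dropped, so phase *decreases* with
propagation distance and focusing on a point uses the conjugate phase
``+k d``.  Units: mm and MHz internally (wavelength_mm = c[m/s] / f[MHz]
/ 1000); density and sound speed enter only as an overall pressure scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosimetry import attenuation_np_per_mm
from .geometry import ArrayGeometry

__all__ = [
    "Medium",
    "FieldGrid",
    "PropagationOperator",
    "PressureField",
    "ExcitationVector",
    "BeamMetrics",
    "SingularDistanceError",
    "FocusOutsideGridError",
    "build_propagator",
    "evaluate_field",
    "conjugate_focus_excitation",
    "measure_beam_widths",
]

_CHUNK = 8192  # field points per mat-vec block, bounds peak memory


class SingularDistanceError(ValueError):
    """A field point (numerically) coincides with an element."""


class FocusOutsideGridError(ValueError):
    """The intensity peak sits on the grid border, widths are undefined."""


@dataclass(frozen=True)
class Medium:
    """Homogeneous propagation medium.

    Attenuation follows the power law a(f) = a0 * f^gamma in dB/cm with f
    in MHz; defaults are vitreous-like water (lossless propagation uses
    ``attenuate=False`` regardless of these values).
    """

    sound_speed: float = 1500.0      # m/s
    density: float = 1000.0          # kg/m^3
    attenuation_a0: float = 0.1      # dB/cm at 1 MHz
    attenuation_gamma: float = 1.2   # dimensionless

    def __post_init__(self) -> None:
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("sound_speed and density must be positive")
        if self.attenuation_a0 < 0:
            raise ValueError("attenuation_a0 must be >= 0")
        if not (1.0 <= self.attenuation_gamma <= 1.9):
            raise ValueError("attenuation_gamma outside the physical 1.0-1.9 range")

    def wavelength_mm(self, frequency_mhz: float) -> float:
        return self.sound_speed / frequency_mhz / 1000.0

    def wavenumber_per_mm(self, frequency_mhz: float) -> float:
        return 2.0 * np.pi / self.wavelength_mm(frequency_mhz)


@dataclass(frozen=True)
class FieldGrid:
    """Regular sampling plane for pressure fields.

    ``plane="xy"``: lateral plane at z = depth, axes (x, y), the grid is
    centred on the beam axis.  ``plane="xz"``: axial plane at y = offset,
    axes (x, z) with z centred on ``depth``.  ``extent`` holds the two full
    side lengths in mm; ``spacing`` is a scalar or a per-axis pair.
    """

    plane: str = "xy"
    extent: tuple[float, float] = (1.5, 1.5)
    spacing: float | tuple[float, float] = 0.01
    depth: float = 7.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.plane not in ("xy", "xz"):
            raise ValueError("plane must be 'xy' or 'xz'")
        if min(self.spacings) <= 0 or min(self.extent) <= 0:
            raise ValueError("spacing and extents must be positive")

    @property
    def spacings(self) -> tuple[float, float]:
        if np.isscalar(self.spacing):
            return (float(self.spacing), float(self.spacing))
        return tuple(float(s) for s in self.spacing)  # type: ignore[return-value]

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """The two in-plane coordinate axes (first = x, second = y or z)."""
        out = []
        for i, (ext, du) in enumerate(zip(self.extent, self.spacings)):
            n = int(round(ext / du)) + 1
            u = (np.arange(n) - (n - 1) / 2.0) * du
            if self.plane == "xz" and i == 1:
                u = u + self.depth
            out.append(u)
        return out[0], out[1]

    @property
    def shape(self) -> tuple[int, int]:
        a, b = self.axes()
        return len(b), len(a)  # rows = second axis, cols = first axis

    def points(self) -> np.ndarray:
        """All grid points as an (M, 3) array, row-major over (second, first) axes."""
        a, b = self.axes()
        bb, aa = np.meshgrid(b, a, indexing="ij")
        if self.plane == "xy":
            z = np.full(aa.size, self.depth)
            return np.column_stack([aa.ravel(), bb.ravel(), z])
        y = np.full(aa.size, self.offset)
        return np.column_stack([aa.ravel(), y, bb.ravel()])


@dataclass
class ExcitationVector:
    """Complex element drive amplitudes (velocity amplitudes), one per element."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("excitation contains non-finite entries")

    def __len__(self) -> int:
        return len(self.values)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    def to_csv(self, path) -> None:
        table = np.column_stack([np.arange(len(self)), self.amplitude, self.phase])
        np.savetxt(
            path,
            table,
            delimiter=",",
            header="element_id,amp,phase_rad",
            comments="",
            fmt=["%d", "%.12g", "%.12g"],
        )


@dataclass
class PropagationOperator:
    """The complex M x N forward matrix H with its provenance."""

    matrix: np.ndarray
    field_points: np.ndarray
    geometry: ArrayGeometry
    medium: Medium
    frequency: float  # MHz
    attenuated: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


@dataclass
class PressureField:
    """Complex pressure sampled on a FieldGrid (shape = grid.shape)."""

    grid: FieldGrid
    pressure: np.ndarray
    excitation_ref: str = ""

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.pressure)

    def db_map(self, floor_db: float = -60.0) -> np.ndarray:
        """Magnitude in dB re the grid peak (0 dB at max), clipped at floor_db."""
        mag = self.magnitude
        peak = mag.max()
        if peak == 0:
            return np.full_like(mag, floor_db)
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(mag / peak)
        return np.clip(db, floor_db, 0.0)


@dataclass
class BeamMetrics:
    """-level_db beam widths through the intensity peak of a sampled field."""

    peak_point: np.ndarray          # 3-D location of the sampled peak, mm
    peak_pressure: float
    widths: dict                    # axis label -> width in mm (inf if unresolved)
    level_db: float
    unresolved: tuple = ()          # axes whose crossings fell outside the grid

    @property
    def lateral_width(self) -> float:
        return self.widths["x"]


def _pairwise_distances(points: np.ndarray, sources: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - sources[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def _kernel_block(
    points: np.ndarray,
    geometry: ArrayGeometry,
    medium: Medium,
    frequency: float,
    attenuate: bool,
    obliquity: bool = False,
) -> np.ndarray:
    k = medium.wavenumber_per_mm(frequency)
    d = _pairwise_distances(points, geometry.positions)
    scale = max(1.0, float(np.abs(points).max(initial=1.0)))
    tol = 10.0 * np.finfo(float).eps * scale
    if d.min() <= tol:
        m, n = np.unravel_index(int(np.argmin(d)), d.shape)
        raise SingularDistanceError(
            f"field point {points[m]} coincides with element {n} at {geometry.positions[n]}"
        )
    const = 1j * medium.density * medium.sound_speed * k / (2.0 * np.pi)
    h = const * geometry.areas[None, :] * np.exp(-1j * k * d) / d
    if attenuate:
        alpha = attenuation_np_per_mm(
            frequency, medium.attenuation_a0, medium.attenuation_gamma
        )
        h = h * np.exp(-alpha * d)
    if obliquity:
        # cosine of the angle between the element normal and the line of
        # sight; pure point sources (the default) omit this factor
        diff = points[:, None, :] - geometry.positions[None, :, :]
        cos = np.einsum("mnk,nk->mn", diff, geometry.normals) / d
        h = h * np.clip(cos, 0.0, None)
    return h


def build_propagator(
    geometry: ArrayGeometry,
    points: np.ndarray,
    medium: Medium,
    frequency: float,
    attenuate: bool = False,
    obliquity: bool = False,
) -> PropagationOperator:
    """Assemble H mapping element excitations to pressures at ``points``."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    h = _kernel_block(points, geometry, medium, frequency, attenuate, obliquity)
    return PropagationOperator(
        matrix=h,
        field_points=points,
        geometry=geometry,
        medium=medium,
        frequency=frequency,
        attenuated=attenuate,
    )


def evaluate_field(
    geometry: ArrayGeometry,
    excitation,
    grid: FieldGrid,
    medium: Medium,
    frequency: float,
    attenuate: bool = False,
    excitation_ref: str = "",
) -> PressureField:
    """P = H U sampled on a grid, evaluated in blocks to bound memory."""
    u = np.asarray(excitation, dtype=complex).ravel()
    if len(u) != geometry.n:
        raise ValueError(f"excitation length {len(u)} != element count {geometry.n}")
    points = grid.points()
    out = np.empty(len(points), dtype=complex)
    for start in range(0, len(points), _CHUNK):
        block = points[start : start + _CHUNK]
        out[start : start + _CHUNK] = _kernel_block(
            block, geometry, medium, frequency, attenuate
        ) @ u
    return PressureField(
        grid=grid, pressure=out.reshape(grid.shape), excitation_ref=excitation_ref
    )


def conjugate_focus_excitation(
    geometry: ArrayGeometry, focus, medium: Medium, frequency: float
) -> ExcitationVector:
    """Unit-amplitude conjugate-phase drive focusing on a single point.

    Each element is phased ``+k d`` so all spherical wavelets arrive at the
    focus in phase (the discrete acoustic lens).
    """
    focus = np.asarray(focus, dtype=float)
    k = medium.wavenumber_per_mm(frequency)
    d = np.linalg.norm(geometry.positions - focus[None, :], axis=1)
    return ExcitationVector(np.exp(1j * k * d))


def _interp_crossing(u: np.ndarray, values: np.ndarray, i_peak: int, thresh: float):
    """Positions where ``values`` crosses ``thresh`` on both sides of i_peak."""
    left = None
    for i in range(i_peak, 0, -1):
        if values[i - 1] < thresh <= values[i]:
            f = (thresh - values[i - 1]) / (values[i] - values[i - 1])
            left = u[i - 1] + f * (u[i] - u[i - 1])
            break
    right = None
    for i in range(i_peak, len(values) - 1):
        if values[i + 1] < thresh <= values[i]:
            f = (thresh - values[i + 1]) / (values[i] - values[i + 1])
            right = u[i + 1] - f * (u[i + 1] - u[i])
            break
    return left, right


def measure_beam_widths(field: PressureField, level_db: float = -3.0) -> BeamMetrics:
    """Beam widths through the intensity peak at ``level_db`` re peak.

    Widths are taken along each principal grid axis through the global
    intensity maximum, with linear interpolation of the |P|^2 crossing
    between samples; the -3 dB intensity width is the FWHM.  A crossing
    that never occurs inside the grid marks that axis "unresolved" and the
    width is reported as +inf (i.e. >= the grid extent).
    """
    intensity = field.magnitude**2
    rows, cols = intensity.shape
    ir, ic = np.unravel_index(int(np.argmax(intensity)), intensity.shape)
    if ir in (0, rows - 1) or ic in (0, cols - 1):
        raise FocusOutsideGridError("intensity peak lies on the grid border")
    ax_a, ax_b = field.grid.axes()  # cols axis, rows axis
    thresh = intensity[ir, ic] * 10.0 ** (level_db / 10.0)

    labels = ("x", "y") if field.grid.plane == "xy" else ("x", "z")
    widths: dict[str, float] = {}
    unresolved = []
    for label, u, profile in (
        (labels[0], ax_a, intensity[ir, :]),
        (labels[1], ax_b, intensity[:, ic]),
    ):
        i_peak = ic if label == labels[0] else ir
        lo, hi = _interp_crossing(u, profile, i_peak, thresh)
        if lo is None or hi is None:
            widths[label] = np.inf
            unresolved.append(label)
        else:
            widths[label] = hi - lo

    if field.grid.plane == "xy":
        peak = np.array([ax_a[ic], ax_b[ir], field.grid.depth])
    else:
        peak = np.array([ax_a[ic], field.grid.offset, ax_b[ir]])
    return BeamMetrics(
        peak_point=peak,
        peak_pressure=float(field.magnitude[ir, ic]),
        widths=widths,
        level_db=level_db,
        unresolved=tuple(unresolved),
    )
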