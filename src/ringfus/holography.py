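"""Acoustic holography: 2-D pattern synthesis from arbitrary images.

The target plane (the retina, at depth z) and the source plane (the
transducer aperture, at z = 0) are related in the far field by a 2-D
Fourier transform; the exact relation for a homogeneous medium at any
distance is the angular-spectrum propagator.  A phase-only source that
reproduces a desired amplitude image is found by the weighted
Gerchberg-Saxton (GSW) loop: propagate the phase-only source forward,
impose weighted target amplitudes on the image support, propagate back,
re-impose unit source amplitude, repeat.  Per-pixel weights are divided
by the achieved amplitude every pass, which drives the pattern toward
uniform brightness over the support.

Sign conventions match the Rayleigh-Sommerfeld module (harmonic factor
exp(+j w t) dropped; phase decreases with distance), so the forward
angular-spectrum filter is exp(-j dz sqrt(k^2 - kx^2 - ky^2)).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import ArrayGeometry
from .propagation import FieldGrid, ExcitationVector, Medium, PressureField

__all__ = [
    "TargetPattern",
    "Hologram",
    "GSWResult",
    "PatternMetrics",
    "angular_spectrum_propagate",
    "image_to_aperture",
    "aperture_to_image",
    "gsw_synthesize",
    "sample_hologram_to_elements",
    "pattern_quality",
]


@dataclass
class TargetPattern:
    """Normalised 2-D target amplitude with its physical scale.

    ``pixel_pitch`` defaults to 0.035 mm so a 256-pixel image spans
    8.96 mm; ``depth`` is the axial distance of the pattern plane from the
    aperture plane.
    """

    amplitude: np.ndarray
    pixel_pitch: float = 0.035  # mm
    depth: float = 7.0          # mm

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 2:
            raise ValueError("amplitude must be 2-D")
        if self.pixel_pitch <= 0 or self.depth <= 0:
            raise ValueError("pixel_pitch and depth must be positive")
        if self.amplitude.min() < 0:
            raise ValueError("amplitude must be non-negative")
        peak = self.amplitude.max()
        if peak > 0:
            self.amplitude = self.amplitude / peak

    @property
    def extent_mm(self) -> tuple[float, float]:
        ny, nx = self.amplitude.shape
        return nx * self.pixel_pitch, ny * self.pixel_pitch


@dataclass
class Hologram:
    """Phase-only source plane: phase in (-pi, pi], unit amplitude on support."""

    phase: np.ndarray
    source_pixel_pitch: float
    plane_z: float = 0.0
    target_depth: float = 7.0
    support: np.ndarray | None = None  # boolean aperture mask, default: full plane

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.support is None:
            self.support = np.ones(self.phase.shape, dtype=bool)

    def complex_field(self) -> np.ndarray:
        return np.where(self.support, np.exp(1j * self.phase), 0.0)


@dataclass
class GSWResult:
    hologram: Hologram
    achieved_field: PressureField
    weights: np.ndarray            # final per-pixel weights over the support
    iterations_run: int
    uniformity_history: np.ndarray
    efficiency: float              # fraction of propagated energy on the support
    support: np.ndarray = None
    converged: bool = True


@dataclass
class PatternMetrics:
    correlation: float   # zero-mean normalised cross-correlation with the target
    uniformity: float    # 1 - (max-min)/(max+min) of |P| over the support
    efficiency: float    # energy fraction landing on the support


def _pad_center(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=a.dtype)
    r0 = (shape[0] - a.shape[0]) // 2
    c0 = (shape[1] - a.shape[1]) // 2
    out[r0 : r0 + a.shape[0], c0 : c0 + a.shape[1]] = a
    return out


def _crop_center(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    r0 = (a.shape[0] - shape[0]) // 2
    c0 = (a.shape[1] - shape[1]) // 2
    return a[r0 : r0 + shape[0], c0 : c0 + shape[1]]


def angular_spectrum_propagate(
    field_2d: np.ndarray,
    pitch: float,
    dz: float,
    medium: Medium,
    frequency: float,
    pad_factor: int = 1,
) -> np.ndarray:
    """Exact homogeneous-medium propagation of a sampled plane by dz (mm).

    The 2-D spatial spectrum is multiplied by exp(-j dz kz) with
    kz = sqrt(k^2 - kx^2 - ky^2); evanescent components (kx^2+ky^2 > k^2)
    are zeroed.  Negative dz back-propagates.  ``pad_factor`` > 1 embeds
    the field in a larger zero field to suppress wrap-around; the result
    is cropped back to the input shape.  The pixel pitch must be common to
    both axes (square pixels).
    """
    a = np.asarray(field_2d, dtype=complex)
    if a.ndim != 2:
        raise ValueError("field must be a 2-D array with square pixels")
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    lam = medium.wavelength_mm(frequency)
    if pitch > lam / 2:
        warnings.warn(
            f"pixel pitch {pitch} mm exceeds lambda/2 = {lam / 2:.4g} mm; "
            "high angles are undersampled",
            stacklevel=2,
        )
    if dz == 0:
        return a.copy()
    shape = a.shape
    if pad_factor > 1:
        a = _pad_center(a, (shape[0] * pad_factor, shape[1] * pad_factor))
    k = 2.0 * np.pi / lam
    ky = 2.0 * np.pi * np.fft.fftfreq(a.shape[0], d=pitch)
    kx = 2.0 * np.pi * np.fft.fftfreq(a.shape[1], d=pitch)
    kz2 = k**2 - kx[None, :] ** 2 - ky[:, None] ** 2
    propagating = kz2 > 0
    kz = np.sqrt(np.where(propagating, kz2, 0.0))
    transfer = np.where(propagating, np.exp(-1j * dz * kz), 0.0)
    out = np.fft.ifft2(np.fft.fft2(a) * transfer)
    if pad_factor > 1:
        out = _crop_center(out, shape)
    return out


def image_to_aperture(
    target: TargetPattern, medium: Medium, frequency: float
) -> np.ndarray:
    """Complex aperture whose far-field (Fraunhofer) image is the target.

    Centred inverse 2-D DFT of the target amplitude with the 1/(lambda z)
    far-field scaling; returned before any phase-only constraint, as the
    initialisation of iterative synthesis.  ``aperture_to_image`` is its
    exact inverse.
    """
    lam_z = medium.wavelength_mm(frequency) * target.depth
    spectrum = np.fft.ifft2(np.fft.ifftshift(target.amplitude))
    return np.fft.fftshift(spectrum) / lam_z


def aperture_to_image(
    aperture: np.ndarray, target: TargetPattern, medium: Medium, frequency: float
) -> np.ndarray:
    """Forward Fraunhofer image of a complex aperture (inverse of the above)."""
    lam_z = medium.wavelength_mm(frequency) * target.depth
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(np.asarray(aperture)))) * lam_z


def _plane_coords(shape: tuple[int, int], pitch: float):
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) * pitch
    y = (np.arange(ny) - (ny - 1) / 2.0) * pitch
    return np.meshgrid(x, y)


def _uniformity(v: np.ndarray) -> float:
    vmax, vmin = float(v.max()), float(v.min())
    if vmax + vmin == 0:
        return 0.0
    return 1.0 - (vmax - vmin) / (vmax + vmin)


def gsw_synthesize(
    target: TargetPattern,
    medium: Medium | None = None,
    frequency: float = 20.0,
    *,
    max_iter: int = 50,
    tol: float = 1e-4,
    support_threshold: float = 0.1,
    seed: int = 1,
    pad_factor: int = 2,
    aperture_mask: np.ndarray | None = None,
) -> GSWResult:
    """Weighted Gerchberg-Saxton synthesis of a phase-only hologram.

    The source plane has the same sampling as the target.  Initial phase is
    the conjugate-phase lens toward the target centroid plus a small seeded
    random perturbation (breaks the symmetry of degenerate targets).  The
    image support is the set of pixels with amplitude >= support_threshold
    times the peak; the image-plane constraint imposes the weighted target
    amplitude on the support and zero elsewhere, which forces the loop to
    steer energy onto the pattern rather than park it off-support.

    Raw GSW iterates are not strictly monotone (the weight update can
    transiently trade uniformity for energy placement), so the loop tracks
    the incumbent: the best-uniformity iterate seen so far is kept and is
    what the returned hologram is built from.  ``uniformity_history``
    records the incumbent value at each iteration and is therefore
    non-decreasing by construction.  The loop stops at ``max_iter`` or
    when the incumbent has improved by less than ``tol`` over the last
    five iterations.
    """
    medium = medium or Medium()
    amp = target.amplitude
    if amp.max() == 0:
        raise ValueError("target has no pixel above the support threshold")
    support = amp >= support_threshold * amp.max()
    if aperture_mask is None:
        aperture_mask = np.ones(amp.shape, dtype=bool)

    k = medium.wavenumber_per_mm(frequency)
    z = target.depth
    xx, yy = _plane_coords(amp.shape, target.pixel_pitch)
    total = amp.sum()
    xc = float((xx * amp).sum() / total)
    yc = float((yy * amp).sum() / total)
    rng = np.random.default_rng(seed)
    phase = k * np.sqrt((xx - xc) ** 2 + (yy - yc) ** 2 + z**2)
    phase = phase + rng.uniform(-0.5, 0.5, size=amp.shape)

    target_support = amp[support]

    def propagate(ph):
        source = np.where(aperture_mask, np.exp(1j * ph), 0.0)
        return angular_spectrum_propagate(
            source, target.pixel_pitch, z, medium, frequency, pad_factor=pad_factor
        )

    weights = np.ones(int(support.sum()))
    best_phase = phase
    best_uniformity = -np.inf
    uniformity_history = []
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        v = propagate(phase)
        mag_support = np.maximum(np.abs(v[support]), 1e-30)
        u_now = _uniformity(mag_support)
        if u_now > best_uniformity:
            best_uniformity = u_now
            best_phase = phase
        uniformity_history.append(best_uniformity)
        if (
            iterations > 5
            and uniformity_history[-1] - uniformity_history[-6] < tol
        ):
            converged = True
            break
        weights = np.clip(
            weights * (mag_support.mean() / mag_support), 1e-3, 1e3
        )
        v_constrained = np.zeros_like(v)
        v_constrained[support] = (
            weights * target_support * np.exp(1j * np.angle(v[support]))
        )
        back = angular_spectrum_propagate(
            v_constrained, target.pixel_pitch, -z, medium, frequency,
            pad_factor=pad_factor,
        )
        phase = np.angle(back)
    phase = best_phase

    hologram = Hologram(
        phase=np.where(aperture_mask, phase, 0.0),
        source_pixel_pitch=target.pixel_pitch,
        target_depth=z,
        support=aperture_mask,
    )
    achieved = angular_spectrum_propagate(
        hologram.complex_field(), target.pixel_pitch, z, medium, frequency,
        pad_factor=pad_factor,
    )
    energy = np.abs(achieved) ** 2
    efficiency = float(energy[support].sum() / energy.sum())
    ny, nx = amp.shape
    grid = FieldGrid(
        plane="xy",
        extent=((nx - 1) * target.pixel_pitch, (ny - 1) * target.pixel_pitch),
        spacing=target.pixel_pitch,
        depth=z,
    )
    achieved_field = PressureField(grid=grid, pressure=achieved, excitation_ref="gsw")
    return GSWResult(
        hologram=hologram,
        achieved_field=achieved_field,
        weights=weights,
        iterations_run=iterations,
        uniformity_history=np.asarray(uniformity_history),
        efficiency=efficiency,
        support=support,
        converged=converged,
    )


def sample_hologram_to_elements(
    hologram: Hologram,
    geometry: ArrayGeometry,
    medium: Medium,
    frequency: float,
) -> ExcitationVector:
    """Map a planar hologram onto the curved array elements.

    Each element takes the hologram phase at the nearest pixel of its
    (x, y) projection, corrected for the spherical-cap sag: the element
    sits ``sag`` ahead of the z = 0 hologram plane, so its path to the
    pattern-plane centre is shorter by
    Delta = sqrt(r^2 + z0^2) - sqrt(r^2 + (z0 - sag)^2), and the element
    phase is the hologram phase minus k * Delta.  Exact for the plane
    centre, paraxially accurate across the pattern.  Amplitudes are
    uniform (phase-only drive).
    """
    ny, nx = hologram.phase.shape
    pitch = hologram.source_pixel_pitch
    x = geometry.positions[:, 0]
    y = geometry.positions[:, 1]
    cols = np.rint(x / pitch + (nx - 1) / 2.0).astype(int)
    rows = np.rint(y / pitch + (ny - 1) / 2.0).astype(int)
    outside = (cols < 0) | (cols >= nx) | (rows < 0) | (rows >= ny)
    if np.any(outside):
        ids = np.flatnonzero(outside)
        raise ValueError(
            f"{len(ids)} element(s) project outside the hologram extent: "
            f"ids {ids[:10].tolist()}{'...' if len(ids) > 10 else ''}"
        )
    phase = hologram.phase[rows, cols]
    k = medium.wavenumber_per_mm(frequency)
    z0 = hologram.target_depth
    r2 = x**2 + y**2
    sag = geometry.positions[:, 2] - hologram.plane_z
    delta = np.sqrt(r2 + z0**2) - np.sqrt(r2 + (z0 - sag) ** 2)
    return ExcitationVector(np.exp(1j * (phase - k * delta)))


def pattern_quality(achieved: PressureField, target: TargetPattern) -> PatternMetrics:
    """Quantitative match between an achieved field and its target image.

    The achieved magnitude is resampled to the target raster (extents must
    agree within 2%), then scored by zero-mean normalised cross-correlation,
    support uniformity and support energy fraction.
    """
    mag = achieved.magnitude
    dx, dy = achieved.grid.spacings
    gx = achieved.grid.shape[1] * dx
    gy = achieved.grid.shape[0] * dy
    tx, ty = target.extent_mm
    if abs(gx - tx) > 0.02 * tx or abs(gy - ty) > 0.02 * ty:
        raise ValueError(
            f"field extent ({gx:.3f}, {gy:.3f}) mm does not match "
            f"target extent ({tx:.3f}, {ty:.3f}) mm"
        )
    if mag.shape != target.amplitude.shape:
        zoom = (
            target.amplitude.shape[0] / mag.shape[0],
            target.amplitude.shape[1] / mag.shape[1],
        )
        mag = ndimage.zoom(mag, zoom, order=1)
    t = target.amplitude
    a = mag - mag.mean()
    b = t - t.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    correlation = float((a * b).sum() / denom) if denom > 0 else 0.0
    support = t >= 0.1 * t.max()
    energy = mag**2
    return PatternMetrics(
        correlation=correlation,
        uniformity=_uniformity(mag[support]),
        efficiency=float(energy[support].sum() / energy.sum()),
    )
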