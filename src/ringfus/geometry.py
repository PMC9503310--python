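"""Annular ("racing ring") transducer layout on a spherical cap.

The array sits on a sphere whose curvature matches the eyeball, with a
central hole so the beam bypasses the crystalline lens.  Coordinate
convention used everywhere in this package: lengths in millimetres, the
cap apex at the origin, the beam propagating along +z, and the sphere
centre at ``(0, 0, curvature_radius)``.  The stimulation plane lives at
``z = depth`` (7 mm by default for the rat eye).

Elements are modelled as point sources placed on a square x-y lattice
(spacing = ``pitch``) projected onto the cap; the physical element size
enters only through the per-element area factor that scales each
element's source strength.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RingArraySpec",
    "ArrayGeometry",
    "EmptyGeometryError",
    "InfeasibleSpecError",
    "build_candidate_grid",
    "sparsify",
    "build_ring_geometry",
]

log = logging.getLogger(__name__)

GEOMETRY_CSV_HEADER = "element_id,x_mm,y_mm,z_mm,nx,ny,nz,area_mm2"


class EmptyGeometryError(ValueError):
    """The annulus holds no lattice point at the requested pitch."""


class InfeasibleSpecError(ValueError):
    """More elements requested than candidate lattice sites available."""


@dataclass(frozen=True)
class RingArraySpec:
    """Design parameters of the ring array.

    Defaults are the reference design: OD 11 mm, ID 9 mm, 512 elements at
    0.075 mm pitch (one wavelength at 20 MHz in water-like media) on a cap
    of 12 mm radius of curvature.
    """

    outer_diameter: float = 11.0   # mm
    inner_diameter: float = 9.0    # mm
    curvature_radius: float = 12.0  # mm
    n_elements: int = 512
    pitch: float = 0.075           # mm, lattice spacing of candidate sites
    element_size: float = 0.15     # mm, square element edge (area factor only)
    center_frequency: float = 20.0  # MHz
    sparsify_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.inner_diameter < self.outer_diameter):
            raise ValueError(
                f"need 0 <= ID < OD, got ID={self.inner_diameter}, OD={self.outer_diameter}"
            )
        if self.outer_diameter > 2.0 * self.curvature_radius:
            raise ValueError("outer diameter exceeds the sphere diameter")
        if self.n_elements < 1:
            raise ValueError("n_elements must be >= 1")
        if self.pitch <= 0 or self.element_size <= 0:
            raise ValueError("pitch and element_size must be positive")


@dataclass
class ArrayGeometry:
    """Element positions/normals/areas of a built array.

    ``positions`` is (N, 3) in mm, ``normals`` (N, 3) unit vectors pointing
    from each element toward the sphere centre (into the eye), ``areas``
    (N,) in mm^2.  ``candidate_count`` records the size of the full lattice
    the elements were drawn from, so the realised sparsity is reproducible
    from the geometry alone.
    """

    positions: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    spec: RingArraySpec
    candidate_count: int = 0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        self.areas = np.asarray(self.areas, dtype=float)
        if self.positions.shape != self.normals.shape:
            raise ValueError("positions and normals must have matching shapes")
        if len(self.areas) != len(self.positions):
            raise ValueError("areas length must match positions")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def realized_sparsity(self) -> float:
        """Fraction of candidate lattice sites populated (0 if unknown)."""
        return self.n / self.candidate_count if self.candidate_count else 0.0

    def to_csv(self, path) -> None:
        table = np.column_stack(
            [np.arange(self.n), self.positions, self.normals, self.areas]
        )
        np.savetxt(
            path,
            table,
            delimiter=",",
            header=GEOMETRY_CSV_HEADER,
            comments="",
            fmt=["%d"] + ["%.12g"] * 7,
        )

    @classmethod
    def from_csv(cls, path, spec: RingArraySpec | None = None) -> "ArrayGeometry":
        table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(
            positions=table[:, 1:4],
            normals=table[:, 4:7],
            areas=table[:, 7],
            spec=spec or RingArraySpec(n_elements=len(table)),
        )


def _sag(r2: np.ndarray, curvature_radius: float) -> np.ndarray:
    """Axial drop z(r) of the spherical cap: z = R - sqrt(R^2 - r^2)."""
    return curvature_radius - np.sqrt(curvature_radius**2 - r2)


def build_candidate_grid(spec: RingArraySpec) -> np.ndarray:
    """All square-lattice sites inside the annulus, projected onto the cap.

    Sites are spaced by ``spec.pitch`` on a lattice centred at the origin,
    kept when ID/2 <= sqrt(x^2+y^2) <= OD/2, and lifted onto the sphere.
    Ordering is row-major (y outer, x inner), which makes the lattice, and
    hence any seeded subset of it, fully deterministic.
    """
    r_out = spec.outer_diameter / 2.0
    r_in = spec.inner_diameter / 2.0
    m = int(np.floor(r_out / spec.pitch))
    axis = np.arange(-m, m + 1) * spec.pitch
    yy, xx = np.meshgrid(axis, axis, indexing="ij")
    x = xx.ravel()
    y = yy.ravel()
    r2 = x**2 + y**2
    keep = (r2 >= r_in**2) & (r2 <= r_out**2)
    if not np.any(keep):
        raise EmptyGeometryError(
            f"annulus ID={spec.inner_diameter} mm, OD={spec.outer_diameter} mm "
            f"holds no lattice point at pitch {spec.pitch} mm"
        )
    x, y, r2 = x[keep], y[keep], r2[keep]
    z = _sag(r2, spec.curvature_radius)
    return np.column_stack([x, y, z])


def sparsify(candidates: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` candidate sites uniformly without replacement.

    The subset is a pure function of ``seed``; candidate ordering is
    preserved in the output.
    """
    candidates = np.asarray(candidates)
    if n > len(candidates):
        raise InfeasibleSpecError(
            f"requested {n} elements but only {len(candidates)} candidate sites exist"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(candidates), size=n, replace=False))
    return candidates[idx]


def build_ring_geometry(
    spec: RingArraySpec, area_mode: str = "element_size"
) -> ArrayGeometry:
    """Construct the sparse ring geometry for a design spec.

    ``area_mode`` selects the per-element area factor:

    - ``"element_size"`` (default): the physical radiating area
      ``element_size**2`` of every element;
    - ``"surface_cell"``: the cap surface tile ``pitch**2 / cos(theta)``
      each lattice site represents, appropriate when a dense non-sparse
      lattice is used to approximate a continuously driven bowl.
    """
    candidates = build_candidate_grid(spec)
    positions = sparsify(candidates, spec.n_elements, spec.sparsify_seed)
    center = np.array([0.0, 0.0, spec.curvature_radius])
    normals = (center - positions) / spec.curvature_radius
    if area_mode == "element_size":
        areas = np.full(len(positions), spec.element_size**2)
    elif area_mode == "surface_cell":
        cos_theta = (spec.curvature_radius - positions[:, 2]) / spec.curvature_radius
        areas = spec.pitch**2 / cos_theta
    else:
        raise ValueError(f"unknown area_mode {area_mode!r}")
    geom = ArrayGeometry(
        positions=positions,
        normals=normals,
        areas=areas,
        spec=spec,
        candidate_count=len(candidates),
    )
    log.info(
        "ring geometry: %d/%d lattice sites kept (fraction %.4f), seed=%d",
        geom.n,
        geom.candidate_count,
        geom.realized_sparsity,
        spec.sparsify_seed,
    )
    return geom


def single_element_geometry(
    position, area: float = 0.0225, normal=(0.0, 0.0, 1.0)
) -> ArrayGeometry:
    """A one-element geometry, handy for point-source checks."""
    spec = RingArraySpec(n_elements=1)
    return ArrayGeometry(
        positions=np.atleast_2d(np.asarray(position, dtype=float)),
        normals=np.atleast_2d(np.asarray(normal, dtype=float)),
        areas=np.array([area]),
        spec=spec,
    )
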