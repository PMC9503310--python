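"""File I/O helpers: grayscale images, HDF5 field export, YAML configs."""
from __future__ import annotations

import numpy as np

from .geometry import RingArraySpec
from .propagation import Medium, PressureField

__all__ = [
    "read_grayscale",
    "write_grayscale",
    "write_pgm_ascii",
    "field_to_hdf5",
    "field_to_csv",
    "load_config",
]


def read_grayscale(path) -> np.ndarray:
    """Load a PNG/PGM image as a float array in [0, 1] (RGB is averaged)."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("F"), dtype=float)
    peak = arr.max()
    return arr / peak if peak > 0 else arr


def write_grayscale(path, array: np.ndarray) -> None:
    """Save a float array (any range) as an 8-bit grayscale PNG/PGM."""
    from PIL import Image

    a = np.asarray(array, dtype=float)
    lo, hi = a.min(), a.max()
    scaled = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
    Image.fromarray((scaled * 255).round().astype(np.uint8)).save(path)


def write_pgm_ascii(path, array: np.ndarray) -> None:
    """Plain-text (P2) PGM of a float array scaled to 0-255."""
    a = np.asarray(array, dtype=float)
    lo, hi = a.min(), a.max()
    scaled = np.zeros_like(a) if hi == lo else (a - lo) / (hi - lo)
    pixels = (scaled * 255).round().astype(int)
    with open(path, "w") as fh:
        fh.write(f"P2\n{a.shape[1]} {a.shape[0]}\n255\n")
        for row in pixels:
            fh.write(" ".join(map(str, row)) + "\n")


def field_to_hdf5(path, field: PressureField, medium: Medium, seed: int = 0) -> None:
    import h5py

    ax_a, ax_b = field.grid.axes()
    labels = ("x_mm", "y_mm") if field.grid.plane == "xy" else ("x_mm", "z_mm")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("pressure_real", data=field.pressure.real)
        fh.create_dataset("pressure_imag", data=field.pressure.imag)
        fh.create_dataset(labels[0], data=ax_a)
        fh.create_dataset(labels[1], data=ax_b)
        fh.attrs["plane"] = field.grid.plane
        fh.attrs["depth_mm"] = field.grid.depth
        fh.attrs["c_mps"] = medium.sound_speed
        fh.attrs["seed"] = seed


def field_to_csv(path, field: PressureField) -> None:
    pts = field.grid.points()
    p = field.pressure.ravel()
    table = np.column_stack([pts, p.real, p.imag])
    np.savetxt(
        path, table, delimiter=",", header="x_mm,y_mm,z_mm,re,im", comments="",
        fmt="%.9g",
    )


def load_config(path) -> tuple[RingArraySpec, Medium]:
    """Read array/medium parameters from a YAML file.

    Expected layout (all keys optional, defaults apply)::

        array:
          outer_diameter: 11.0
          ...
        medium:
          sound_speed: 1500.0
          ...
    """
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    spec = RingArraySpec(**(cfg.get("array") or {}))
    medium = Medium(**(cfg.get("medium") or {}))
    return spec, medium
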