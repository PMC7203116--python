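"""Reading and writing projection images and spectra.

Two interchangeable on-disk forms: CCP4/MRC maps (via gemmi, stored as a
single-section volume) for interoperability with EM software, and a plain
whitespace-separated text grid with a one-line header for desk-scale work.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .diffraction import ProjectionImage


def write_image_mrc(image: ProjectionImage, path) -> None:
    """Write an image as a single-section MRC/CCP4 map (mode 2, float32)."""
    # gemmi's FloatGrid takes (nu, nv, nw); store rows->u, cols->v, one section.
    grid = np.ascontiguousarray(image.grid[:, :, None], dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(grid)
    nu, nv, nw = grid.shape
    m.grid.unit_cell = gemmi.UnitCell(
        nu * image.pixel_size, nv * image.pixel_size, image.pixel_size,
        90, 90, 90,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_image_mrc(path) -> ProjectionImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    m = gemmi.read_ccp4_map(str(path))
    arr = np.squeeze(np.array(m.grid, copy=True))
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-section image map")
    pixel = m.grid.unit_cell.a / m.grid.nu
    return ProjectionImage(grid=np.asarray(arr, dtype=float), pixel_size=pixel)


def write_image_text(image: ProjectionImage, path) -> None:
    """Plain text grid: '# pixel_size <Å>' header then rows of intensities."""
    with open(path, "w") as fh:
        fh.write(f"# pixel_size {image.pixel_size!r}\n")
        np.savetxt(fh, image.grid)


def read_image_text(path) -> ProjectionImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3 or header[1] != "pixel_size":
            raise ValueError(f"{path}: expected '# pixel_size <value>' header")
        pixel = float(header[2])
        grid = np.loadtxt(fh)
    return ProjectionImage(grid=grid, pixel_size=pixel)


def read_image(path) -> ProjectionImage:
    """Dispatch on extension: .mrc/.map to MRC, anything else to text."""
    suffix = Path(path).suffix.lower()
    if suffix in (".mrc", ".map", ".ccp4"):
        return read_image_mrc(path)
    return read_image_text(path)
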