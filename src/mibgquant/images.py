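"""Planar count images: in-memory container and portable fixture I/O.

Anterior planar acquisitions are 256x256 count matrices.  The portable
fixture format is an ASCII portable graymap (PGM, magic ``P2``, 16-bit
maxval) next to a ``<stem>.meta`` key-value sidecar carrying the
acquisition minute and collimator id — both plain text, so fixtures
survive any transport.  Single-frame DICOM ingestion is available when
pydicom is installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError

__all__ = ["FRAME_SHAPE", "PlanarImage", "read_pgm", "write_pgm", "read_dicom"]

#: Required planar matrix size.
FRAME_SHAPE: tuple[int, int] = (256, 256)


@dataclass
class PlanarImage:
    """A 256x256 non-negative count grid with acquisition metadata."""

    grid: np.ndarray
    acquisition_minute: float
    collimator_id: str = "MEGP"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != FRAME_SHAPE:
            raise ValidationError(
                f"planar image must be {FRAME_SHAPE[0]}x{FRAME_SHAPE[1]}, got {self.grid.shape}"
            )
        if np.any(self.grid < 0):
            raise ValidationError("planar image contains negative counts")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta")


def write_pgm(image: PlanarImage, path: str | Path) -> None:
    """Write an ASCII (P2) 16-bit PGM plus its ``.meta`` sidecar.

    Counts are rounded to the nearest integer and clipped at 65535, the
    PGM maxval.
    """
    path = Path(path)
    grid = np.clip(np.rint(image.grid), 0, 65535).astype(int)
    with open(path, "w") as fh:
        fh.write(f"P2\n{grid.shape[1]} {grid.shape[0]}\n65535\n")
        for row in grid:
            fh.write(" ".join(map(str, row)) + "\n")
    _meta_path(path).write_text(
        f"acquisition_minute: {image.acquisition_minute}\n"
        f"collimator_id: {image.collimator_id}\n"
    )


def read_pgm(path: str | Path) -> PlanarImage:
    """Read an ASCII PGM (with sidecar) or a bare whitespace integer grid."""
    path = Path(path)
    tokens = path.read_text().split()
    if tokens and tokens[0] == "P2":
        width, height = int(tokens[1]), int(tokens[2])
        data = np.array(tokens[4:], dtype=float)  # tokens[3] is maxval
    else:
        data = np.array(tokens, dtype=float)
        height = width = int(round(len(data) ** 0.5))
    if data.size != height * width:
        raise ValidationError(f"{path}: expected {height * width} pixels, found {data.size}")
    grid = data.reshape(height, width)

    acquisition_minute, collimator_id = 0.0, "MEGP"
    meta = _meta_path(path)
    if meta.exists():
        for line in meta.read_text().splitlines():
            if ":" not in line:
                continue
            key, value = (s.strip() for s in line.split(":", 1))
            if key == "acquisition_minute":
                acquisition_minute = float(value)
            elif key == "collimator_id":
                collimator_id = value
    return PlanarImage(grid, acquisition_minute, collimator_id)


def read_dicom(path: str | Path) -> PlanarImage:
    """Read a single-frame planar DICOM into the same contract.

    Requires pydicom (optional dependency).  The acquisition minute is
    taken from AcquisitionTime relative to RadiopharmaceuticalStartTime
    when both are present, else 0.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional path
        raise ImportError(
            "DICOM ingestion requires the optional dependency pydicom; "
            "install it or use the PGM fixture format"
        ) from exc

    ds = pydicom.dcmread(str(path))  # pragma: no cover - optional path
    grid = np.asarray(ds.pixel_array, dtype=float)

    def _seconds(hhmmss: str) -> float:
        h, m, s = int(hhmmss[0:2]), int(hhmmss[2:4]), float(hhmmss[4:] or 0)
        return 3600 * h + 60 * m + s

    minute = 0.0
    try:
        start = ds.RadiopharmaceuticalInformationSequence[0].RadiopharmaceuticalStartTime
        minute = (_seconds(str(ds.AcquisitionTime)) - _seconds(str(start))) / 60.0
    except (AttributeError, IndexError):
        pass
    return PlanarImage(grid, minute, getattr(ds, "CollimatorGridName", "UNKNOWN") or "UNKNOWN")
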