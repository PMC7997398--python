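"""Dataset file I/O: concatenated XYZ frames with energies and gradients.

Grammar (one frame, repeated)::

    <N>                                  atom count, integer
    E = <energy>                         comment line; energy in cm^-1
    <species> <x> <y> <z>                N coordinate lines
    GRADIENTS                            optional sentinel
    <gx> <gy> <gz>                       N gradient lines (cm^-1/bohr)

Coordinates are bohr by default; ``units="angstrom"`` converts coordinates
(Angstrom -> bohr) and gradients (cm^-1/Angstrom -> cm^-1/bohr) on read,
and the reverse on write.  Energies are opaque cm^-1 values (absolute or
relative to any reference the producer chose).
"""

from __future__ import annotations

import numpy as np

from .constants import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM
from .geometry import DataRecord, Dataset, Geometry

GRADIENT_SENTINEL = "GRADIENTS"
_UNITS = ("bohr", "angstrom")


class DatasetParseError(ValueError):
    """Malformed dataset file; the message names the offending line."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _check_units(units: str) -> None:
    if units not in _UNITS:
        raise ValueError(f"units must be one of {_UNITS}, got {units!r}")


def read_dataset(path, units: str = "bohr") -> Dataset:
    """Parse a dataset file; see module docstring for the grammar."""
    _check_units(units)
    with open(path) as fh:
        lines = fh.read().splitlines()
    records: list[DataRecord] = []
    n_expected: int | None = None
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():  # blank lines between frames tolerated
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise DatasetParseError(pos + 1, f"expected atom count, got {lines[pos]!r}")
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise DatasetParseError(
                pos + 1, f"inconsistent atom count {n} (first frame had {n_expected})"
            )
        if pos + 1 >= len(lines):
            raise DatasetParseError(pos + 2, "missing energy line")
        comment = lines[pos + 1]
        try:
            energy = float(comment.replace("E", "").replace("=", "").strip())
        except ValueError:
            raise DatasetParseError(pos + 2, f"no energy on comment line {comment!r}")
        if pos + 2 + n > len(lines):
            raise DatasetParseError(len(lines), f"truncated frame: expected {n} atoms")
        species, coords = [], []
        for k in range(n):
            parts = lines[pos + 2 + k].split()
            if len(parts) != 4:
                raise DatasetParseError(
                    pos + 3 + k, f"expected 'species x y z', got {lines[pos + 2 + k]!r}"
                )
            species.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:]])
            except ValueError:
                raise DatasetParseError(pos + 3 + k, "non-numeric coordinate")
        coords = np.array(coords)
        pos += 2 + n
        gradient = None
        if pos < len(lines) and lines[pos].strip() == GRADIENT_SENTINEL:
            pos += 1
            if pos + n > len(lines):
                raise DatasetParseError(
                    len(lines), f"truncated gradient block: expected {n} lines"
                )
            grad = []
            for k in range(n):
                parts = lines[pos + k].split()
                if len(parts) != 3:
                    raise DatasetParseError(
                        pos + 1 + k,
                        f"expected 3 gradient components, got {lines[pos + k]!r}",
                    )
                try:
                    grad.append([float(v) for v in parts])
                except ValueError:
                    raise DatasetParseError(pos + 1 + k, "non-numeric gradient")
            gradient = np.array(grad).ravel()
            pos += n
        if units == "angstrom":
            coords = coords * ANGSTROM_TO_BOHR
            if gradient is not None:
                gradient = gradient * BOHR_TO_ANGSTROM  # per-Angstrom -> per-bohr
        records.append(
            DataRecord(Geometry(tuple(species), coords), energy, gradient)
        )
    return Dataset(records)


def write_dataset(ds: Dataset, path, units: str = "bohr") -> None:
    """Write a dataset in the documented dialect (inverse of :func:`read_dataset`)."""
    _check_units(units)
    with open(path, "w") as fh:
        for rec in ds:
            g = rec.geometry
            fh.write(f"{g.n_atoms}\n")
            fh.write(f"E = {rec.energy:.10f}\n")
            coords = g.coords
            grad = rec.gradient
            if units == "angstrom":
                coords = coords * BOHR_TO_ANGSTROM
                if grad is not None:
                    grad = grad * ANGSTROM_TO_BOHR
            for sp, row in zip(g.species, coords):
                fh.write(f"{sp} {row[0]:.12f} {row[1]:.12f} {row[2]:.12f}\n")
            if grad is not None:
                fh.write(GRADIENT_SENTINEL + "\n")
                for row in grad.reshape(-1, 3):
                    fh.write(f"{row[0]:.10f} {row[1]:.10f} {row[2]:.10f}\n")


def read_geometry(path, units: str = "bohr") -> Geometry:
    """Read the first frame of an XYZ-style file as a bare geometry.

    The comment line need not carry an energy here.
    """
    _check_units(units)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines()]
    if not lines:
        raise DatasetParseError(1, "empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise DatasetParseError(1, f"expected atom count, got {lines[0]!r}")
    if len(lines) < 2 + n:
        raise DatasetParseError(len(lines), f"truncated frame: expected {n} atoms")
    species, coords = [], []
    for k in range(n):
        parts = lines[2 + k].split()
        if len(parts) != 4:
            raise DatasetParseError(3 + k, f"expected 'species x y z'")
        species.append(parts[0])
        coords.append([float(v) for v in parts[1:]])
    coords = np.array(coords)
    if units == "angstrom":
        coords = coords * ANGSTROM_TO_BOHR
    return Geometry(tuple(species), coords)
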