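"""Microplate geometry, well addressing, and section matrices.

Whole-body scanning PCR grids a frozen sagittal mouse section onto a
1536-well plate, lyses the exposed tissue well by well, and transfers the
lysates to a 384-well qPCR plate.  This module models the plate formats,
A1-style well addressing, the section matrix (the set of 1536-plate wells
actually covered by tissue) and the deterministic mapping of section
samples onto the analysis plate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "PlateFormat",
    "WellAddress",
    "SectionMatrix",
    "LayoutPolicy",
    "AnalysisLayout",
    "FORMAT_96",
    "FORMAT_384",
    "FORMAT_1536",
    "parse_well_label",
    "format_well_label",
    "well_center",
    "build_default_section_matrix",
    "map_to_analysis_plate",
]

_ALLOWED_WELL_COUNTS = {96, 384, 1536}


@dataclass(frozen=True)
class PlateFormat:
    """A microplate format (rows x cols) with ANSI/SLAS physical geometry.

    ``pitch`` is the center-to-center spacing of adjacent wells in mm;
    ``a1_offset`` is the (x, y) position in mm of the center of well A1
    relative to the plate origin.
    """

    name: str
    n_rows: int
    n_cols: int
    pitch: float  # mm
    a1_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols not in _ALLOWED_WELL_COUNTS:
            raise ValueError(
                f"unsupported plate size {self.n_rows}x{self.n_cols}"
            )
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols


# ANSI/SLAS 4-2004 footprint geometry.
FORMAT_96 = PlateFormat("96", 8, 12, 9.0, (14.38, 11.24))
FORMAT_384 = PlateFormat("384", 16, 24, 4.5, (12.13, 8.99))
FORMAT_1536 = PlateFormat("1536", 32, 48, 2.25, (11.005, 7.865))


def _row_letters(row: int) -> str:
    """0-based row index -> plate row letters (A..Z, AA..AF, ...)."""
    if row < 0:
        raise ValueError("negative row index")
    if row < 26:
        return chr(ord("A") + row)
    # plate convention continues AA, AB, ... after Z
    return "A" + chr(ord("A") + row - 26)


def _letters_to_row(letters: str) -> int:
    if len(letters) == 1:
        return ord(letters) - ord("A")
    if len(letters) == 2 and letters[0] == "A":
        return 26 + ord(letters[1]) - ord("A")
    raise ValueError(f"malformed row letters {letters!r}")


@dataclass(frozen=True)
class WellAddress:
    """A single well, 0-based indices plus its plate format."""

    row: int
    col: int
    format: PlateFormat

    def __post_init__(self) -> None:
        if not (0 <= self.row < self.format.n_rows):
            raise ValueError(f"row {self.row} out of range for {self.format.name}-well plate")
        if not (0 <= self.col < self.format.n_cols):
            raise ValueError(f"col {self.col} out of range for {self.format.name}-well plate")

    @property
    def label(self) -> str:
        return format_well_label(self)


_LABEL_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def parse_well_label(label: str, fmt: PlateFormat) -> WellAddress:
    """Parse an A1-style label into a :class:`WellAddress`.

    Rows run A..Z then AA..AF (1536 plates); columns are 1-based numbers.
    """
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"malformed well label {label!r}")
    row = _letters_to_row(m.group(1).upper())
    col = int(m.group(2)) - 1
    if not (0 <= row < fmt.n_rows and 0 <= col < fmt.n_cols):
        raise ValueError(f"label {label!r} out of range for {fmt.name}-well plate")
    return WellAddress(row, col, fmt)


def format_well_label(addr: WellAddress) -> str:
    """Canonical upper-case A1-style label for a well address."""
    return f"{_row_letters(addr.row)}{addr.col + 1}"


def well_center(addr: WellAddress) -> tuple[float, float]:
    """Physical (x, y) center of a well in mm from the plate origin."""
    fmt = addr.format
    return (
        fmt.a1_offset[0] + addr.col * fmt.pitch,
        fmt.a1_offset[1] + addr.row * fmt.pitch,
    )


class SectionMatrix:
    """The set of extraction wells covered by a tissue section.

    The matrix is a boolean mask over a rectangular bounding window of a
    1536-well plate.  Masked cells are enumerated row-major; this sample
    order is the contract that makes every downstream export reproducible.
    """

    def __init__(
        self,
        mask: np.ndarray,
        fmt: PlateFormat = FORMAT_1536,
        window_origin: tuple[int, int] = (0, 0),
    ):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        r0, c0 = window_origin
        if r0 < 0 or c0 < 0:
            raise ValueError("window origin must be non-negative")
        if r0 + mask.shape[0] > fmt.n_rows or c0 + mask.shape[1] > fmt.n_cols:
            raise ValueError("mask window exceeds plate bounds")
        self.format = fmt
        self.window_origin = (int(r0), int(c0))
        self.mask = mask
        # row-major enumeration of masked cells, in window coordinates
        self.sample_order: list[tuple[int, int]] = [
            (int(r), int(c)) for r, c in np.argwhere(mask)
        ]
        self._index = {cell: i for i, cell in enumerate(self.sample_order)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_order)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def cell_of_sample(self, i: int) -> tuple[int, int]:
        """Window (row, col) of sample number ``i``."""
        return self.sample_order[i]

    def sample_of_cell(self, cell: tuple[int, int]) -> int:
        return self._index[tuple(cell)]

    def plate_address(self, i: int) -> WellAddress:
        """Absolute 1536-plate address of sample ``i``."""
        r, c = self.sample_order[i]
        return WellAddress(r + self.window_origin[0], c + self.window_origin[1], self.format)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.sample_order)

    # ---- TSV round-trip -------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the matrix as row_label / col_index / role lines."""
        with open(path, "w") as fh:
            fh.write("row_label\tcol_index\trole\n")
            fh.write(f"#window_origin\t{self.window_origin[0]}\t{self.window_origin[1]}\n")
            fh.write(f"#window_shape\t{self.mask.shape[0]}\t{self.mask.shape[1]}\n")
            for r, c in self.sample_order:
                rr = r + self.window_origin[0]
                cc = c + self.window_origin[1]
                fh.write(f"{_row_letters(rr)}\t{cc + 1}\tsample\n")

    @classmethod
    def from_tsv(cls, path, fmt: PlateFormat = FORMAT_1536) -> "SectionMatrix":
        origin = (0, 0)
        shape = None
        cells = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("row_label"):
                raise ValueError("not a section-matrix TSV")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "#window_origin":
                    origin = (int(parts[1]), int(parts[2]))
                elif parts[0] == "#window_shape":
                    shape = (int(parts[1]), int(parts[2]))
                elif parts and parts[0]:
                    cells.append((_letters_to_row(parts[0]), int(parts[1]) - 1))
        if shape is None:
            rmax = max(r for r, _ in cells) - origin[0] + 1
            cmax = max(c for _, c in cells) - origin[1] + 1
            shape = (rmax, cmax)
        mask = np.zeros(shape, dtype=bool)
        for r, c in cells:
            mask[r - origin[0], c - origin[1]] = True
        return cls(mask, fmt, origin)


def _default_silhouette_mask() -> np.ndarray:
    """Stylized sagittal mouse silhouette with exactly 363 cells.

    Built from a fixed union of ellipses (torso, head, snout, hindquarters,
    tail, legs) on a 22-row x 33-col window and deterministically trimmed
    from the extremities (cells farthest from the centroid, row-major
    tie-break) down to 363 cells.  The construction is pure arithmetic, so
    repeated calls are bit-identical.
    """
    R, C = 22, 33
    yy, xx = np.mgrid[0:R, 0:C].astype(float)

    def ell(cy, cx, ry, rx):
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    mask = ell(11, 16, 7.6, 11.6)      # torso
    mask |= ell(9, 5, 5.0, 4.6)        # head
    mask |= ell(12.5, 2.2, 1.8, 2.4)   # snout
    mask |= ell(7.5, 26, 3.2, 4.8)     # hindquarters
    for c in range(27, 33):            # tail
        r = int(round(14 + 0.35 * (c - 27)))
        mask[r, c] = True
        mask[r - 1, c] = True
    mask[16:20, 10:12] = True          # foreleg
    mask[16:20, 22:24] = True          # hindleg

    target = 363
    cells = np.argwhere(mask)
    cy, cx = cells.mean(axis=0)
    dist = (cells[:, 0] - cy) ** 2 + (cells[:, 1] - cx) ** 2
    order = np.lexsort((cells[:, 1], cells[:, 0], -dist))
    i = 0
    while mask.sum() > target:
        r, c = cells[order[i]]
        mask[r, c] = False
        i += 1
    if mask.sum() != target:
        raise AssertionError("silhouette template does not have 363 cells")
    return mask


def build_default_section_matrix() -> SectionMatrix:
    """The packaged 363-well mouse-section matrix on a 1536-well plate.

    The window is placed at plate row 5, column 7 so that the whole
    silhouette sits inside the 32x48 grid with margins on all sides.
    """
    return SectionMatrix(_default_silhouette_mask(), FORMAT_1536, window_origin=(5, 7))


@dataclass(frozen=True)
class LayoutPolicy:
    """How section samples are laid onto the 384-well analysis plate.

    Defaults match the published accounting: 363 samples plus 20 wells
    reserved for reference samples or standards; the single remaining well
    is an explicit blank.
    """

    n_reference: int = 20
    n_blank: int = 1
    fill_order: str = "column-major"  # or "row-major"
    reference_kind: str = "reference"


class AnalysisLayout:
    """Role assignment (sample / reference / blank) for every analysis well."""

    def __init__(
        self,
        fmt: PlateFormat,
        roles: list[tuple[str, int | str | None]],
        matrix: SectionMatrix | None = None,
    ):
        # roles: one (role, payload) per well in row-major well order;
        # payload is the sample index for samples, a kind label for references
        if len(roles) != fmt.n_wells:
            raise ValueError("role list must cover every well")
        self.format = fmt
        self.roles = roles
        self.matrix = matrix
        self._well_of_sample: dict[int, int] = {}
        for wi, (role, payload) in enumerate(roles):
            if role == "sample":
                if payload in self._well_of_sample:
                    raise ValueError(f"sample {payload} assigned twice")
                self._well_of_sample[int(payload)] = wi

    def _addr(self, well_index: int) -> WellAddress:
        return WellAddress(well_index // self.format.n_cols, well_index % self.format.n_cols, self.format)

    def well_for_sample(self, sample: int) -> WellAddress:
        return self._addr(self._well_of_sample[sample])

    def sample_for_well(self, addr: WellAddress | str) -> int | None:
        """Sample index of a well, or None for reference/blank wells."""
        if isinstance(addr, str):
            addr = parse_well_label(addr, self.format)
        role, payload = self.roles[addr.row * self.format.n_cols + addr.col]
        return int(payload) if role == "sample" else None

    def role_of_well(self, addr: WellAddress | str) -> str:
        if isinstance(addr, str):
            addr = parse_well_label(addr, self.format)
        return self.roles[addr.row * self.format.n_cols + addr.col][0]

    def wells_with_role(self, role: str) -> list[WellAddress]:
        return [self._addr(i) for i, (r, _) in enumerate(self.roles) if r == role]

    @property
    def n_samples(self) -> int:
        return len(self._well_of_sample)

    # ---- TSV round-trip -------------------------------------------------
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("well_label\trole\tsample_index\n")
            for wi, (role, payload) in enumerate(self.roles):
                idx = payload if role == "sample" else ""
                fh.write(f"{self._addr(wi).label}\t{role}\t{idx}\n")

    @classmethod
    def from_tsv(cls, path, fmt: PlateFormat = FORMAT_384) -> "AnalysisLayout":
        roles: list[tuple[str, int | str | None]] = [("blank", None)] * fmt.n_wells
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("well_label"):
                raise ValueError("not a layout TSV")
            for line in fh:
                label, role, idx = line.rstrip("\n").split("\t")
                addr = parse_well_label(label, fmt)
                payload: int | str | None
                if role == "sample":
                    payload = int(idx)
                elif role == "blank":
                    payload = None
                else:
                    payload = role
                    role = "reference"
                roles[addr.row * fmt.n_cols + addr.col] = (role, payload)
        return cls(fmt, roles)


def map_to_analysis_plate(
    matrix: SectionMatrix,
    policy: LayoutPolicy = LayoutPolicy(),
    fmt: PlateFormat = FORMAT_384,
) -> AnalysisLayout:
    """Assign every section sample to an analysis well, deterministically.

    Samples fill the plate in the policy's order (default column-major:
    A1, B1, ... P1, A2, ...), followed by the reference wells, then blanks.
    """
    n = matrix.n_samples
    capacity = fmt.n_wells - policy.n_reference - policy.n_blank
    if n > capacity:
        raise ValueError(
            f"{n} samples exceed capacity {capacity} "
            f"({fmt.n_wells} wells minus {policy.n_reference} reference, {policy.n_blank} blank)"
        )
    if policy.fill_order == "column-major":
        # column-major rank k -> row-major well index
        well_order = [
            (k % fmt.n_rows) * fmt.n_cols + (k // fmt.n_rows)
            for k in range(fmt.n_wells)
        ]
    elif policy.fill_order == "row-major":
        well_order = list(range(fmt.n_wells))
    else:
        raise ValueError(f"unknown fill order {policy.fill_order!r}")

    roles: list[tuple[str, int | str | None]] = [("blank", None)] * fmt.n_wells
    pos = 0
    for s in range(n):
        roles[well_order[pos]] = ("sample", s)
        pos += 1
    for _ in range(policy.n_reference):
        roles[well_order[pos]] = ("reference", policy.reference_kind)
        pos += 1
    return AnalysisLayout(fmt, roles, matrix)
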