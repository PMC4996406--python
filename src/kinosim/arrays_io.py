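"""Data model and file I/O for kinome peptide-microarray intensity data.

A kinome array carries ``m`` peptides ("probes"), each printed as ``l``
within-array replicate spots.  Every spot records a raw foreground and a raw
background fluorescence intensity; the background-corrected value
(foreground - background) is the quantity all downstream analysis works on
and *may be negative* at low signal-to-noise -- negatives are preserved,
never clipped.

Two on-disk dialects are supported:

* ``long_tsv`` -- the canonical tab-separated long format with columns
  ``array_id, peptide_id, replicate_index, foreground, background``
  (one header line, UTF-8, 1-based replicate index).  Round-trips are
  bit-exact.
* ``gpr`` -- a minimal GenePix Results (ATF 1.0) reader consuming only the
  ``Name`` column and two configurable intensity columns (defaults
  ``"F532 Median"`` / ``"B532 Median"``).  Replicate spots of the same
  peptide are numbered in file order.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ArrayFormatError",
    "ArrayValidationError",
    "SpotMeasurement",
    "PeptideReplicateSet",
    "KinomeArray",
    "background_corrected",
    "peptide_mean_abc",
    "read_array_table",
    "write_array_table",
    "LONG_TSV_COLUMNS",
]

LONG_TSV_COLUMNS = ("array_id", "peptide_id", "replicate_index", "foreground", "background")


class ArrayFormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ArrayValidationError(ValueError):
    """In-memory array data violates a structural invariant."""


@dataclasses.dataclass(frozen=True)
class SpotMeasurement:
    """One within-array replicate spot: raw foreground and background intensity."""

    foreground: float
    background: float

    def __post_init__(self) -> None:
        for name in ("foreground", "background"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ArrayValidationError(f"{name} must be a real number, got {value!r}")
            if not math.isfinite(value):
                raise ArrayValidationError(f"{name} must be finite, got {value!r}")
            object.__setattr__(self, name, float(value))


def background_corrected(spot: SpotMeasurement) -> float:
    """Background-corrected intensity ``F - B``; may be negative or zero."""
    return spot.foreground - spot.background


@dataclasses.dataclass(frozen=True)
class PeptideReplicateSet:
    """The ordered set of within-array replicate spots for one peptide.

    This is the atomic unit the synthesis algorithms move between arrays:
    when a peptide is replaced, all ``l`` spots (raw foreground and
    background) travel together.
    """

    peptide_id: str
    spots: tuple[SpotMeasurement, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "spots", tuple(self.spots))
        if not self.spots:
            raise ArrayValidationError(f"peptide {self.peptide_id!r} has no spots")

    @property
    def n_replicates(self) -> int:
        return len(self.spots)

    def corrected_values(self) -> np.ndarray:
        """Background-corrected value of each spot, in replicate order."""
        return np.array([background_corrected(s) for s in self.spots], dtype=float)


def peptide_mean_abc(peptide: PeptideReplicateSet) -> float:
    """Mean background-corrected intensity over the within-array replicates.

    This is the "mean of a peptide" used throughout replicate synthesis and
    fold-change bound computation (``abc_t``).
    """
    return float(np.mean(peptide.corrected_values()))


@dataclasses.dataclass(frozen=True)
class KinomeArray:
    """An ordered collection of peptide replicate sets from one array."""

    array_id: str
    peptides: tuple[PeptideReplicateSet, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptides", tuple(self.peptides))
        if not self.peptides:
            raise ArrayValidationError(f"array {self.array_id!r} has no peptides")
        counts = {p.n_replicates for p in self.peptides}
        if len(counts) != 1:
            ragged = [p.peptide_id for p in self.peptides if p.n_replicates != self.peptides[0].n_replicates]
            raise ArrayValidationError(
                f"array {self.array_id!r} has ragged replicate counts; offending peptide_ids: {ragged}"
            )
        ids = [p.peptide_id for p in self.peptides]
        if len(set(ids)) != len(ids):
            dups = sorted({i for i in ids if ids.count(i) > 1})
            raise ArrayValidationError(f"array {self.array_id!r} has duplicate peptide_ids: {dups}")

    @property
    def m(self) -> int:
        """Number of peptides."""
        return len(self.peptides)

    @property
    def l(self) -> int:
        """Number of within-array replicate spots per peptide."""
        return self.peptides[0].n_replicates

    @property
    def peptide_ids(self) -> tuple[str, ...]:
        return tuple(p.peptide_id for p in self.peptides)

    def corrected_matrix(self) -> np.ndarray:
        """(m, l) matrix of background-corrected spot values."""
        return np.array([p.corrected_values() for p in self.peptides], dtype=float)

    def peptide_means(self) -> np.ndarray:
        """(m,) vector of per-peptide mean background-corrected intensities."""
        return self.corrected_matrix().mean(axis=1)

    def comparable_with(self, other: "KinomeArray") -> bool:
        """Two arrays are comparable iff they share peptide_id sequence and l."""
        return self.peptide_ids == other.peptide_ids and self.l == other.l

    def with_peptide_spots(self, index: int, spots: Sequence[SpotMeasurement]) -> "KinomeArray":
        """Copy of the array with the spots of peptide ``index`` replaced.

        The peptide keeps its identifier so the result remains comparable
        with the original; only the measurements change.
        """
        peptides = list(self.peptides)
        peptides[index] = PeptideReplicateSet(peptides[index].peptide_id, tuple(spots))
        return KinomeArray(self.array_id, tuple(peptides))


def _parse_float(text: str, line_no: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ArrayFormatError(f"non-numeric {column} value {text!r} at line {line_no}") from None


def _read_long_tsv(path: Path) -> KinomeArray:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ArrayFormatError(f"{path}: empty file") from None
        if tuple(header) != LONG_TSV_COLUMNS:
            missing = [c for c in LONG_TSV_COLUMNS if c not in header]
            if missing:
                raise ArrayFormatError(f"{path}: missing column(s) {missing}")
            raise ArrayFormatError(
                f"{path}: header must be exactly {list(LONG_TSV_COLUMNS)}, got {header}"
            )
        array_ids: set[str] = set()
        spots_by_peptide: dict[str, list[tuple[int, SpotMeasurement]]] = {}
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(LONG_TSV_COLUMNS):
                raise ArrayFormatError(f"{path}: expected {len(LONG_TSV_COLUMNS)} fields at line {line_no}")
            array_id, peptide_id, rep_text, fg_text, bg_text = row
            array_ids.add(array_id)
            try:
                rep = int(rep_text)
            except ValueError:
                raise ArrayFormatError(
                    f"non-numeric replicate_index value {rep_text!r} at line {line_no}"
                ) from None
            spot = SpotMeasurement(
                _parse_float(fg_text, line_no, "foreground"),
                _parse_float(bg_text, line_no, "background"),
            )
            spots_by_peptide.setdefault(peptide_id, []).append((rep, spot))
    if not spots_by_peptide:
        raise ArrayFormatError(f"{path}: no data rows")
    if len(array_ids) != 1:
        raise ArrayFormatError(f"{path}: expected a single array_id per file, got {sorted(array_ids)}")
    peptides = []
    for peptide_id, indexed in spots_by_peptide.items():
        indexed.sort(key=lambda pair: pair[0])
        peptides.append(PeptideReplicateSet(peptide_id, tuple(s for _, s in indexed)))
    return KinomeArray(array_ids.pop(), tuple(peptides))


def _read_gpr(path: Path, foreground_column: str, background_column: str) -> KinomeArray:
    with open(path, newline="", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise ArrayFormatError(f"{path}: not an ATF/GPR file (missing 'ATF' signature)")
    try:
        n_header_records = int(lines[1].split("\t")[0])
    except (IndexError, ValueError):
        raise ArrayFormatError(f"{path}: malformed ATF record-count line") from None
    column_line_idx = 2 + n_header_records
    if column_line_idx >= len(lines):
        raise ArrayFormatError(f"{path}: truncated ATF header block")
    columns = [c.strip().strip('"') for c in lines[column_line_idx].split("\t")]
    for required in ("Name", foreground_column, background_column):
        if required not in columns:
            raise ArrayFormatError(f"{path}: missing column {required!r}")
    name_idx = columns.index("Name")
    fg_idx = columns.index(foreground_column)
    bg_idx = columns.index(background_column)
    spots_by_peptide: dict[str, list[SpotMeasurement]] = {}
    for line_no, line in enumerate(lines[column_line_idx + 1 :], start=column_line_idx + 2):
        if not line.strip():
            continue
        fields = [c.strip().strip('"') for c in line.split("\t")]
        if len(fields) <= max(name_idx, fg_idx, bg_idx):
            raise ArrayFormatError(f"{path}: short record at line {line_no}")
        spot = SpotMeasurement(
            _parse_float(fields[fg_idx], line_no, foreground_column),
            _parse_float(fields[bg_idx], line_no, background_column),
        )
        spots_by_peptide.setdefault(fields[name_idx], []).append(spot)
    if not spots_by_peptide:
        raise ArrayFormatError(f"{path}: no data records")
    peptides = tuple(
        PeptideReplicateSet(name, tuple(spots)) for name, spots in spots_by_peptide.items()
    )
    return KinomeArray(path.stem, peptides)


def read_array_table(
    path,
    dialect: str = "long_tsv",
    *,
    foreground_column: str = "F532 Median",
    background_column: str = "B532 Median",
) -> KinomeArray:
    """Read one kinome array from ``path``.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"long_tsv"`` (canonical format) or ``"gpr"`` (minimal GenePix
        Results reader).
    foreground_column, background_column:
        Intensity columns consumed by the ``gpr`` dialect.

    Peptides appear in first-occurrence order; within a peptide, spots follow
    the ``replicate_index`` column (long_tsv) or file order (gpr).
    """
    path = Path(path)
    if dialect == "long_tsv":
        return _read_long_tsv(path)
    if dialect == "gpr":
        return _read_gpr(path, foreground_column, background_column)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'long_tsv' or 'gpr'")


def write_array_table(array: KinomeArray, path) -> None:
    """Write ``array`` to ``path`` in the canonical long_tsv dialect.

    Intensities are serialized with full ``repr`` precision so that
    ``read_array_table(write_array_table(A)) == A`` holds bit-exactly,
    including negative background-corrected spots.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(LONG_TSV_COLUMNS) + "\n")
        for peptide in array.peptides:
            for k, spot in enumerate(peptide.spots, start=1):
                fh.write(
                    f"{array.array_id}\t{peptide.peptide_id}\t{k}\t"
                    f"{spot.foreground!r}\t{spot.background!r}\n"
                )


def read_arrays(paths: Iterable, dialect: str = "long_tsv", **kwargs) -> list[KinomeArray]:
    """Read several arrays (one per file); convenience for CLI repositories."""
    return [read_array_table(p, dialect=dialect, **kwargs) for p in paths]
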