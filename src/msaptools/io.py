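"""Data model and I/O for MSAP/AFLP band matrices and sample metadata.

MSAP (methylation-sensitive amplified polymorphism) scores every sample at a
panel of anonymous 5'-CCGG loci twice: once after an EcoRI+HpaII digest and
once after an EcoRI+MspI digest.  Each digest yields a dominant binary band
call (present/absent), so a dataset is a *pair* of aligned samples-by-loci
binary matrices.  The companion AFLP (amplified fragment length polymorphism)
genetic track is a single such matrix.

Matrices are stored rows = samples, columns = loci, with values
``1`` (band present), ``0`` (band absent) and ``MISSING`` (= -1) for cells
that could not be scored.  Missing cells are never silently imputed here;
downstream statistics exclude them pairwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Integer sentinel for an unscored band call.
MISSING: int = -1

#: Recognised enzyme tracks.
TRACKS = ("HPA", "MSP", "AFLP")


class BandMatrixError(ValueError):
    """Malformed band-matrix input (bad cell value, duplicate ids, ...)."""


class AlignmentError(ValueError):
    """The two enzyme tracks of a pair do not share sample/locus sets."""


class FixtureError(RuntimeError):
    """The packaged variety-profile fixture failed its integrity checks."""


# ---------------------------------------------------------------------------
# Band matrices
# ---------------------------------------------------------------------------

@dataclass
class BandMatrix:
    """A samples-by-loci dominant binary marker matrix for one enzyme track.

    Parameters
    ----------
    matrix_id : str
        Free-form identifier (usually the source file stem).
    enzyme_track : str
        One of ``"HPA"`` (EcoRI+HpaII digest), ``"MSP"`` (EcoRI+MspI digest)
        or ``"AFLP"`` (genetic track).
    sample_ids, locus_ids : sequence of str
        Row and column labels, in matrix order.  Must be unique.
    values : ndarray of int8, shape (n_samples, n_loci)
        Entries in ``{1, 0, MISSING}``.
    """

    matrix_id: str
    enzyme_track: str
    sample_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(c) for c in self.locus_ids]
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.enzyme_track not in TRACKS:
            raise BandMatrixError(
                f"unknown enzyme track {self.enzyme_track!r}; expected one of {TRACKS}"
            )
        if self.values.ndim != 2 or self.values.shape != (
            len(self.sample_ids),
            len(self.locus_ids),
        ):
            raise BandMatrixError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        for name, ids in (("sample", self.sample_ids), ("locus", self.locus_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise BandMatrixError(f"duplicate {name} ids: {sorted(dupes)}")
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise BandMatrixError(
                f"non-binary cell at sample {self.sample_ids[i]!r}, "
                f"locus {self.locus_ids[j]!r}: {self.values[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        """Return a labelled copy, with missing cells as pandas NA."""
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.locus_ids, dtype="Int8"
        )
        return df.mask(df == MISSING)

    def reordered(self, sample_ids: Sequence[str], locus_ids: Sequence[str]) -> "BandMatrix":
        """Return a copy with rows/columns permuted to the given orders."""
        ri = [self.sample_ids.index(s) for s in sample_ids]
        ci = [self.locus_ids.index(c) for c in locus_ids]
        return BandMatrix(
            self.matrix_id,
            self.enzyme_track,
            list(sample_ids),
            list(locus_ids),
            self.values[np.ix_(ri, ci)],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.enzyme_track == other.enzyme_track
            and self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.values, other.values)
        )


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for x in ids:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text().splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_band_matrix(
    path: str | Path,
    enzyme_track: str,
    *,
    delimiter: str | None = None,
    missing_token: str = "NA",
) -> BandMatrix:
    """Read a delimited band matrix: first row locus ids, first column sample ids.

    Cells must be ``0``, ``1`` or the designated *missing_token*.  The
    delimiter is auto-detected (tab vs comma) when not given.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    if len(rows) < 2 or len(rows[0]) < 2:
        raise BandMatrixError(f"{path}: expected a header row and at least one sample row")
    locus_ids = [c.strip() for c in rows[0][1:]]
    sample_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(locus_ids)), dtype=np.int8)
    for i, row in enumerate(rows[1:]):
        if len(row) != len(locus_ids) + 1:
            raise BandMatrixError(
                f"{path}: row {i + 2} has {len(row) - 1} cells, expected {len(locus_ids)}"
            )
        sample_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            cell = cell.strip()
            if cell == missing_token or cell == "":
                values[i, j] = MISSING
            elif cell in ("0", "1"):
                values[i, j] = int(cell)
            else:
                raise BandMatrixError(
                    f"{path}: non-binary cell {cell!r} at row {row[0]!r}, "
                    f"column {locus_ids[j]!r}"
                )
    return BandMatrix(path.stem, enzyme_track, sample_ids, locus_ids, values)


def write_band_matrix(
    matrix: BandMatrix,
    path: str | Path,
    *,
    delimiter: str = ",",
    missing_token: str = "NA",
) -> None:
    """Write a band matrix in the format :func:`read_band_matrix` accepts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["sample_id", *matrix.locus_ids])
        for sid, row in zip(matrix.sample_ids, matrix.values):
            w.writerow([sid, *(missing_token if v == MISSING else str(v) for v in row)])


# ---------------------------------------------------------------------------
# Dual-enzyme pairs
# ---------------------------------------------------------------------------

@dataclass
class BandMatrixPair:
    """Aligned HpaII-track and MspI-track matrices over identical samples/loci."""

    hpa: BandMatrix
    msp: BandMatrix

    def __post_init__(self) -> None:
        if self.hpa.sample_ids != self.msp.sample_ids or self.hpa.locus_ids != self.msp.locus_ids:
            raise AlignmentError("tracks are not aligned; use pair_matrices()")

    @property
    def sample_ids(self) -> list[str]:
        return self.hpa.sample_ids

    @property
    def locus_ids(self) -> list[str]:
        return self.hpa.locus_ids


def pair_matrices(hpa: BandMatrix, msp: BandMatrix) -> BandMatrixPair:
    """Pair the two enzyme tracks, reordering *msp* to the *hpa* layout.

    Raises :class:`AlignmentError` listing every sample/locus id that is not
    shared by both tracks.
    """
    problems: list[str] = []
    s_h, s_m = set(hpa.sample_ids), set(msp.sample_ids)
    l_h, l_m = set(hpa.locus_ids), set(msp.locus_ids)
    if s_h != s_m:
        problems.append(f"samples only in HPA: {sorted(s_h - s_m)}; only in MSP: {sorted(s_m - s_h)}")
    if l_h != l_m:
        problems.append(f"loci only in HPA: {sorted(l_h - l_m)}; only in MSP: {sorted(l_m - l_h)}")
    if problems:
        raise AlignmentError("; ".join(problems))
    if msp.sample_ids != hpa.sample_ids or msp.locus_ids != hpa.locus_ids:
        msp = msp.reordered(hpa.sample_ids, hpa.locus_ids)
    return BandMatrixPair(hpa, msp)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample annotations: variety name, mutation group, reference flag."""

    sample_id: str
    variety_name: str
    group: str
    is_reference: bool = False


def metadata_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "variety_name": [r.variety_name for r in records],
            "group": [r.group for r in records],
            "is_reference": [r.is_reference for r in records],
        }
    )


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read metadata CSV with header ``sample_id,variety_name,group,is_reference``."""
    df = pd.read_csv(path, dtype={"sample_id": str, "variety_name": str, "group": str})
    required = {"sample_id", "variety_name", "group", "is_reference"}
    missing = required - set(df.columns)
    if missing:
        raise BandMatrixError(f"{path}: metadata missing columns {sorted(missing)}")
    truthy = {"1", "true", "yes"}
    return [
        SampleMetadata(
            str(r.sample_id),
            str(r.variety_name),
            str(r.group),
            str(r.is_reference).strip().lower() in truthy,
        )
        for r in df.itertuples()
    ]


def write_sample_metadata(records: Sequence[SampleMetadata], path: str | Path) -> None:
    metadata_frame(records).to_csv(path, index=False)


def reference_sample(records: Sequence[SampleMetadata]) -> str:
    """Return the unique reference sample id, or raise if not exactly one."""
    refs = [r.sample_id for r in records if r.is_reference]
    if len(refs) != 1:
        raise BandMatrixError(
            f"pattern-change analysis needs exactly one reference sample, found {refs}"
        )
    return refs[0]


def groups_of(records: Sequence[SampleMetadata], *, include_reference: bool = False) -> dict[str, str]:
    """Map sample id -> group, optionally dropping the reference sample."""
    return {
        r.sample_id: r.group
        for r in records
        if include_reference or not r.is_reference
    }


# ---------------------------------------------------------------------------
# Packaged per-variety profile fixture (Fuji bud-mutation panel)
# ---------------------------------------------------------------------------

@dataclass
class ProfileFixtureRow:
    """Published per-variety MSAP amplification summary for the Fuji panel.

    Counts refer to scored (band-observed) CCGG loci of one variety:
    unmethylated (condition I), CG-methylated (internal cytosine, condition
    III) and CHG-methylated (external cytosine, condition II).  Printed
    percentages are retained verbatim for cross-checks; the counts are the
    authoritative values.
    """

    variety_code: str
    name: str
    group: str
    n_total: int
    n_unmethylated: int
    n_cg: int
    n_chg: int
    pct_unmethylated: float
    pct_cg: float
    pct_chg: float
    pct_total_methylated: float

    def __post_init__(self) -> None:
        if self.n_unmethylated + self.n_cg + self.n_chg != self.n_total:
            raise FixtureError(
                f"{self.variety_code}: counts {self.n_unmethylated}+{self.n_cg}"
                f"+{self.n_chg} != {self.n_total}"
            )


_EXPECTED_GROUPS = {"Origin": 1, "Color": 51, "Early-maturation": 23, "Spur": 17}


def load_fuji_profiles() -> list[ProfileFixtureRow]:
    """Load the packaged 92-variety Fuji profile fixture, validated."""
    with resources.files("msaptools.data").joinpath("fuji_variety_profiles.csv").open() as fh:
        df = pd.read_csv(fh)
    rows = [
        ProfileFixtureRow(
            variety_code=str(r.variety_code),
            name=str(r.name),
            group=str(r.group),
            n_total=int(r.n_total),
            n_unmethylated=int(r.n_unmethylated),
            n_cg=int(r.n_cg),
            n_chg=int(r.n_chg),
            pct_unmethylated=float(r.pct_unmethylated),
            pct_cg=float(r.pct_cg),
            pct_chg=float(r.pct_chg),
            pct_total_methylated=float(r.pct_total_methylated),
        )
        for r in df.itertuples()
    ]
    if len(rows) != 92:
        raise FixtureError(f"expected 92 fixture rows, found {len(rows)}")
    counts = pd.Series([r.group for r in rows]).value_counts().to_dict()
    if counts != _EXPECTED_GROUPS:
        raise FixtureError(f"unexpected group composition {counts}")
    return rows


def fuji_profiles_frame() -> pd.DataFrame:
    """The fixture as a DataFrame indexed by variety code."""
    rows = load_fuji_profiles()
    return pd.DataFrame([vars(r) for r in rows]).set_index("variety_code")
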