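"""Methylation-state scoring from dual-enzyme band pairs.

At a 5'-CCGG site the HpaII and MspI isoschizomers respond differently to
cytosine methylation, so the joint band outcome of the two digests encodes
one of four conditions:

======  =========  ==========================================
state   (H, M)     interpretation
======  =========  ==========================================
I       (1, 1)     unmethylated
II      (1, 0)     CHG (external cytosine, hemi-) methylation
III     (0, 1)     CG (internal cytosine) methylation
IV      (0, 0)     full CG/CHG methylation or target absence
======  =========  ==========================================

Condition IV is uninformative on its own (hypermethylation and fragment
absence are confounded), which is why per-variety profiles default to the
*observed* denominator (conditions I+II+III) and why the MSL recoding maps
IV to missing.

Loci are partitioned into methylation-sensitive loci (MSL: states II/III
occur above an error threshold) and non-methylated loci (NML), and recoded
to the binary matrices consumed by the diversity and outlier-scan modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import MISSING, BandMatrixPair

__all__ = [
    "MethylationState",
    "StateMatrix",
    "MethylationProfile",
    "LocusPartition",
    "BinaryRecodedMatrix",
    "classify_state",
    "build_state_matrix",
    "profile_of",
    "profile_from_counts",
    "partition_loci",
    "recode_msl",
    "polymorphic_fraction",
]


class MethylationState(IntEnum):
    """The four joint digest outcomes, plus a missing sentinel."""

    MISSING = 0
    I = 1  # noqa: E741 - the field's name for the unmethylated condition
    II = 2
    III = 3
    IV = 4


def classify_state(hpa_band: int, msp_band: int) -> MethylationState:
    """Map an (HpaII, MspI) band pair to a methylation condition.

    ``(1,1) -> I``, ``(1,0) -> II``, ``(0,1) -> III``, ``(0,0) -> IV``; any
    missing band propagates to ``MISSING``.  Total on its domain.
    """
    if hpa_band == MISSING or msp_band == MISSING:
        return MethylationState.MISSING
    return _STATE_OF[(int(hpa_band), int(msp_band))]


_STATE_OF = {
    (1, 1): MethylationState.I,
    (1, 0): MethylationState.II,
    (0, 1): MethylationState.III,
    (0, 0): MethylationState.IV,
}

#: Inverse of :func:`classify_state` on the non-missing states.
BANDS_OF_STATE = {v: k for k, v in _STATE_OF.items()}


@dataclass
class StateMatrix:
    """Samples-by-loci matrix of methylation conditions (int8 state codes)."""

    sample_ids: list[str]
    locus_ids: list[str]
    states: np.ndarray  # int8, values in MethylationState

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError("states shape does not match id lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.states[self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.states, index=self.sample_ids, columns=self.locus_ids)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# states: 1=I 2=II 3=III 4=IV 0=missing\n")
            self.to_frame().to_csv(fh, index_label="sample_id")


def build_state_matrix(pair: BandMatrixPair) -> StateMatrix:
    """Element-wise :func:`classify_state` over an aligned band-matrix pair."""
    h = pair.hpa.values
    m = pair.msp.values
    states = np.zeros(h.shape, dtype=np.int8)
    valid = (h != MISSING) & (m != MISSING)
    # code = 4 - 2h - m reproduces the lookup table branch-free
    states[valid] = (4 - 2 * h[valid] - m[valid]).astype(np.int8)
    return StateMatrix(list(pair.sample_ids), list(pair.locus_ids), states)


# ---------------------------------------------------------------------------
# Per-sample profiles
# ---------------------------------------------------------------------------

@dataclass
class MethylationProfile:
    """Condition counts and percentage profile for one sample.

    ``denominator_convention`` is ``"observed"`` (divide by I+II+III, the
    convention that reproduces the published per-variety tables) or
    ``"panel"`` (divide by I+II+III+IV).
    """

    sample_id: str
    n_I: int
    n_II: int
    n_III: int
    n_IV: int
    denominator_convention: str
    pct_unmethylated: float
    pct_CHG: float
    pct_CG: float
    pct_total: float


class UndefinedProfileError(ZeroDivisionError):
    """All counts in the chosen denominator are zero."""


def profile_from_counts(
    sample_id: str,
    n_I: int,
    n_II: int,
    n_III: int,
    n_IV: int = 0,
    convention: str = "observed",
) -> MethylationProfile:
    """Build a profile directly from condition counts.

    Percentages: unmethylated = I/denom, CHG = II/denom, CG = III/denom,
    total methylation = (II+III)/denom, with denom = I+II+III under the
    observed convention and I+II+III+IV under the panel convention.
    """
    if convention not in ("observed", "panel"):
        raise ValueError(f"unknown denominator convention {convention!r}")
    denom = n_I + n_II + n_III + (n_IV if convention == "panel" else 0)
    if denom == 0:
        raise UndefinedProfileError(f"{sample_id}: zero denominator under {convention}")
    return MethylationProfile(
        sample_id=sample_id,
        n_I=n_I,
        n_II=n_II,
        n_III=n_III,
        n_IV=n_IV,
        denominator_convention=convention,
        pct_unmethylated=100.0 * n_I / denom,
        pct_CHG=100.0 * n_II / denom,
        pct_CG=100.0 * n_III / denom,
        pct_total=100.0 * (n_II + n_III) / denom,
    )


def profile_of(
    states: StateMatrix, sample_id: str, convention: str = "observed"
) -> MethylationProfile:
    """Count conditions I-IV for one sample (missing excluded) and profile them."""
    row = states.row(sample_id)
    counts = [int((row == s).sum()) for s in (1, 2, 3, 4)]
    return profile_from_counts(sample_id, *counts, convention=convention)


def profiles_frame(states: StateMatrix, convention: str = "observed") -> pd.DataFrame:
    """Profiles for every sample, shaped like the published variety table."""
    rows = [profile_of(states, s, convention) for s in states.sample_ids]
    return pd.DataFrame([vars(p) for p in rows]).set_index("sample_id")


# ---------------------------------------------------------------------------
# MSL / NML partition and binary recoding
# ---------------------------------------------------------------------------

@dataclass
class LocusPartition:
    """MSL/NML classification of every locus at a given error threshold.

    A locus is methylation-sensitive (MSL) when the fraction of non-missing
    samples in state II or III *strictly exceeds* ``msl_error_threshold``;
    otherwise it is non-methylated (NML).  All-missing loci are excluded
    from both classes and listed in ``excluded_loci``.
    """

    msl_loci: list[str]
    nml_loci: list[str]
    excluded_loci: list[str]
    msl_error_threshold: float

    def cls(self, locus_id: str) -> str:
        if locus_id in set(self.msl_loci):
            return "MSL"
        if locus_id in set(self.nml_loci):
            return "NML"
        return "EXCLUDED"


def partition_loci(states: StateMatrix, error_threshold: float = 0.05) -> LocusPartition:
    s = states.states
    scored = (s != MethylationState.MISSING).sum(axis=0)
    methylated = ((s == MethylationState.II) | (s == MethylationState.III)).sum(axis=0)
    msl, nml, excluded = [], [], []
    for j, locus in enumerate(states.locus_ids):
        if scored[j] == 0:
            excluded.append(locus)
        elif methylated[j] / scored[j] > error_threshold:
            msl.append(locus)
        else:
            nml.append(locus)
    return LocusPartition(msl, nml, excluded, error_threshold)


@dataclass
class BinaryRecodedMatrix:
    """Binary (1/0/missing) matrix with a semantics tag.

    ``semantics_tag`` is ``"MSL-methylation"`` (1 = methylated at an MSL
    locus) or ``"NML-band"`` (1 = band present at an NML locus).
    """

    sample_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray  # int8 in {1, 0, MISSING}
    semantics_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError("values shape does not match id lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.locus_ids, dtype="Int8"
        )
        return df.mask(df == MISSING)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# semantics: {self.semantics_tag}; missing={MISSING}\n")
            self.to_frame().to_csv(fh, index_label="sample_id")


class RecodedMatrices(NamedTuple):
    msl: BinaryRecodedMatrix
    nml: BinaryRecodedMatrix


def recode_msl(
    states: StateMatrix,
    partition: LocusPartition,
    *,
    iv_as_methylated: bool = False,
) -> RecodedMatrices:
    """Recode conditions to the two binary matrices used downstream.

    MSL loci: states II/III -> 1 (methylated), I -> 0, IV -> missing by
    default (hypermethylation and target loss are confounded) or 1 when
    ``iv_as_methylated`` is set.  NML loci: any band (I-III) -> 1, IV -> 0.
    State MISSING propagates.
    """
    locus_index = {c: j for j, c in enumerate(states.locus_ids)}
    s = states.states

    msl_cols = [locus_index[c] for c in partition.msl_loci]
    msl = np.full((states.n_samples, len(msl_cols)), MISSING, dtype=np.int8)
    sub = s[:, msl_cols]
    msl[(sub == MethylationState.II) | (sub == MethylationState.III)] = 1
    msl[sub == MethylationState.I] = 0
    msl[sub == MethylationState.IV] = 1 if iv_as_methylated else MISSING

    nml_cols = [locus_index[c] for c in partition.nml_loci]
    nml = np.full((states.n_samples, len(nml_cols)), MISSING, dtype=np.int8)
    sub = s[:, nml_cols]
    nml[(sub >= MethylationState.I) & (sub <= MethylationState.III)] = 1
    nml[sub == MethylationState.IV] = 0

    return RecodedMatrices(
        BinaryRecodedMatrix(
            list(states.sample_ids), list(partition.msl_loci), msl, "MSL-methylation"
        ),
        BinaryRecodedMatrix(
            list(states.sample_ids), list(partition.nml_loci), nml, "NML-band"
        ),
    )


def polymorphic_fraction(matrix: BinaryRecodedMatrix) -> float:
    """Percentage of loci showing >= 2 distinct non-missing values."""
    if matrix.n_samples < 2:
        raise ValueError("polymorphism needs at least two samples")
    if matrix.n_loci == 0:
        return 0.0
    v = matrix.values
    has0 = (v == 0).any(axis=0)
    has1 = (v == 1).any(axis=0)
    return 100.0 * float((has0 & has1).sum()) / matrix.n_loci
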