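"""Synthetic dual-enzyme MSAP datasets (and companion AFLP matrices) with
known ground truth.

The generator emulates a clonal bud-mutation panel: a single reference
variety whose per-locus methylation conditions are drawn from a reference
state distribution, plus mutant groups whose varieties derive from the
reference by state transitions.  Three mechanisms create structure:

* per-group 4x4 state-transition matrices (diagonal-dominant) give each
  group its own expected pattern-change rates;
* a per-(locus, group) shared target state, adopted by each group member
  with probability ``group_coherence``, creates *between-group* variance at
  a locus — the signal AMOVA and the outlier scan detect, which purely
  i.i.d. per-sample transitions would not produce;
* a handful of planted outlier loci receive strongly group-specific
  methylation frequencies (one divergent group per locus, round-robin).

States are converted to (HpaII, MspI) band pairs by the inverse of the
state classification, and band-flip noise is applied per cell afterwards,
modelling scoring error at the electropherogram level (which is what the
MSL error threshold exists to absorb).

The companion AFLP track is generated independently of the methylation
track under a Balding-Nichols model with a configurable among-group
differentiation theta, so the genetic-epigenetic (Mantel) correlation is
null by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import BandMatrix, BandMatrixPair, SampleMetadata, pair_matrices
from .states import StateMatrix

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "make_transition_matrix",
    "generate",
    "generate_aflp",
]

_STATES = (1, 2, 3, 4)  # I, II, III, IV


def make_transition_matrix(
    cg_hyper: float,
    chg_hyper: float,
    cg_hypo: float,
    chg_hypo: float,
    joint: float = 0.01,
) -> np.ndarray:
    """Build a diagonal-dominant 4x4 state-transition matrix from category rates.

    Each rate is the per-locus probability of the corresponding single-context
    transition; ``joint`` feeds the rarer double-context moves.  Rows are
    ordered I, II, III, IV and sum to 1.
    """
    t = np.zeros((4, 4))
    # from I: gain CHG -> II, gain CG -> III, gain both -> IV
    t[0, 1], t[0, 2], t[0, 3] = chg_hyper, cg_hyper, joint
    # from II: lose CHG -> I, swap to CG -> III, gain CG -> IV
    t[1, 0], t[1, 2], t[1, 3] = chg_hypo, joint, cg_hyper
    # from III: lose CG -> I, swap to CHG -> II, gain CHG -> IV
    t[2, 0], t[2, 1], t[2, 3] = cg_hypo, joint, chg_hyper
    # from IV: lose both -> I, lose CG -> II, lose CHG -> III
    t[3, 0], t[3, 1], t[3, 2] = joint, cg_hypo, chg_hypo
    for i in range(4):
        off = t[i].sum()
        if off >= 1.0:
            raise ValueError(f"transition row {i} off-diagonal mass {off} >= 1")
        t[i, i] = 1.0 - off
    return t


_DEFAULT_RATES = {
    "Color": dict(cg_hyper=0.17, chg_hyper=0.17, cg_hypo=0.20, chg_hypo=0.25),
    "Early-maturation": dict(cg_hyper=0.13, chg_hyper=0.16, cg_hypo=0.18, chg_hypo=0.22),
    "Spur": dict(cg_hyper=0.12, chg_hyper=0.15, cg_hypo=0.16, chg_hypo=0.20),
}


def _default_transitions(groups: Sequence[tuple[str, int]]) -> dict[str, np.ndarray]:
    fallback = dict(cg_hyper=0.14, chg_hyper=0.16, cg_hypo=0.18, chg_hypo=0.22)
    return {
        name: make_transition_matrix(**_DEFAULT_RATES.get(name, fallback))
        for name, _ in groups
    }


@dataclass
class SyntheticSpec:
    """Generator settings.  Defaults mirror the Fuji study's panel layout:
    a 2954-locus panel and mutant groups of 51 (Color), 23 (Early-maturation)
    and 17 (Spur) varieties plus the reference.

    ``reference_state_probs`` is the (I, II, III, IV) distribution of the
    reference variety; its observed-band shares (I:II:III renormalised)
    match the published panel means 64.090 / 13.599 / 22.311 with a small
    condition-IV mass.
    """

    n_loci: int = 2954
    groups: tuple[tuple[str, int], ...] = (
        ("Color", 51),
        ("Early-maturation", 23),
        ("Spur", 17),
    )
    reference_state_probs: tuple[float, float, float, float] = (0.614, 0.130, 0.214, 0.042)
    transition_rates: dict[str, np.ndarray] | None = None
    group_coherence: float = 0.2
    n_outlier_loci: int = 16
    outlier_divergence: float = 0.6
    noise_rate: float = 0.01
    seed: int | None = None
    reference_name: str = "Fuji"
    aflp_n_loci: int = 1745
    aflp_differentiation: float = 0.05

    def __post_init__(self) -> None:
        probs = np.asarray(self.reference_state_probs, dtype=float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise ValueError("reference_state_probs must be a probability vector")
        if self.n_outlier_loci > self.n_loci:
            raise ValueError("more planted outlier loci than loci")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0,1)")
        if not 0.0 <= self.group_coherence <= 1.0:
            raise ValueError("group_coherence must be in [0,1]")
        if self.transition_rates is None:
            self.transition_rates = _default_transitions(self.groups)
        for name, _ in self.groups:
            t = np.asarray(self.transition_rates[name], dtype=float)
            if t.shape != (4, 4) or not np.allclose(t.sum(axis=1), 1.0) or t.min() < 0:
                raise ValueError(f"transition matrix for {name!r} is not row-stochastic")
            self.transition_rates[name] = t


@dataclass
class SyntheticTruth:
    """Everything the generator knows: pre-noise states and planted signals."""

    ref_states: np.ndarray  # (n_loci,) reference condition codes
    states: StateMatrix  # pre-noise states, all samples incl. reference
    outlier_locus_ids: list[str]
    group_state_freqs: dict[str, np.ndarray]  # per group, realized P(I..IV)
    realized_phi_pt: float | None = None


def _draw_transitions(
    ref: np.ndarray, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised categorical draw of mutant states given reference states."""
    out = np.empty_like(ref)
    for s in _STATES:
        idx = np.flatnonzero(ref == s)
        if idx.size:
            out[idx] = rng.choice(_STATES, size=idx.size, p=t[s - 1])
    return out


def _states_to_bands(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    hmap = np.array([0, 1, 1, 0, 0], dtype=np.int8)  # index by state code
    mmap = np.array([0, 1, 0, 1, 0], dtype=np.int8)
    return hmap[states], mmap[states]


def generate(
    spec: SyntheticSpec,
) -> tuple[BandMatrixPair, list[SampleMetadata], SyntheticTruth]:
    """Generate a dual-enzyme dataset with metadata and full ground truth.

    Deterministic given ``spec.seed``.  The reference sample is emitted
    first, flagged ``is_reference`` with group ``"Origin"``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_loci
    locus_ids = [f"L{j + 1:05d}" for j in range(L)]

    ref = rng.choice(_STATES, size=L, p=np.asarray(spec.reference_state_probs))

    outlier_idx = np.sort(rng.choice(L, size=spec.n_outlier_loci, replace=False))
    group_names = [name for name, _ in spec.groups]
    # round-robin: each planted locus has one divergent group
    divergent_group = {
        int(j): group_names[k % len(group_names)] for k, j in enumerate(outlier_idx)
    }
    hi = min(0.5 + spec.outlier_divergence / 2, 0.97)
    lo = max(0.5 - spec.outlier_divergence / 2, 0.03)

    sample_ids = [spec.reference_name]
    metadata = [SampleMetadata(spec.reference_name, spec.reference_name, "Origin", True)]
    all_states = [ref.copy()]
    for name, n_samples in spec.groups:
        t = spec.transition_rates[name]
        shared = _draw_transitions(ref, t, rng)
        for k in range(n_samples):
            sid = f"{name}-{k + 1:02d}"
            sample_ids.append(sid)
            metadata.append(SampleMetadata(sid, sid, name, False))
            own = _draw_transitions(ref, t, rng)
            adopt = rng.random(L) < spec.group_coherence
            row = np.where(adopt, shared, own)
            # planted outliers: group-specific methylation frequency
            for j in outlier_idx:
                p_meth = hi if divergent_group[int(j)] == name else lo
                if rng.random() < p_meth:
                    row[j] = 3 if rng.random() < 0.5 else 2  # CG or CHG methylated
                else:
                    row[j] = 1
            all_states.append(row)

    states = np.vstack(all_states).astype(np.int8)
    truth_states = StateMatrix(sample_ids, locus_ids, states.copy())

    h, m = _states_to_bands(states)
    if spec.noise_rate > 0:
        h = np.where(rng.random(h.shape) < spec.noise_rate, 1 - h, h)
        m = np.where(rng.random(m.shape) < spec.noise_rate, 1 - m, m)

    hpa = BandMatrix("synthetic-hpa", "HPA", sample_ids, locus_ids, h)
    msp = BandMatrix("synthetic-msp", "MSP", sample_ids, locus_ids, m)
    pair = pair_matrices(hpa, msp)

    group_freqs: dict[str, np.ndarray] = {}
    offset = 1
    for name, n_samples in spec.groups:
        block = states[offset : offset + n_samples]
        group_freqs[name] = np.array([(block == s).mean() for s in _STATES])
        offset += n_samples

    truth = SyntheticTruth(
        ref_states=ref,
        states=truth_states,
        outlier_locus_ids=[locus_ids[int(j)] for j in outlier_idx],
        group_state_freqs=group_freqs,
        realized_phi_pt=_realized_phi_pt(truth_states, metadata),
    )
    return pair, metadata, truth


def _realized_phi_pt(states: StateMatrix, metadata: list[SampleMetadata]) -> float | None:
    """PhiPT of the noiseless MSL recode — the generator's planted target."""
    from .diversity import amova
    from .states import partition_loci, recode_msl

    groups = {r.sample_id: r.group for r in metadata if not r.is_reference}
    part = partition_loci(states)
    if not part.msl_loci:
        return None
    msl, _ = recode_msl(states, part)
    keep = [i for i, s in enumerate(msl.sample_ids) if s in groups]
    from .states import BinaryRecodedMatrix

    sub = BinaryRecodedMatrix(
        [msl.sample_ids[i] for i in keep],
        msl.locus_ids,
        msl.values[keep],
        msl.semantics_tag,
    )
    try:
        return amova(sub, groups, n_permutations=0, seed=0).phi_pt
    except ValueError:
        return None


def generate_aflp(spec: SyntheticSpec) -> BandMatrix:
    """Independent genetic (AFLP) track under a Balding-Nichols model.

    Per locus, an ancestral band frequency p ~ U(0.1, 0.9); each group's
    frequency is Beta-distributed around p with among-group differentiation
    ``aflp_differentiation`` (theta), and samples are Bernoulli draws.  The
    reference sample draws from the ancestral frequency.  The stream is
    seeded independently of the methylation track (seed offset), so the two
    tracks are statistically independent.
    """
    seed = None if spec.seed is None else (int(spec.seed) + 900_001) % (2**31)
    rng = np.random.default_rng(seed)
    L = spec.aflp_n_loci
    locus_ids = [f"A{j + 1:05d}" for j in range(L)]
    p = rng.uniform(0.1, 0.9, size=L)
    theta = spec.aflp_differentiation
    rows = [(rng.random(L) < p).astype(np.int8)]  # reference
    sample_ids = [spec.reference_name]
    for name, n_samples in spec.groups:
        if theta > 0:
            a = p * (1 - theta) / theta
            b = (1 - p) * (1 - theta) / theta
            pg = rng.beta(a, b)
        else:
            pg = p
        for k in range(n_samples):
            sample_ids.append(f"{name}-{k + 1:02d}")
            rows.append((rng.random(L) < pg).astype(np.int8))
    values = np.vstack(rows)
    if spec.noise_rate > 0:
        values = np.where(rng.random(values.shape) < spec.noise_rate, 1 - values, values)
    return BandMatrix("synthetic-aflp", "AFLP", sample_ids, locus_ids, values.astype(np.int8))
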