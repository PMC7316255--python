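"""Methylation pattern-change classification and the V5-V16 parameter system.

Each mutant variety is compared locus-by-locus against the reference
('Fuji') variety.  Two complementary classifications are produced:

* a *subtype* code (A1..A4, B1..B4, C1..C4, D1..D3) naming the reference
  band class (A = +/+, B = +/-, C = -/+, D = -/-) and the mutant band
  pattern; the fully-absent-to-fully-absent transition (D4) carries no
  information and is excluded;
* a *category set* drawn from {CG-hyper, CHG-hyper, CG-hypo, CHG-hypo},
  derived from the (reference state -> mutant state) transition.  A single
  transition can carry two categories: unmethylated -> fully methylated
  (I -> IV) is simultaneously a CG and a CHG methylation gain.

From these, twelve per-variety epigenetic parameters are computed:

* V5-V8: CHG-hyper, CG-hyper, CG-hypo, CHG-hypo frequencies (percent of a
  fixed locus panel of size T);
* V9 = V5+V6 (total hyper), V10 = V7+V8 (total hypo) — exact sums because
  doubly-categorised transitions increment both addends;
* V11-V15: methylation-level fractions (total, condition I, II, III over
  the variety's observed loci V16; condition IV over the panel T);
* V16: number of observed (band-bearing) loci.

V15 = 100*(T - V16)/T is affine-decreasing in V16, so their Pearson
correlation is exactly -1 whenever the panel size T is held fixed — the
reason the panel denominator, not the per-variety V16, is the default for
pattern frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .states import BANDS_OF_STATE, MethylationState, StateMatrix

__all__ = [
    "PatternSubtype",
    "classify_subtype",
    "categorize_change",
    "change_records",
    "change_frequencies",
    "level_parameters",
    "epi_parameter_table",
    "group_summaries",
    "parameter_correlations",
    "CATEGORIES",
]

CATEGORIES = ("CG-hyper", "CHG-hyper", "CG-hypo", "CHG-hypo")

_REF_CLASS = {(1, 1): "A", (1, 0): "B", (0, 1): "C", (0, 0): "D"}
# Subtype number by mutant band pattern, constant across reference classes.
_MUT_INDEX = {(1, 0): 1, (1, 1): 2, (0, 1): 3, (0, 0): 4}
_PATTERN_STR = {(1, 1): "+/+", (1, 0): "+/-", (0, 1): "-/+", (0, 0): "-/-"}


@dataclass(frozen=True)
class PatternSubtype:
    """One of the 15 valid reference->mutant band transitions."""

    ref_class: str  # A/B/C/D
    mut_pattern: str  # "+/-" etc.
    code: str  # e.g. "A1"


def classify_subtype(
    ref_bands: tuple[int, int], mut_bands: tuple[int, int]
) -> PatternSubtype | None:
    """Code the reference->mutant band transition; None for D4 or missing.

    ``ref_bands`` and ``mut_bands`` are (HpaII, MspI) presence calls.  The
    absent-in-both to absent-in-both transition (D4) is not a recordable
    pattern; any missing band makes the pair unclassifiable.  Both return
    ``None`` and are excluded from frequency denominators' numerators.
    """
    if -1 in ref_bands or -1 in mut_bands:
        return None
    ref = (int(ref_bands[0]), int(ref_bands[1]))
    mut = (int(mut_bands[0]), int(mut_bands[1]))
    if ref == (0, 0) and mut == (0, 0):
        return None
    cls = _REF_CLASS[ref]
    return PatternSubtype(cls, _PATTERN_STR[mut], f"{cls}{_MUT_INDEX[mut]}")


# Transition -> category set, transcribed from the four published lists
# (in H/M notation: I=H1M1, II=H1M0, III=H0M1, IV=H0M0).
# (a) CG hyper:  I->III, II->IV, II->III, I->IV
# (b) CHG hyper: I->II, III->IV, I->IV, III->II
# (c) CG hypo:   III->I, IV->II, III->II
# (d) CHG hypo:  II->I, IV->III, II->III, IV->I
_S = MethylationState
_CATEGORY_OF: dict[tuple[int, int], frozenset[str]] = {}
for _ref in (_S.I, _S.II, _S.III, _S.IV):
    for _mut in (_S.I, _S.II, _S.III, _S.IV):
        _CATEGORY_OF[(_ref, _mut)] = frozenset()


def _add(cat: str, pairs: Iterable[tuple[int, int]]) -> None:
    for p in pairs:
        _CATEGORY_OF[p] = _CATEGORY_OF[p] | {cat}


_add("CG-hyper", [(_S.I, _S.III), (_S.II, _S.IV), (_S.II, _S.III), (_S.I, _S.IV)])
_add("CHG-hyper", [(_S.I, _S.II), (_S.III, _S.IV), (_S.I, _S.IV), (_S.III, _S.II)])
_add("CG-hypo", [(_S.III, _S.I), (_S.IV, _S.II), (_S.III, _S.II)])
_add("CHG-hypo", [(_S.II, _S.I), (_S.IV, _S.III), (_S.II, _S.III), (_S.IV, _S.I)])


def categorize_change(
    ref_state: MethylationState, mut_state: MethylationState
) -> frozenset[str]:
    """Category set of a state transition; empty set means no change.

    Exact membership follows the four published lists.  Note their one
    asymmetry: I->IV carries both hyper categories, while the reverse IV->I
    is listed only as CHG-hypo.
    """
    if ref_state == MethylationState.MISSING or mut_state == MethylationState.MISSING:
        raise ValueError("categorize_change is defined on states I-IV only")
    return _CATEGORY_OF[(ref_state, mut_state)]


def change_records(states: StateMatrix, reference_sample: str) -> pd.DataFrame:
    """Long-format per-(sample, locus) subtype and category records.

    Loci where either the reference or the mutant state is missing are
    skipped.  The reference sample itself is not compared against itself.
    """
    ref_row = states.row(reference_sample)
    out = []
    for i, sid in enumerate(states.sample_ids):
        if sid == reference_sample:
            continue
        for j, locus in enumerate(states.locus_ids):
            r, m = int(ref_row[j]), int(states.states[i, j])
            if r == MethylationState.MISSING or m == MethylationState.MISSING:
                continue
            sub = classify_subtype(BANDS_OF_STATE[_S(r)], BANDS_OF_STATE[_S(m)])
            cats = _CATEGORY_OF[(r, m)]
            out.append(
                {
                    "sample_id": sid,
                    "locus_id": locus,
                    "subtype": sub.code if sub else "",
                    "categories": ";".join(sorted(cats)),
                }
            )
    return pd.DataFrame(out, columns=["sample_id", "locus_id", "subtype", "categories"])


def change_frequencies(
    states: StateMatrix, reference_sample: str, panel_total: int
) -> pd.DataFrame:
    """Per-sample V5-V10 pattern-change frequencies (percent of panel).

    V5 CHG-hyper, V6 CG-hyper, V7 CG-hypo, V8 CHG-hypo, V9 = V5+V6,
    V10 = V7+V8.  A locus whose transition carries two categories counts
    once in each.  Denominator is the fixed panel size ``panel_total``.
    """
    if panel_total < states.n_loci:
        raise ValueError(
            f"panel_total {panel_total} smaller than scored loci {states.n_loci}"
        )
    ref_row = states.row(reference_sample)
    cat_keys = {"V5": "CHG-hyper", "V6": "CG-hyper", "V7": "CG-hypo", "V8": "CHG-hypo"}
    rows = {}
    for i, sid in enumerate(states.sample_ids):
        if sid == reference_sample:
            continue
        counts = dict.fromkeys(cat_keys, 0)
        row = states.states[i]
        valid = (ref_row != 0) & (row != 0)
        for r, m in zip(ref_row[valid], row[valid]):
            cats = _CATEGORY_OF[(int(r), int(m))]
            for k, cat in cat_keys.items():
                if cat in cats:
                    counts[k] += 1
        freqs = {k: 100.0 * c / panel_total for k, c in counts.items()}
        freqs["V9"] = freqs["V5"] + freqs["V6"]
        freqs["V10"] = freqs["V7"] + freqs["V8"]
        rows[sid] = freqs
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df[["V5", "V6", "V7", "V8", "V9", "V10"]]


def level_parameters(states: StateMatrix, panel_total: int) -> pd.DataFrame:
    """Per-sample V11-V16 methylation-level parameters.

    V16 = observed loci (conditions I-III); V12/V13/V14 = percent of V16 in
    condition I/II/III; V11 = V13+V14 (total methylation of observed loci);
    V15 = percent of the fixed panel absent from the sample,
    100*(T-V16)/T.
    """
    rows = {}
    for i, sid in enumerate(states.sample_ids):
        row = states.states[i]
        n = {s: int((row == s).sum()) for s in (1, 2, 3, 4)}
        v16 = n[1] + n[2] + n[3]
        if v16 == 0:
            raise ZeroDivisionError(f"{sid}: no observed loci, V11-V14 undefined")
        rows[sid] = {
            "V11": 100.0 * (n[2] + n[3]) / v16,
            "V12": 100.0 * n[1] / v16,
            "V13": 100.0 * n[2] / v16,
            "V14": 100.0 * n[3] / v16,
            "V15": 100.0 * (panel_total - v16) / panel_total,
            "V16": float(v16),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df


def epi_parameter_table(
    states: StateMatrix, reference_sample: str, panel_total: int | None = None
) -> pd.DataFrame:
    """Join V5-V10 and V11-V16 for every non-reference sample.

    ``panel_total`` defaults to the number of scored loci in the dataset.
    The table carries the panel size in ``df.attrs["panel_total"]``.
    """
    T = panel_total if panel_total is not None else states.n_loci
    freqs = change_frequencies(states, reference_sample, T)
    levels = level_parameters(states, T).drop(index=reference_sample, errors="ignore")
    df = freqs.join(levels)
    df.attrs["panel_total"] = T
    return df


def group_summaries(
    table: pd.DataFrame, groups: Mapping[str, str], parameters: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean, sample SD (n-1) and CV% per (group, parameter).

    CV = SD/mean * 100.  Singleton groups get NaN SD/CV; a zero group mean
    leaves CV NaN (undefined) rather than infinite.
    """
    params = list(parameters) if parameters is not None else list(table.columns)
    glabels = pd.Series({s: groups[s] for s in table.index if s in groups})
    out = []
    for grp, members in glabels.groupby(glabels):
        sub = table.loc[members.index, params]
        for p in params:
            vals = sub[p].astype(float)
            mean = vals.mean()
            sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
            cv = 100.0 * sd / mean if mean != 0 and not np.isnan(sd) else np.nan
            out.append(
                {"group": grp, "parameter": p, "n": len(vals), "mean": mean, "sd": sd, "cv": cv}
            )
    return pd.DataFrame(out)


def parameter_correlations(
    table: pd.DataFrame,
    parameters: Sequence[str] | None = None,
    *,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of the V-parameters with two-sided p.

    Needs >= 3 samples.  Zero-variance parameters yield NaN entries (their
    correlation is undefined), matching how degenerate columns are flagged
    rather than dropped.  ``holm=True`` applies a Holm step-down correction
    over the distinct pairs.
    """
    params = list(parameters) if parameters is not None else list(table.columns)
    if len(table) < 3:
        raise ValueError("parameter correlations need at least 3 samples")
    k = len(params)
    r = pd.DataFrame(np.eye(k), index=params, columns=params)
    p = pd.DataFrame(np.zeros((k, k)), index=params, columns=params)
    pairs = []
    for a in range(k):
        for b in range(a + 1, k):
            x = table[params[a]].astype(float).to_numpy()
            y = table[params[b]].astype(float).to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                rv, pv = np.nan, np.nan
            else:
                rv, pv = stats.pearsonr(x, y)
            r.iloc[a, b] = r.iloc[b, a] = rv
            p.iloc[a, b] = p.iloc[b, a] = pv
            pairs.append((a, b, pv))
    if holm:
        valid = [(a, b, pv) for a, b, pv in pairs if not np.isnan(pv)]
        m = len(valid)
        for rank, (a, b, pv) in enumerate(sorted(valid, key=lambda t: t[2])):
            adj = min(1.0, pv * (m - rank))
            p.iloc[a, b] = p.iloc[b, a] = adj
    return r, p
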