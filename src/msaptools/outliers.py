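"""Bayesian FST-outlier scan for dominant binary data.

The model decomposes locus-by-population differentiation logistically:

    logit(F_ij) = alpha_i + beta_j

where ``F_ij`` is the FST-like divergence of locus *i* in population *j*,
``beta_j`` a population effect (shared demography/drift) and ``alpha_i`` a
locus-specific selection effect.  Group band frequencies are modelled
hierarchically: the latent frequency of locus *i* in population *j* is
Beta-distributed around the ancestral frequency ``p_i`` with precision
``(1 - F_ij)/F_ij``, and the observed count of state-1 samples ``a_ij`` is
binomial.  The latent frequency is integrated out analytically, giving a
beta-binomial likelihood

    a_ij ~ BetaBin(n_j; p_i * t_ij, (1 - p_i) * t_ij),   t_ij = (1-F_ij)/F_ij

which leaves (p, alpha, beta) as the only sampled parameters.

A reversible-jump move toggles each ``alpha_i`` in and out of the model;
prior odds of ``prior_odds_neutral : 1`` favour exclusion (neutrality).
The posterior inclusion probability P_i yields posterior odds
``PO_i = P_i/(1-P_i) * prior_odds_neutral`` (the Bayes factor for
selection); log10(PO) > 2 is "strong evidence" on Jeffreys' scale.
q-values are the cumulative mean of (1 - P_i) down the list ranked by
decreasing P_i (the mean posterior error rate of the rejection set), and a
locus is an outlier when its q-value is at or below the target FDR.

Band frequencies are treated as the evolving character directly (no
dominant-marker recessive-genotype deconvolution), consistent with the
band-phenotype convention of the diversity module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit

from .io import MISSING
from .states import BinaryRecodedMatrix

__all__ = [
    "LocusGroupCounts",
    "ScanConfig",
    "tabulate_counts",
    "posterior_odds",
    "run_scan",
    "classify_selection",
    "group_outlier_frequencies",
]

logger = logging.getLogger(__name__)


@dataclass
class LocusGroupCounts:
    """Per-locus, per-group counts of state-1 samples and scored samples."""

    locus_ids: list[str]
    group_names: list[str]
    a: np.ndarray  # (loci, groups) state-1 counts
    n: np.ndarray  # (loci, groups) scored samples

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.a.shape != self.n.shape or self.a.shape != (
            len(self.locus_ids),
            len(self.group_names),
        ):
            raise ValueError("count array shapes do not match id lists")
        if (self.a < 0).any() or (self.a > self.n).any():
            raise ValueError("counts must satisfy 0 <= a <= n")


def tabulate_counts(
    matrix: BinaryRecodedMatrix, groups: Mapping[str, str]
) -> LocusGroupCounts:
    """Count state-1 and scored samples per locus and group.

    Missing cells are excluded.  A locus with zero scored samples in any
    group is dropped (and logged) — its group frequency is undefined.
    """
    labels = [groups[s] for s in matrix.sample_ids if s in groups]
    rows = [i for i, s in enumerate(matrix.sample_ids) if s in groups]
    if len(set(labels)) < 2:
        raise ValueError("outlier scan needs at least two groups")
    group_names = sorted(set(labels))
    v = matrix.values[rows]
    lab = np.array(labels)
    a = np.zeros((matrix.n_loci, len(group_names)), dtype=np.int64)
    n = np.zeros_like(a)
    for j, g in enumerate(group_names):
        sub = v[lab == g]
        a[:, j] = (sub == 1).sum(axis=0)
        n[:, j] = (sub != MISSING).sum(axis=0)
    keep = (n > 0).all(axis=1)
    dropped = [c for c, k in zip(matrix.locus_ids, keep) if not k]
    if dropped:
        logger.warning("excluding %d loci unscored in an entire group", len(dropped))
    loci = [c for c, k in zip(matrix.locus_ids, keep) if k]
    return LocusGroupCounts(loci, group_names, a[keep], n[keep])


@dataclass
class ScanConfig:
    """MCMC settings.  Defaults are the published full-scale run lengths.

    Total post-pilot iterations are ``burn_in + sample_size * thinning``;
    posterior summaries use ``sample_size`` draws taken every ``thinning``
    iterations after burn-in.  ``prior_odds_neutral`` is the prior odds of
    the neutral (alpha excluded) model over selection.
    """

    n_pilot: int = 10
    pilot_length: int = 5000
    burn_in: int = 50_000
    thinning: int = 20
    sample_size: int = 5000
    prior_odds_neutral: float = 10.0
    fdr: float = 0.05
    seed: int | None = None

    @property
    def main_iterations(self) -> int:
        return self.burn_in + self.sample_size * self.thinning

    def __post_init__(self) -> None:
        if self.prior_odds_neutral <= 0:
            raise ValueError("prior_odds_neutral must be positive")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0,1)")

    @classmethod
    def reduced(cls, seed: int | None = None) -> "ScanConfig":
        """A scaled-down configuration (20k main iterations) for small panels."""
        return cls(
            n_pilot=5,
            pilot_length=1000,
            burn_in=10_000,
            thinning=5,
            sample_size=2000,
            seed=seed,
        )


# Priors: alpha ~ N(0,1); beta ~ N(-1,1); p ~ Uniform(0,1).
_ALPHA_SD = 1.0
_BETA_MEAN, _BETA_SD = -1.0, 1.0
_ACC_LO, _ACC_HI = 0.25, 0.45


class _Model:
    """Vectorised likelihood and samplers; loci are conditionally independent."""

    def __init__(self, counts: LocusGroupCounts, config: ScanConfig, rng: np.random.Generator):
        self.a = counts.a.astype(float)
        self.n = counts.n.astype(float)
        self.L, self.J = self.a.shape
        self.cfg = config
        self.rng = rng
        # init: p from pooled frequency (shrunk off the boundary), alpha off, beta at prior mean
        pooled = (self.a.sum(axis=1) + 1.0) / (self.n.sum(axis=1) + 2.0)
        self.p = pooled
        self.alpha = np.zeros(self.L)
        self.delta = np.zeros(self.L, dtype=bool)
        self.beta = np.full(self.J, _BETA_MEAN)
        # proposal widths, tuned by pilots
        self.w_p = np.full(self.L, 0.5)
        self.w_alpha = np.full(self.L, 0.7)
        self.w_beta = np.full(self.J, 0.3)
        self.ll = self._loglik(self.p, self.alpha * self.delta, self.beta)

    def _loglik(self, p: np.ndarray, alpha_eff: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """(L, J) beta-binomial log-likelihood, binomial coefficient dropped."""
        f = expit(alpha_eff[:, None] + beta[None, :])
        t = (1.0 - f) / f
        ap = p[:, None] * t
        bp = (1.0 - p[:, None]) * t
        return betaln(self.a + ap, self.n - self.a + bp) - betaln(ap, bp)

    # -- per-iteration updates ------------------------------------------------

    def update_p(self) -> float:
        z = logit(self.p) + self.rng.normal(0.0, self.w_p)
        p_new = expit(z)
        ll_new = self._loglik(p_new, self.alpha * self.delta, self.beta)
        # uniform prior on p with logit-scale RW: Jacobian p(1-p)
        log_acc = (
            ll_new.sum(axis=1)
            - self.ll.sum(axis=1)
            + np.log(p_new * (1 - p_new))
            - np.log(self.p * (1 - self.p))
        )
        acc = np.log(self.rng.random(self.L)) < log_acc
        self.p[acc] = p_new[acc]
        self.ll[acc] = ll_new[acc]
        return float(acc.mean())

    def update_alpha(self) -> float:
        inc = self.delta
        if not inc.any():
            return np.nan
        prop = self.alpha + self.rng.normal(0.0, self.w_alpha)
        ll_new = self._loglik(self.p, prop * self.delta, self.beta)
        log_acc = (
            ll_new.sum(axis=1)
            - self.ll.sum(axis=1)
            - 0.5 * (prop**2 - self.alpha**2) / _ALPHA_SD**2
        )
        acc = inc & (np.log(self.rng.random(self.L)) < log_acc)
        self.alpha[acc] = prop[acc]
        self.ll[acc] = ll_new[acc]
        return float(acc[inc].mean())

    def update_rj(self) -> None:
        """Toggle each alpha's inclusion; proposal for a new alpha is its prior,
        so prior and proposal densities cancel in the acceptance ratio."""
        pi_incl = 1.0 / (1.0 + self.cfg.prior_odds_neutral)
        log_prior_odds = math.log(pi_incl) - math.log(1.0 - pi_incl)
        prop_alpha = np.where(
            self.delta, self.alpha, self.rng.normal(0.0, _ALPHA_SD, self.L)
        )
        ll_on = self._loglik(self.p, prop_alpha, self.beta)
        ll_off = self._loglik(self.p, np.zeros(self.L), self.beta)
        # birth: off -> on; death: on -> off
        log_acc_birth = ll_on.sum(axis=1) - ll_off.sum(axis=1) + log_prior_odds
        log_acc_death = -log_acc_birth
        u = np.log(self.rng.random(self.L))
        birth = ~self.delta & (u < log_acc_birth)
        death = self.delta & (u < log_acc_death)
        self.delta[birth] = True
        self.alpha[birth] = prop_alpha[birth]
        self.ll[birth] = ll_on[birth]
        self.delta[death] = False
        self.ll[death] = ll_off[death]

    def _loglik_col(self, j: int, beta_j: float) -> np.ndarray:
        f = expit(self.alpha * self.delta + beta_j)
        t = (1.0 - f) / f
        ap = self.p * t
        bp = (1.0 - self.p) * t
        return betaln(self.a[:, j] + ap, self.n[:, j] - self.a[:, j] + bp) - betaln(ap, bp)

    def update_beta(self) -> float:
        acc_count = 0
        for j in range(self.J):
            prop_j = self.beta[j] + self.rng.normal(0.0, self.w_beta[j])
            ll_new = self._loglik_col(j, prop_j)
            log_acc = (
                ll_new.sum()
                - self.ll[:, j].sum()
                - 0.5 * ((prop_j - _BETA_MEAN) ** 2 - (self.beta[j] - _BETA_MEAN) ** 2)
                / _BETA_SD**2
            )
            if math.log(self.rng.random()) < log_acc:
                self.beta[j] = prop_j
                self.ll[:, j] = ll_new
                acc_count += 1
        return acc_count / self.J

    def sweep(self) -> tuple[float, float, float]:
        ap = self.update_p()
        aa = self.update_alpha()
        self.update_rj()
        ab = self.update_beta()
        return ap, aa, ab

    def fst(self) -> np.ndarray:
        """Per-locus F averaged over populations at the current state."""
        f = expit((self.alpha * self.delta)[:, None] + self.beta[None, :])
        return f.mean(axis=1)


def _tune(width: np.ndarray, rate: float | np.ndarray) -> np.ndarray:
    rate = np.asarray(rate, dtype=float)
    width = np.where(rate < _ACC_LO, width * 0.8, width)
    width = np.where(rate > _ACC_HI, width * 1.2, width)
    return width


def posterior_odds(
    prob: np.ndarray | float, prior_odds_neutral: float, n_samples: int | None = None
) -> np.ndarray | float:
    """Bayes factor for selection: P/(1-P) scaled by the neutral prior odds.

    With prior odds 10:1 for neutrality, an inclusion probability of 0.5
    gives posterior odds 10 (log10 PO = 1).  When ``n_samples`` is given,
    P is capped away from 0/1 at the Monte-Carlo resolution so the odds
    stay finite.
    """
    p = np.asarray(prob, dtype=float)
    if n_samples:
        p = np.clip(p, 1.0 / (2 * n_samples), 1.0 - 1.0 / (2 * n_samples))
    out = p / (1.0 - p) * prior_odds_neutral
    return out if out.ndim else float(out)


def run_scan(counts: LocusGroupCounts, config: ScanConfig | None = None) -> pd.DataFrame:
    """Run the RJ-MCMC scan and summarise posteriors per locus.

    Returns a DataFrame indexed by locus with columns ``alpha_mean``
    (posterior mean of alpha conditional on inclusion; 0 if never
    included), ``fst_mean``, ``posterior_prob_selection``, ``log10_po``,
    ``q_value``, ``decision`` (diversifying/purifying-or-neutral by the
    sign of alpha_mean) and ``is_outlier`` (q <= fdr).
    """
    config = config or ScanConfig()
    if len(counts.group_names) < 2:
        raise ValueError("the scan is unidentifiable with a single group")
    rng = np.random.default_rng(config.seed)
    model = _Model(counts, config, rng)

    for pilot in range(config.n_pilot):
        accs = np.zeros(3)
        n_acc = np.zeros(3)
        for _ in range(config.pilot_length):
            rates = model.sweep()
            for k, r in enumerate(rates):
                if not np.isnan(r):
                    accs[k] += r
                    n_acc[k] += 1
        mean_rates = np.where(n_acc > 0, accs / np.maximum(n_acc, 1), 0.35)
        model.w_p = _tune(model.w_p, mean_rates[0])
        model.w_alpha = _tune(model.w_alpha, mean_rates[1])
        model.w_beta = _tune(model.w_beta, mean_rates[2])
        if pilot == config.n_pilot - 1 and not (
            (_ACC_LO * 0.5 <= mean_rates[0] <= _ACC_HI * 1.8)
        ):
            logger.warning(
                "pilot acceptance rates %s outside target band after tuning", mean_rates
            )

    for _ in range(config.burn_in):
        model.sweep()

    sum_delta = np.zeros(model.L)
    sum_alpha = np.zeros(model.L)
    n_incl = np.zeros(model.L)
    sum_fst = np.zeros(model.L)
    for _ in range(config.sample_size):
        for _ in range(config.thinning):
            model.sweep()
        sum_delta += model.delta
        sum_alpha += np.where(model.delta, model.alpha, 0.0)
        n_incl += model.delta
        sum_fst += model.fst()

    S = config.sample_size
    prob = sum_delta / S
    po = posterior_odds(prob, config.prior_odds_neutral, n_samples=S)
    alpha_mean = np.where(n_incl > 0, sum_alpha / np.maximum(n_incl, 1), 0.0)
    fst_mean = sum_fst / S

    order = np.argsort(-prob, kind="stable")
    q = np.empty(model.L)
    q[order] = np.cumsum(1.0 - prob[order]) / np.arange(1, model.L + 1)
    # enforce monotone non-decreasing q along the ranked list
    q[order] = np.minimum.accumulate(q[order][::-1])[::-1]

    df = pd.DataFrame(
        {
            "alpha_mean": alpha_mean,
            "fst_mean": fst_mean,
            "posterior_prob_selection": prob,
            "log10_po": np.log10(po),
            "q_value": q,
            "decision": np.where(alpha_mean > 0, "diversifying", "purifying/neutral"),
            "is_outlier": q <= config.fdr,
        },
        index=pd.Index(counts.locus_ids, name="locus_id"),
    )
    return df


def classify_selection(results: pd.DataFrame) -> dict:
    """Counts/percentages of positive vs negative alpha and the outlier list."""
    n = len(results)
    if n == 0:
        return {
            "n_loci": 0,
            "n_positive_alpha": 0,
            "n_negative_alpha": 0,
            "pct_positive": float("nan"),
            "pct_negative": float("nan"),
            "outlier_loci": [],
        }
    pos = int((results["alpha_mean"] > 0).sum())
    neg = n - pos
    return {
        "n_loci": n,
        "n_positive_alpha": pos,
        "n_negative_alpha": neg,
        "pct_positive": 100.0 * pos / n,
        "pct_negative": 100.0 * neg / n,
        "outlier_loci": list(results.index[results["is_outlier"]]),
    }


def group_outlier_frequencies(
    matrix: BinaryRecodedMatrix,
    groups: Mapping[str, str],
    outlier_loci: Sequence[str],
    majority_threshold: float = 0.5,
) -> pd.DataFrame:
    """State-1 frequency of each outlier locus per group, with specificity.

    A locus is *specific* to a group when its frequency there strictly
    exceeds ``majority_threshold``.
    """
    counts = tabulate_counts(matrix, groups)
    idx = [counts.locus_ids.index(c) for c in outlier_loci if c in counts.locus_ids]
    freq = counts.a[idx] / counts.n[idx]
    df = pd.DataFrame(
        freq,
        index=pd.Index([counts.locus_ids[i] for i in idx], name="locus_id"),
        columns=counts.group_names,
    )
    for g in counts.group_names:
        df[f"specific_{g}"] = df[g] > majority_threshold
    return df
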