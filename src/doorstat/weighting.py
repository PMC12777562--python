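"""IPTW-weighted DOOR analyses for nonrandomized comparisons.

When treatment assignment depends on measured baseline covariates, the
unweighted DOOR probability contrasts the arms as observed, confounding the
treatment effect with case mix.  Reweighting each participant by the inverse
probability of the treatment actually received (stabilized by the marginal
arm probability) recovers the marginal contrast that randomization would
have produced, under the usual no-unmeasured-confounding and positivity
assumptions.

Propensity scores are inputs — this module constructs weights from supplied
scores and computes weighted analogues of the rank- and grade-based
estimators, with stratified-bootstrap percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import EffectEstimate, GradingKey, PatientDataset
from .rank import EstimationError

__all__ = [
    "WeightedPairCounts",
    "stabilized_weights",
    "weighted_pair_counts",
    "weighted_door",
    "weighted_partial_credit",
]


@dataclass(frozen=True)
class WeightedPairCounts:
    """Win/tie/loss weight-mass over cross-arm pairs (Σ w_i·w_j per outcome).

    Reduces to ordinary pair counts under unit weights.  ``ess1``/``ess2``
    are Kish effective sample sizes (Σw)²/Σw² per arm.
    """

    wins: float
    ties: float
    losses: float
    ess1: float
    ess2: float

    @property
    def total(self) -> float:
        return self.wins + self.ties + self.losses


def stabilized_weights(
    data: PatientDataset, truncate_percentiles: tuple[float, float] = (0.0, 100.0)
) -> PatientDataset:
    """Attach stabilized IPTW weights computed from supplied propensity scores.

    weight = P(arm = experimental)/e for experimental participants and
    (1 − P(exp))/(1 − e) for controls, where e is the participant's
    propensity of receiving the experimental arm.  Weights beyond the given
    percentiles of the weight distribution are truncated, with the count
    reported via a warning.
    """
    if "propensity" not in data.df.columns or data.df["propensity"].isna().any():
        missing = (
            data.df.index[data.df["propensity"].isna()].tolist()
            if "propensity" in data.df.columns
            else "all"
        )
        raise EstimationError(f"propensity scores missing for records: {missing}")
    e = data.df["propensity"].to_numpy(dtype=float)
    is_exp = (data.df["arm"] == data.experimental).to_numpy()
    marginal = float(is_exp.mean())
    w = np.where(is_exp, marginal / e, (1.0 - marginal) / (1.0 - e))
    lo_pct, hi_pct = truncate_percentiles
    if (lo_pct, hi_pct) != (0.0, 100.0):
        lo, hi = np.percentile(w, [lo_pct, hi_pct])
        n_trunc = int(((w < lo) | (w > hi)).sum())
        if n_trunc:
            import warnings

            warnings.warn(f"truncated {n_trunc} extreme weight(s)", UserWarning, stacklevel=2)
        w = np.clip(w, lo, hi)
    return data.with_weights(w)


def _arm_weight_by_category(data: PatientDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-category summed weight for (experimental, control)."""
    K = data.scheme.K
    exp, ctl = data.arm_frames()
    out = []
    for frame in (exp, ctl):
        cats = frame["category"].astype(int).to_numpy()
        w = frame["weight"].to_numpy(dtype=float)
        out.append(np.bincount(cats, weights=w, minlength=K + 1)[1:])
    return out[0], out[1]


def weighted_pair_counts(data: PatientDataset) -> WeightedPairCounts:
    """Weighted win/tie/loss mass via the closed-form category cross-tabulation."""
    wa, wb = _arm_weight_by_category(data)
    if wa.sum() <= 0 or wb.sum() <= 0:
        raise EstimationError("total weight must be positive in both arms")
    tail_b = np.concatenate([np.cumsum(wb[::-1])[::-1][1:], [0.0]])
    wins = float(np.dot(wa, tail_b))
    ties = float(np.dot(wa, wb))
    total = float(wa.sum() * wb.sum())
    exp, ctl = data.arm_frames()
    ess = []
    for frame in (exp, ctl):
        w = frame["weight"].to_numpy(dtype=float)
        ess.append(float(w.sum() ** 2 / np.dot(w, w)))
    return WeightedPairCounts(wins, ties, total - wins - ties, ess[0], ess[1])


def _weighted_p(data: PatientDataset) -> float:
    pc = weighted_pair_counts(data)
    return (pc.wins + pc.ties / 2.0) / pc.total


def _weighted_grade_diff(data: PatientDataset, key: GradingKey) -> float:
    wa, wb = _arm_weight_by_category(data)
    g = key.as_array()
    return float(np.dot(wa, g) / wa.sum() - np.dot(wb, g) / wb.sum())


def _stratified_bootstrap(
    data: PatientDataset,
    statistic,
    n_boot: int,
    seed: int | np.random.Generator,
    level: float,
) -> tuple[float, float, np.ndarray]:
    """Percentile bootstrap resampling participants within each arm."""
    rng = np.random.default_rng(seed)
    cc = data.complete()
    is_exp = (cc["arm"] == data.experimental).to_numpy()
    cats = cc["category"].astype(int).to_numpy()
    w = cc["weight"].to_numpy(dtype=float)
    K = data.scheme.K
    idx_exp = np.flatnonzero(is_exp)
    idx_ctl = np.flatnonzero(~is_exp)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx_exp, size=len(idx_exp)), rng.choice(idx_ctl, size=len(idx_ctl))]
        )
        wa = np.bincount(cats[take[: len(idx_exp)]], weights=w[take[: len(idx_exp)]],
                         minlength=K + 1)[1:]
        wb = np.bincount(cats[take[len(idx_exp):]], weights=w[take[len(idx_exp):]],
                         minlength=K + 1)[1:]
        stats[b] = statistic(wa, wb)
    stats = stats[~np.isnan(stats)]  # replicates whose resample left an arm weightless
    alpha = 1.0 - level
    if len(stats) == 0:
        return float("nan"), float("nan"), stats
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi), stats


def weighted_door(
    data: PatientDataset,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> EffectEstimate:
    """IPTW-weighted DOOR probability with a stratified-bootstrap percentile CI.

    p̂_w = Σ_{i∈exp, j∈ctl} w_i w_j [win + ½·tie] / Σ w_i w_j.  Identical to
    the unweighted estimator when all weights are 1.  The bootstrap resamples
    participants (with their weights) within each arm.
    """
    pc = weighted_pair_counts(data)
    p = (pc.wins + pc.ties / 2.0) / pc.total

    def stat(wa: np.ndarray, wb: np.ndarray) -> float:
        if wa.sum() <= 0 or wb.sum() <= 0:
            return np.nan
        tail_b = np.concatenate([np.cumsum(wb[::-1])[::-1][1:], [0.0]])
        wins = np.dot(wa, tail_b)
        ties = np.dot(wa, wb)
        return float((wins + ties / 2.0) / (wa.sum() * wb.sum()))

    lo, hi, _ = _stratified_bootstrap(data, stat, n_boot, seed, level)
    lo = p if np.isnan(lo) else min(lo, p)
    hi = p if np.isnan(hi) else max(hi, p)
    return EffectEstimate(
        p, lo, hi, level, None, f"iptw-bootstrap(B={n_boot})", "probability",
        data.n1, data.n2,
        extras={"ess_experimental": pc.ess1, "ess_control": pc.ess2},
    )


def weighted_partial_credit(
    data: PatientDataset,
    key: GradingKey,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> EffectEstimate:
    """IPTW-weighted difference in mean grades with a bootstrap percentile CI."""
    if key.K != data.scheme.K:
        raise ValueError("grading key length must match the number of DOOR categories")
    diff = _weighted_grade_diff(data, key)
    g = key.as_array()

    def stat(wa: np.ndarray, wb: np.ndarray) -> float:
        if wa.sum() <= 0 or wb.sum() <= 0:
            return np.nan
        return float(np.dot(wa, g) / wa.sum() - np.dot(wb, g) / wb.sum())

    lo, hi, _ = _stratified_bootstrap(data, stat, n_boot, seed, level)
    lo = diff if np.isnan(lo) else min(lo, diff)
    hi = diff if np.isnan(hi) else max(hi, diff)
    return EffectEstimate(
        diff, lo, hi, level, None, f"iptw-bootstrap(B={n_boot})", "grade-points",
        data.n1, data.n2,
    )
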