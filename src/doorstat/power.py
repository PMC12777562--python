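"""Design-stage power and sample-size evaluation for the WMW test of the
DOOR probability.

A design scenario specifies the per-arm multinomial category distributions.
The true DOOR probability implied by the two multinomials has the closed
form Σ_k π_exp,k (Σ_{j>k} π_ctl,j + ½ π_ctl,k); power for the two-sided WMW
test at a given per-arm sample size is estimated by simulating multinomial
trials, with a binomial Monte-Carlo confidence interval attached.  The
sample-size search bisects over n using common random numbers (nested
per-patient category draws) so that estimated power is monotone in n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binomtest, norm

__all__ = [
    "DesignScenario",
    "PowerResult",
    "true_door_probability",
    "power_sim",
    "sample_size_search",
]


@dataclass(frozen=True)
class DesignScenario:
    """Two-arm multinomial design: category probabilities (most desirable
    first), per-arm sample size, test level, number of simulated trials and
    seed."""

    probs_exp: tuple[float, ...]
    probs_ctl: tuple[float, ...]
    n_per_arm: int
    alpha: float = 0.05
    n_sims: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in (("probs_exp", self.probs_exp), ("probs_ctl", self.probs_ctl)):
            arr = np.asarray(p, dtype=float)
            if arr.ndim != 1 or len(arr) < 2:
                raise ValueError(f"{name} must be a vector of ≥ 2 category probabilities")
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if len(self.probs_exp) != len(self.probs_ctl):
            raise ValueError("both arms must use the same number of categories")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        if self.n_sims < 100:
            raise ValueError("n_sims must be at least 100")
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be at least 2")


@dataclass(frozen=True)
class PowerResult:
    power: float
    mc_ci: tuple[float, float]
    n_per_arm: int
    n_sims: int
    alpha: float
    seed: int
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "power": self.power,
            "mc_ci_low": self.mc_ci[0],
            "mc_ci_high": self.mc_ci[1],
            "n_per_arm": self.n_per_arm,
            "n_sims": self.n_sims,
            "alpha": self.alpha,
            "seed": self.seed,
            **self.extras,
        }


def true_door_probability(probs_exp, probs_ctl) -> float:
    """Population DOOR probability implied by two category distributions."""
    pe = np.asarray(probs_exp, dtype=float)
    pc = np.asarray(probs_ctl, dtype=float)
    tail_c = np.concatenate([np.cumsum(pc[::-1])[::-1][1:], [0.0]])
    return float(np.dot(pe, tail_c + 0.5 * pc))


def _wmw_reject(A: np.ndarray, B: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized two-sided tie-corrected WMW rejection over stacked tables.

    A, B: (S, K) category counts per simulated trial.
    """
    n1 = A.sum(axis=1, keepdims=True).astype(float)
    n2 = B.sum(axis=1, keepdims=True).astype(float)
    tail_B = np.concatenate(
        [np.cumsum(B[:, ::-1], axis=1)[:, ::-1][:, 1:], np.zeros((B.shape[0], 1))], axis=1
    )
    wins = (A * tail_B).sum(axis=1)
    ties = (A * B).sum(axis=1)
    p = (wins + ties / 2.0) / (n1[:, 0] * n2[:, 0])
    N = (n1 + n2)[:, 0]
    t = (A + B).astype(float)
    corr = 1.0 - (t**3 - t).sum(axis=1) / (N**3 - N)
    var0 = (N + 1.0) / (12.0 * n1[:, 0] * n2[:, 0]) * corr
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var0 > 0, (p - 0.5) / np.sqrt(var0), 0.0)
    return np.abs(z) > z_crit


def power_sim(scenario: DesignScenario) -> PowerResult:
    """Monte-Carlo power of the two-sided WMW test under the scenario.

    Deterministic given the scenario's seed; the Monte-Carlo CI is the
    Wilson interval for the rejection fraction.
    """
    rng = np.random.default_rng(scenario.seed)
    A = rng.multinomial(scenario.n_per_arm, scenario.probs_exp, size=scenario.n_sims)
    B = rng.multinomial(scenario.n_per_arm, scenario.probs_ctl, size=scenario.n_sims)
    rejected = _wmw_reject(A, B, scenario.alpha)
    k = int(rejected.sum())
    ci = binomtest(k, scenario.n_sims).proportion_ci(confidence_level=0.95, method="wilson")
    return PowerResult(
        power=k / scenario.n_sims,
        mc_ci=(float(ci.low), float(ci.high)),
        n_per_arm=scenario.n_per_arm,
        n_sims=scenario.n_sims,
        alpha=scenario.alpha,
        seed=scenario.seed,
        extras={"true_door_probability": true_door_probability(scenario.probs_exp,
                                                               scenario.probs_ctl)},
    )


class SampleSizeError(RuntimeError):
    """Target power unreachable within the allowed maximum sample size."""

    def __init__(self, message: str, best: PowerResult):
        super().__init__(message)
        self.best = best


def sample_size_search(
    probs_exp,
    probs_ctl,
    target_power: float = 0.90,
    alpha: float = 0.05,
    n_sims: int = 2000,
    seed: int = 0,
    n_min: int = 2,
    n_max: int = 20000,
) -> PowerResult:
    """Smallest per-arm n whose simulated power reaches ``target_power``.

    Uses common random numbers: one per-patient category stream of length
    ``n_max`` per arm per simulation, with size-n trials formed from the
    first n patients, so power is nondecreasing in n up to Monte-Carlo
    noise and bisection is justified.  Raises :class:`SampleSizeError`
    carrying the best result when the target is out of reach at ``n_max``.
    """
    p_true = true_door_probability(probs_exp, probs_ctl)
    if abs(p_true - 0.5) < 1e-12:
        raise ValueError("no effect: the true DOOR probability is 0.5; no n achieves power")
    if not 0 < target_power < 1:
        raise ValueError("target_power must be in (0,1)")
    rng = np.random.default_rng(seed)
    K = len(probs_exp)
    # per-patient categories as uint8 streams (K ≤ 255)
    cats_exp = rng.choice(K, size=(n_sims, n_max), p=np.asarray(probs_exp, float)).astype(np.uint8)
    cats_ctl = rng.choice(K, size=(n_sims, n_max), p=np.asarray(probs_ctl, float)).astype(np.uint8)

    def power_at(n: int) -> float:
        A = np.stack([(cats_exp[:, :n] == k).sum(axis=1) for k in range(K)], axis=1)
        B = np.stack([(cats_ctl[:, :n] == k).sum(axis=1) for k in range(K)], axis=1)
        return float(_wmw_reject(A, B, alpha).mean())

    def result(n: int, pw: float) -> PowerResult:
        k = int(round(pw * n_sims))
        ci = binomtest(k, n_sims).proportion_ci(confidence_level=0.95, method="wilson")
        return PowerResult(pw, (float(ci.low), float(ci.high)), n, n_sims, alpha, seed,
                           extras={"true_door_probability": p_true, "target_power": target_power})

    pw_lo = power_at(n_min)
    if pw_lo >= target_power:
        return result(n_min, pw_lo)
    pw_hi = power_at(n_max)
    if pw_hi < target_power:
        raise SampleSizeError(
            f"target power {target_power} unreachable at n_max={n_max} "
            f"(achieved {pw_hi:.3f})",
            result(n_max, pw_hi),
        )
    lo, hi = n_min, n_max  # power(lo) < target ≤ power(hi)
    pw_at_hi = pw_hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        pw = power_at(mid)
        if pw >= target_power:
            hi, pw_at_hi = mid, pw
        else:
            lo = mid
    return result(hi, pw_at_hi)
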