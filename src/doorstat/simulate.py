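"""Synthetic two-arm DOOR trial generator.

Emulates the structure of the packaged clinical example: an ordinal outcome
whose categories count cumulative deleterious events — category 1 = alive
with no events, category k = alive with k−1 events, category K = death —
with binary component flags drawn consistently with the category (a patient
"alive with 1 event" has exactly one non-fatal component flag set; death
sets the death flag).

An optional single binary baseline covariate (think severity score) shifts
both treatment assignment and the outcome by the same log-odds ``effect``,
producing the confounded nonrandomized setting that IPTW is meant to fix;
true propensity scores are recorded so weighting can be tested against an
analytically known marginal DOOR probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import DoorCategoryScheme, PatientDataset
from .power import true_door_probability

__all__ = [
    "GeneratorSpec",
    "generate",
    "confounded_scenario",
    "shifted_probs",
]

_DEFAULT_COMPONENTS = ("clinical_failure", "infectious_complication", "serious_ae")


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a synthetic two-arm DOOR trial.

    ``probs_exp``/``probs_ctl`` are the per-arm category distributions used
    when ``confounder_effect`` is 0.  With a nonzero confounder effect, a
    binary covariate (prevalence ``confounder_prevalence``) adds ``effect``
    to the log-odds of receiving the experimental arm and subtracts it from
    every cumulative log-odds of the outcome (sicker patients fare worse),
    and ``probs_exp``/``probs_ctl`` are interpreted as the covariate-free
    baseline distributions.
    """

    probs_exp: tuple[float, ...]
    probs_ctl: tuple[float, ...]
    n_exp: int
    n_ctl: int
    seed: int
    scheme: DoorCategoryScheme | None = None
    component_names: tuple[str, ...] = _DEFAULT_COMPONENTS
    component_choice_probs: tuple[float, ...] | None = None
    confounder_effect: float = 0.0
    confounder_prevalence: float = 0.5
    arms: tuple[str, str] = ("experimental", "control")

    def __post_init__(self) -> None:
        for name, p in (("probs_exp", self.probs_exp), ("probs_ctl", self.probs_ctl)):
            arr = np.asarray(p, dtype=float)
            if np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        K = len(self.probs_exp)
        if len(self.probs_ctl) != K:
            raise ValueError("arms must share the number of categories")
        if self.scheme is not None and self.scheme.K != K:
            raise ValueError("scheme size does not match probability vectors")
        # categories 2..K-1 hold 1..K-2 deleterious events; need enough components
        if len(self.component_names) < K - 2:
            raise ValueError(
                f"{K}-level outcome needs at least {K - 2} non-fatal components, "
                f"got {len(self.component_names)}"
            )
        if self.component_choice_probs is not None and (
            len(self.component_choice_probs) != len(self.component_names)
        ):
            raise ValueError("component_choice_probs must match component_names")
        if self.n_exp < 1 or self.n_ctl < 1:
            raise ValueError("arm sizes must be positive")
        if not 0 <= self.confounder_prevalence <= 1:
            raise ValueError("confounder prevalence must be in [0,1]")


def shifted_probs(base_probs, shift: float) -> np.ndarray:
    """Shift a category distribution on the cumulative log-odds scale.

    Positive ``shift`` moves mass toward the desirable end: every cumulative
    probability P(category ≤ k) is moved by ``shift`` on the logit scale
    (a proportional-odds shift).
    """
    base = np.asarray(base_probs, dtype=float)
    cum = np.clip(np.cumsum(base)[:-1], 1e-12, 1 - 1e-12)
    new_cum = expit(logit(cum) + shift)
    full = np.concatenate([[0.0], new_cum, [1.0]])
    return np.diff(full)


def _draw_components(
    rng: np.random.Generator,
    categories: np.ndarray,
    K: int,
    names: tuple[str, ...],
    choice_probs: tuple[float, ...] | None,
) -> pd.DataFrame:
    """Component flags consistent with each category's event count."""
    n = len(categories)
    m = len(names)
    probs = (
        np.asarray(choice_probs, float) / np.sum(choice_probs)
        if choice_probs is not None
        else np.full(m, 1.0 / m)
    )
    n_events = np.where(categories < K, categories - 1, 0)  # death: non-fatal flags stay 0
    # weighted sampling without replacement for all patients at once
    # (Gumbel top-k): patient i sets the flags of its n_events[i] top-scoring
    # components, score = log p + Gumbel noise
    with np.errstate(divide="ignore"):
        scores = np.log(probs)[None, :] + rng.gumbel(size=(n, m))
    order = np.argsort(-scores, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(m)[None, :].repeat(n, axis=0), axis=1)
    chosen = ranks < n_events[:, None]
    flags = {name: chosen[:, c].astype(np.int64) for c, name in enumerate(names)}
    flags["death"] = (categories == K).astype(np.int64)
    return pd.DataFrame(flags)


def generate(spec: GeneratorSpec) -> PatientDataset:
    """Draw a reproducible patient-level dataset from the spec.

    Unconfounded: per-arm multinomial categories with the given
    distributions.  Confounded (``confounder_effect`` ≠ 0): the covariate is
    drawn first, assignment follows the true propensity, the outcome
    distribution is covariate-shifted, and the true propensity score is
    stored in the ``propensity`` column.
    """
    rng = np.random.default_rng(spec.seed)
    K = len(spec.probs_exp)
    scheme = spec.scheme or _event_scheme(K)

    if spec.confounder_effect == 0.0:
        cats = np.concatenate(
            [
                rng.choice(K, size=spec.n_exp, p=np.asarray(spec.probs_exp, float)) + 1,
                rng.choice(K, size=spec.n_ctl, p=np.asarray(spec.probs_ctl, float)) + 1,
            ]
        )
        arm = np.array([spec.arms[0]] * spec.n_exp + [spec.arms[1]] * spec.n_ctl)
        z = rng.binomial(1, spec.confounder_prevalence, size=len(cats))
        propensity = np.full(len(cats), spec.n_exp / (spec.n_exp + spec.n_ctl))
    else:
        n = spec.n_exp + spec.n_ctl
        z = rng.binomial(1, spec.confounder_prevalence, size=n)
        e = expit(spec.confounder_effect * (z - 0.5))
        is_exp = rng.random(n) < e
        # ensure both arms are represented
        if is_exp.all():
            is_exp[rng.integers(n)] = False
        if not is_exp.any():
            is_exp[rng.integers(n)] = True
        arm = np.where(is_exp, spec.arms[0], spec.arms[1])
        propensity = e
        cats = np.empty(n, dtype=np.int64)
        for t, base in ((True, spec.probs_exp), (False, spec.probs_ctl)):
            for zz in (0, 1):
                mask = (is_exp == t) & (z == zz)
                if mask.any():
                    probs = shifted_probs(base, -spec.confounder_effect * zz)
                    cats[mask] = rng.choice(K, size=int(mask.sum()), p=probs) + 1

    df = pd.DataFrame(
        {
            "id": [f"s{i:06d}" for i in range(len(cats))],
            "arm": arm,
            "category": cats.astype(float),
            "confounder": z,
        }
    )
    comp = _draw_components(rng, cats, K, spec.component_names, spec.component_choice_probs)
    df = pd.concat([df, comp], axis=1)
    df["weight"] = 1.0
    df["propensity"] = propensity
    return PatientDataset(
        df, scheme, spec.arms, tuple(spec.component_names) + ("death",)
    )


def _event_scheme(K: int) -> DoorCategoryScheme:
    labels = ["Alive with no events"]
    labels += [f"Alive with {k} event{'s' if k > 1 else ''}" for k in range(1, K - 1)]
    labels.append("Death")
    return DoorCategoryScheme(tuple(labels))


# Baseline (covariate-free) category distributions of the packaged confounded
# scenario, patterned on the magnitude of the packaged clinical example, with
# a modest true benefit of 0.3 on the cumulative log-odds for the
# experimental arm.
_SCENARIO_CTL = (0.55, 0.30, 0.10, 0.03, 0.02)
_SCENARIO_TREATMENT_SHIFT = 0.3


def confounded_scenario(
    effect: float = 2.0,
    seed: int = 0,
    n_total: int = 1000,
    prevalence: float = 0.5,
) -> tuple[PatientDataset, float]:
    """The packaged confounded scenario and its analytic marginal truth.

    A binary severity covariate shifts treatment assignment toward the
    experimental arm and the outcome toward less desirable categories by the
    same log-odds ``effect``.  Returns the dataset (with true propensities)
    and the marginal DOOR probability — the contrast between the two
    counterfactual marginal category distributions, each a
    prevalence-weighted mixture over the covariate — which the IPTW-weighted
    estimator targets and the unweighted estimator misses.
    """
    probs_ctl = np.asarray(_SCENARIO_CTL, float)
    probs_exp = shifted_probs(probs_ctl, _SCENARIO_TREATMENT_SHIFT)
    spec = GeneratorSpec(
        probs_exp=tuple(probs_exp),
        probs_ctl=tuple(probs_ctl),
        n_exp=n_total // 2,
        n_ctl=n_total - n_total // 2,
        seed=seed,
        confounder_effect=effect,
        confounder_prevalence=prevalence,
    )
    data = generate(spec)
    marg_exp = (1 - prevalence) * shifted_probs(probs_exp, 0.0) + prevalence * shifted_probs(
        probs_exp, -effect
    )
    marg_ctl = (1 - prevalence) * shifted_probs(probs_ctl, 0.0) + prevalence * shifted_probs(
        probs_ctl, -effect
    )
    truth = true_door_probability(marg_exp, marg_ctl)
    return data, truth


def conditional_arm_mixture(effect: float, prevalence: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Asymptotic conditional-on-arm category distributions of the scenario.

    Used to compute the closed-form large-sample value of the *unweighted*
    estimator under confounding (its asymptotic bias relative to the
    marginal truth).
    """
    probs_ctl = np.asarray(_SCENARIO_CTL, float)
    probs_exp = shifted_probs(probs_ctl, _SCENARIO_TREATMENT_SHIFT)
    e1 = expit(effect * 0.5)     # P(exp | z=1)
    e0 = expit(-effect * 0.5)    # P(exp | z=0)
    p_exp = prevalence * e1 + (1 - prevalence) * e0
    w1_exp = prevalence * e1 / p_exp
    w1_ctl = prevalence * (1 - e1) / (1 - p_exp)
    mix_exp = (1 - w1_exp) * probs_exp + w1_exp * shifted_probs(probs_exp, -effect)
    mix_ctl = (1 - w1_ctl) * probs_ctl + w1_ctl * shifted_probs(probs_ctl, -effect)
    return mix_exp, mix_ctl
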