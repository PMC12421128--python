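"""Power analysis by simulation for the group term of a random-intercept LME.

Outcomes follow y = b0 + b_group*g + b_time*t + b_int*g*t + u_subject + e with
sum-coded group and visit (g, t in {-1, +1}), subject random intercepts
u ~ N(0, between_var) and residuals e ~ N(0, within_var).  The default
variance split is 0.1 / 0.9 so total variance is 1, making b_group a quarter
of the between-group mean difference averaged over visits.  Follow-up rows
are deleted with group-specific probability (0.25 for the reference/HC group;
0.32-0.64 is the realistic clinical range).  Each replicate fits
y ~ group*time + (1|subject) by REML and records the Wald p-value of the
group coefficient; power is the proportion of p-values below alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class PowerSimSpec:
    n_hc: int = 100
    n_clinical: int = 100
    between_var: float = 0.1
    within_var: float = 0.9
    missing_prob_hc: float = 0.25
    missing_prob_clinical: float = 0.48
    effect_beta: float = 0.0
    time_beta: float = 0.0
    interaction_beta: float = 0.0
    intercept: float = 0.0
    reps: int = 4000
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.between_var < 0 or self.within_var <= 0:
            raise ValueError("variances must be non-negative (within > 0)")
        for p in (self.missing_prob_hc, self.missing_prob_clinical):
            if not 0 <= p < 1:
                raise ValueError("missingness probabilities must be in [0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def simulate_lme_dataset(
    spec: PowerSimSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """One long-format replicate: columns subject, group, time, y.

    Baseline rows are complete; follow-up rows are deleted per the
    group-specific missingness probability.
    """
    n = spec.n_hc + spec.n_clinical
    group = np.repeat([-1.0, 1.0], [spec.n_hc, spec.n_clinical])
    b = rng.normal(0.0, np.sqrt(spec.between_var), n)
    miss_p = np.where(
        group < 0, spec.missing_prob_hc, spec.missing_prob_clinical
    )
    rows = []
    for i in range(n):
        for t in (-1.0, 1.0):
            if t > 0 and rng.random() < miss_p[i]:
                continue
            y = (
                spec.intercept
                + spec.effect_beta * group[i]
                + spec.time_beta * t
                + spec.interaction_beta * group[i] * t
                + b[i]
                + rng.normal(0.0, np.sqrt(spec.within_var))
            )
            rows.append((i, group[i], t, y))
    return pd.DataFrame(rows, columns=["subject", "group", "time", "y"])


def _group_term_pvalue(data: pd.DataFrame) -> float:
    """REML fit of y ~ group*time + (1|subject); Wald p for the group term."""
    exog = np.column_stack(
        [
            np.ones(len(data)),
            data["group"],
            data["time"],
            data["group"] * data["time"],
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(data["y"].to_numpy(), exog, groups=data["subject"])
        res = model.fit(reml=True)
    p = float(res.pvalues[1])
    if not np.isfinite(p):
        raise RuntimeError("non-finite p-value")
    return p


def estimate_power(
    spec: PowerSimSpec, seed: int = 0, reps: int | None = None
) -> dict:
    """Monte-Carlo power of the group term with a binomial 95% CI.

    Replicates whose REML fit fails are skipped and counted; a warning is
    raised if failures exceed 5%.
    """
    if reps is not None:
        spec = replace(spec, reps=reps)
    if spec.reps < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_ok = 0
    n_fail = 0
    for _ in range(spec.reps):
        data = simulate_lme_dataset(spec, rng)
        try:
            p = _group_term_pvalue(data)
        except Exception:  # noqa: BLE001 - counted fit failure
            n_fail += 1
            continue
        n_ok += 1
        n_sig += p < spec.alpha
    if n_fail > 0.05 * spec.reps:
        warnings.warn(f"{n_fail} of {spec.reps} LME fits failed")
    power = n_sig / n_ok if n_ok else np.nan
    se = np.sqrt(power * (1 - power) / n_ok) if n_ok else np.nan
    return {
        "power": power,
        "ci_low": max(0.0, power - 1.96 * se),
        "ci_high": min(1.0, power + 1.96 * se),
        "reps": spec.reps,
        "n_fitted": n_ok,
        "n_failures": n_fail,
        "alpha": spec.alpha,
    }


def power_curve(
    spec: PowerSimSpec, effect_betas, seed: int = 0, reps: int | None = None
) -> pd.DataFrame:
    """Power across a grid of group effect sizes."""
    rows = []
    for i, beta in enumerate(effect_betas):
        est = estimate_power(
            replace(spec, effect_beta=float(beta)), seed=seed + i, reps=reps
        )
        rows.append({"effect_beta": float(beta), **est})
    return pd.DataFrame(rows)
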