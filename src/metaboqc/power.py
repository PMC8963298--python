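"""Statistical power for planned downstream analyses.

Binary traits: two-sided two-sample t-test with unequal group sizes via
the noncentral t distribution. Continuous traits: F-test for a general
linear model via the noncentral F distribution. Power is evaluated at
effective sample sizes n_eff = n x (1 - q) for q over the observed
feature-missingness quantiles, illustrating the power cost of missing
data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "power_binary",
    "power_continuous",
    "power_grid_for_missingness",
    "PowerCurve",
    "D_GRID",
    "F2_GRID",
]

D_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))  # Cohen's d
F2_GRID = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2)  # Cohen's f^2
MISSINGNESS_QUANTILES = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class PowerCurve:
    kind: str  # "binary" | "continuous"
    effect_grid: tuple
    n_grid: tuple  # effective sample sizes
    quantiles: tuple  # missingness quantiles behind n_grid
    alpha: float
    power: np.ndarray  # |effect_grid| x |n_grid|

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.power,
            index=pd.Index(self.effect_grid, name="effect_size"),
            columns=[f"n={n}" for n in self.n_grid],
        )
        df.insert(0, "kind", self.kind)
        return df


def power_binary(n1: int, n2: int, effect_size_d: float, alpha: float = 0.05) -> float:
    """Power of a two-sided two-sample t-test (pooled variance).

    Noncentrality ncp = d * sqrt(n1 n2 / (n1 + n2)), df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    if effect_size_d < 0:
        raise ValueError("effect size d must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n1 + n2 - 2
    ncp = effect_size_d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)
    # the opposite-tail term underflows to NaN at large noncentrality
    if not np.isfinite(lower):
        lower = 0.0
    if not np.isfinite(upper):
        upper = 1.0 if ncp > tcrit else 0.0
    return float(upper + lower)


def power_continuous(
    n: int, effect_f2: float, alpha: float = 0.05, k_predictors: int = 1
) -> float:
    """Power of the F-test for a linear model with ``k_predictors``.

    Noncentrality ncp = f2 * n, df1 = k, df2 = n - k - 1.
    """
    if n <= k_predictors + 1:
        raise ValueError("n must exceed k_predictors + 1")
    if effect_f2 < 0:
        raise ValueError("effect size f2 must be >= 0")
    df1, df2 = k_predictors, n - k_predictors - 1
    fcrit = stats.f.ppf(1 - alpha, df1, df2)
    return float(1 - stats.ncf.cdf(fcrit, df1, df2, effect_f2 * n))


def power_grid_for_missingness(
    sample_n: int,
    missingness: pd.Series,
    alpha: float = 0.05,
) -> list[PowerCurve]:
    """Power curves at effective sample sizes implied by missingness.

    ``missingness`` is the observed per-feature missingness; effective
    n = sample_n x (1 - q) at each of its quantiles. Binary power
    splits the effective n into two equal groups.
    """
    q = tuple(float(x) for x in MISSINGNESS_QUANTILES)
    miss_q = np.asarray(missingness.dropna().quantile(list(q)))
    n_eff = tuple(int(max(np.floor(sample_n * (1 - m)), 6)) for m in miss_q)

    binary = np.array(
        [
            [power_binary(max(n // 2, 2), max(n - n // 2, 2), d, alpha) for n in n_eff]
            for d in D_GRID
        ]
    )
    continuous = np.array(
        [[power_continuous(n, f2, alpha) for n in n_eff] for f2 in F2_GRID]
    )
    return [
        PowerCurve("binary", D_GRID, n_eff, q, alpha, binary),
        PowerCurve("continuous", F2_GRID, n_eff, q, alpha, continuous),
    ]
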