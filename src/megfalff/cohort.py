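"""Synthetic cohort: trait scores and covariates.

Happiness is a 4-item global subjective-happiness composite on a 1–7 scale;
the generator draws it from a normal distribution truncated to the scale,
calibrated to the published sample (mean 4.6, SD 0.8). Age and full-scale IQ
match the published sample moments; sex is balanced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["make_cohort", "scale_span_fraction", "COHORT_COLUMNS"]

COHORT_COLUMNS = ["subject_id", "happiness", "sex", "age", "iq"]

HAPPINESS_MEAN, HAPPINESS_SD = 4.6, 0.8
HAPPINESS_RANGE = (1.0, 7.0)
AGE_MEAN, AGE_SD, AGE_MIN = 22.3, 4.4, 18.0
IQ_MEAN, IQ_SD = 121.7, 8.6


def _truncnorm(mean: float, sd: float, lo: float, hi: float, n: int,
               rng: np.random.Generator) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def scale_span_fraction(lo_obs: float, hi_obs: float,
                        scale: tuple[float, float] = HAPPINESS_RANGE) -> float:
    """Fraction of the rating scale spanned by an observed score range."""
    if not (scale[0] <= lo_obs <= hi_obs <= scale[1]):
        raise ValueError("observed range must lie within the scale")
    return (hi_obs - lo_obs) / (scale[1] - scale[0])


def make_cohort(n: int, seed: int) -> pd.DataFrame:
    """Generate ``n`` subjects with happiness, sex, age and IQ.

    Deterministic for a fixed seed. Sexes are balanced (coded 0/1) and, by
    default, all covariates are independent of each other and of happiness.
    """
    if n < 2:
        raise ValueError(f"need at least 2 subjects, got n={n}")
    rng = np.random.default_rng(seed)
    happiness = _truncnorm(HAPPINESS_MEAN, HAPPINESS_SD, *HAPPINESS_RANGE, n, rng)
    sex = np.tile([0, 1], (n + 1) // 2)[:n]
    rng.shuffle(sex)
    age = _truncnorm(AGE_MEAN, AGE_SD, AGE_MIN, np.inf, n, rng)
    iq = rng.normal(IQ_MEAN, IQ_SD, size=n)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "happiness": happiness,
            "sex": sex.astype(int),
            "age": age,
            "iq": iq,
        }
    )
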