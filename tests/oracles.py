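"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the exact
binomial CI comes from statsmodels, the permutation tail from full
multinomial enumeration, and the expectation moments from the
closed-form Poisson-binomial sums.
"""

from math import factorial

import numpy as np
from statsmodels.stats.proportion import proportion_confint


def clopper_pearson_oracle(alt: int, depth: int, level: float = 0.95):
    """Exact binomial CI via statsmodels' beta method."""
    lo, hi = proportion_confint(alt, depth, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the k=0 / k=n boundaries for one side
    if alt == 0:
        lo = 0.0
    if alt == depth:
        hi = 1.0
    return float(lo), float(hi)


def _compositions(total: int, parts: int):
    """All ordered compositions of `total` into `parts` non-negative ints."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


def exact_multinomial_tail(n_events: int, n_blastocysts: int,
                           observed_value: float, statistic: str) -> float:
    """P(statistic >= observed) for n_events thrown uniformly on
    n_blastocysts cells, by exact enumeration (feasible for small T, B)."""
    total_p = 0.0
    denom = n_blastocysts ** n_events
    fact_T = factorial(n_events)
    for counts in _compositions(n_events, n_blastocysts):
        if statistic == "max_per_blastocyst":
            stat = max(counts)
        elif statistic == "sd_across_blastocysts":
            stat = float(np.std(counts))
        else:
            raise ValueError(statistic)
        if stat >= observed_value - 1e-12:
            w = fact_T
            for c in counts:
                w //= factorial(c)
            total_p += w / denom
    return total_p


def poisson_binomial_moments(p, n_units_per_variant):
    """Exact mean/SD of the total transmission count under independence."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n_units_per_variant, dtype=float)
    mean = float((n * p).sum())
    sd = float(np.sqrt((n * p * (1 - p)).sum()))
    return mean, sd
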