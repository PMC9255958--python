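"""Permutation test for evenness of transmissions across blastocysts.

If mosaic variants transmit independently, the observed transmission
events should scatter uniformly across a donor's blastocysts. Variants
sharing a germ-cell lineage co-transmit, concentrating events in few
blastocysts. The test reassigns the observed number of events uniformly
at random to the blastocysts (10,000 permutations by default) and
compares either the maximum per-blastocyst count or the SD of
per-blastocyst counts against the observed value; the p-value is the
upper tail fraction (permuted >= observed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mpas_genotyper import TransmissionMatrix

__all__ = ["PermutationResult", "permute_evenness", "evenness_from_matrix"]

STATISTICS = ("max_per_blastocyst", "sd_across_blastocysts")


@dataclass
class PermutationResult:
    statistic: str
    observed_value: float
    permuted_values: np.ndarray = field(repr=False)
    p_value: float
    n_perm: int
    seed: int
    n_events: int
    n_blastocysts: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"statistic": self.statistic,
                "observed_value": self.observed_value,
                "p_value": self.p_value, "n_perm": self.n_perm,
                "seed": self.seed, "n_events": self.n_events,
                "n_blastocysts": self.n_blastocysts,
                "degenerate": self.degenerate}


def _stat(counts: np.ndarray, statistic: str) -> np.ndarray:
    """Per-row statistic over blastocyst count vectors.

    SD uses ddof=0; with the blastocyst number fixed the p-value is
    identical under either ddof convention (a common scale factor).
    """
    if statistic == "max_per_blastocyst":
        return counts.max(axis=-1)
    if statistic == "sd_across_blastocysts":
        return counts.std(axis=-1)
    raise ValueError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


def permute_evenness(
    per_blastocyst_counts,
    statistic: str = "max_per_blastocyst",
    n_perm: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> PermutationResult:
    """Tail-probability permutation test on observed per-blastocyst counts.

    Each permutation throws the T observed transmission events
    independently and uniformly onto the B blastocysts (equivalently, a
    single multinomial draw). ``plus_one`` applies the (k+1)/(n+1)
    small-sample correction; the default reproduces the plain tail
    fraction. T = 0 yields a degenerate result with p = 1.
    """
    observed = np.asarray(per_blastocyst_counts, dtype=int)
    n_b = observed.size
    if n_b < 2:
        raise ValueError("need at least 2 blastocysts")
    n_events = int(observed.sum())
    if n_events == 0:
        return PermutationResult(
            statistic=statistic, observed_value=0.0,
            permuted_values=np.zeros(0), p_value=1.0,
            n_perm=n_perm, seed=seed, n_events=0, n_blastocysts=n_b,
            degenerate=True)

    rng = np.random.default_rng(seed)
    perm_counts = rng.multinomial(n_events, np.full(n_b, 1.0 / n_b), size=n_perm)
    permuted = _stat(perm_counts, statistic).astype(float)
    obs_value = float(_stat(observed, statistic))
    # ties count toward the tail; tolerance guards against last-ulp
    # differences when a permutation reproduces the observed pattern
    k = int((permuted >= obs_value - 1e-9).sum())
    p = (k + 1) / (n_perm + 1) if plus_one else k / n_perm
    return PermutationResult(
        statistic=statistic, observed_value=obs_value,
        permuted_values=permuted, p_value=float(p),
        n_perm=int(n_perm), seed=int(seed),
        n_events=n_events, n_blastocysts=n_b)


def evenness_from_matrix(
    matrix: TransmissionMatrix,
    statistic: str = "max_per_blastocyst",
    n_perm: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> PermutationResult:
    """Run the evenness test on one donor's transmission matrix.

    Only QC-passing blastocysts appear as matrix columns, so B is the
    column count; the observed event vector is the per-column positive
    count.
    """
    counts = matrix.per_blastocyst_counts().to_numpy()
    return permute_evenness(counts, statistic=statistic, n_perm=n_perm,
                            seed=seed, plus_one=plus_one)
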