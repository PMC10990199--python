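"""Sampling completeness of haplotype discovery.

Observed haplotype richness is compared with a Chao1-family asymptotic
estimate built from singleton (f1) and doubleton (f2) haplotype
frequencies, with the (N-1)/N small-sample factor of the
rarefaction/extrapolation framework for abundance data (Hill number q = 0):

    S_est = S_obs + (N-1)/N * f1^2 / (2 f2)            if f2 > 0
    S_est = S_obs + (N-1)/N * f1 (f1 - 1) / 2          if f2 = 0

R = S_obs / S_est is the estimated fraction of haplotype diversity
retrieved and L = S_est - S_obs the number of haplotypes likely remaining.
Estimates are withheld for species with 10 or fewer specimens, where the
asymptote is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln


class InsufficientSamplingError(ValueError):
    """Raised when N <= min_n: the asymptotic estimate would be unreliable."""


@dataclass
class CompletenessResult:
    N: int
    S_obs: int
    f1: int
    f2: int
    S_est: float
    R: float
    L: float


def asymptotic_richness(haplotype_counts: list[int],
                        min_n: int = 10) -> CompletenessResult:
    """Chao1-type asymptotic haplotype richness with R and L derived."""
    counts = np.asarray(haplotype_counts, dtype=int)
    if np.any(counts < 1):
        raise ValueError("haplotype counts must be positive")
    N = int(counts.sum())
    if N <= min_n:
        raise InsufficientSamplingError(
            f"insufficient sampling: N={N} <= {min_n}")
    S_obs = len(counts)
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    factor = (N - 1) / N
    if f2 > 0:
        S_est = S_obs + factor * f1 * f1 / (2.0 * f2)
    else:
        S_est = S_obs + factor * f1 * (f1 - 1) / 2.0
    return CompletenessResult(N=N, S_obs=S_obs, f1=f1, f2=f2, S_est=S_est,
                              R=S_obs / S_est, L=S_est - S_obs)


def _log_comb(n: np.ndarray | int, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(n >= k, out, -np.inf)


def expected_richness(haplotype_counts: list[int], m: int) -> float:
    """Expected haplotype richness in a random subsample of size m.

    Interpolation (m <= N) uses the exact hypergeometric expectation
    E[S(m)] = S_obs - sum_i C(N - n_i, m) / C(N, m); extrapolation
    (N < m <= 2N) follows the Chao-type approach-to-asymptote curve
    S_obs + f0 * (1 - (1 - f1 / (N f0 + f1))^(m - N)).
    """
    counts = np.asarray(haplotype_counts, dtype=int)
    N = int(counts.sum())
    S_obs = len(counts)
    if m <= 0:
        raise ValueError("subsample size must be positive")
    if m <= N:
        log_p = _log_comb(N - counts, m) - _log_comb(N, m)
        return float(S_obs - np.sum(np.exp(log_p)))
    f1 = int(np.sum(counts == 1))
    f2 = int(np.sum(counts == 2))
    factor = (N - 1) / N
    f0 = factor * f1 * f1 / (2.0 * f2) if f2 > 0 else factor * f1 * (f1 - 1) / 2.0
    if f0 == 0 or f1 == 0:
        return float(S_obs)
    return float(S_obs + f0 * (1.0 - (1.0 - f1 / (N * f0 + f1)) ** (m - N)))


def rarefaction_curve(haplotype_counts: list[int],
                      sizes: list[int]) -> list[tuple[int, float]]:
    """Accumulation curve: (m, E[S(m)]) for each requested subsample size."""
    return [(int(m), expected_richness(haplotype_counts, int(m))) for m in sizes]
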