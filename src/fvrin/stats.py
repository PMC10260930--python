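"""Subsample-bootstrap comparison of a small group against a large one.

Feature values at deficiency-associated residues (a few dozen) are compared
with the remaining residues (over a thousand) with a procedure that is
insensitive to the group-size disparity: repeatedly draw, from the larger
group, as many elements as the smaller group holds, and record how often
the median of the draw exceeds the median of the small group.  The p-value
is that count divided by the number of iterations, so it is one-sided and
granular in units of 1/n_iter: p near 0 means the small group sits high,
p near 1 means it sits low, p near 0.5 means no separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BootstrapTestResult", "bootstrap_median_test"]

_CHUNK = 2000  # iterations per vectorized block, bounds memory


@dataclass(frozen=True)
class BootstrapTestResult:
    feature: str
    n_small: int
    n_large: int
    n_iter: int
    statistic: str
    median_small: float
    median_large_full: float
    p_value: float
    seed: int

    @property
    def p_two_sided(self) -> float:
        """Convenience two-sided version: 2 * min(p, 1 - p)."""
        return 2.0 * min(self.p_value, 1.0 - self.p_value)


def bootstrap_median_test(
    large,
    small,
    n_iter: int = 10_000,
    seed: int = 0,
    replace: bool = False,
    statistic: str = "median",
    feature: str = "",
) -> BootstrapTestResult:
    """One-sided subsample-bootstrap test of small-group elevation.

    Per iteration, ``len(small)`` elements are drawn from ``large``
    (without replacement by default — a subsample) and the chosen statistic
    of the draw is compared with the same statistic of ``small``.  The
    p-value is the fraction of iterations in which the draw's statistic is
    strictly greater.  Deterministic given ``seed``.
    """
    large = np.asarray(large, dtype=float).ravel()
    small = np.asarray(small, dtype=float).ravel()
    if small.size < 1:
        raise ValueError("small group must have at least 1 element")
    if large.size < small.size:
        raise ValueError("large group must be at least as big as the small group")
    if not replace and large.size < small.size:
        raise ValueError("cannot subsample without replacement: large group too small")
    if statistic not in ("median", "mean"):
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = np.median if statistic == "median" else np.mean

    rng = np.random.default_rng(seed)
    target = float(stat(small))
    k, n = small.size, large.size
    count = 0
    done = 0
    while done < n_iter:
        block = min(_CHUNK, n_iter - done)
        if replace:
            idx = rng.integers(0, n, size=(block, k))
        else:
            # k smallest of a random row = a uniform k-subset without replacement
            noise = rng.random((block, n))
            idx = np.argpartition(noise, k - 1, axis=1)[:, :k]
        resampled = stat(large[idx], axis=1)
        count += int(np.count_nonzero(resampled > target))
        done += block

    return BootstrapTestResult(
        feature=feature,
        n_small=k,
        n_large=n,
        n_iter=n_iter,
        statistic=statistic,
        median_small=target,
        median_large_full=float(stat(large)),
        p_value=count / n_iter,
        seed=seed,
    )
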