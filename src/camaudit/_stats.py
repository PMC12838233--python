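"""Resampling statistics used by the criterion aggregators."""

from __future__ import annotations

import numpy as np

#: bootstrap resamples for the 95% CI of summary means
N_BOOTSTRAP = 2000


def bootstrap_mean_ci(
    values, n_boot: int = N_BOOTSTRAP, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Mean with a percentile-bootstrap (1-alpha) confidence interval."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    if values.size < 2:
        return mean, mean, mean
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boots = values[idx].mean(axis=1)
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return mean, float(lo), float(hi)


def sign_flip_test(
    diffs, n_perm: int = 10000, seed: int = 0, alternative: str = "greater"
) -> float:
    """Paired sign-flip permutation test on the mean of differences.

    Under the null the paired differences are symmetric about zero, so their
    signs are exchangeable; the p-value is the fraction of sign-flipped
    resamples whose mean is at least as extreme as the observed one
    (including the identity flip, so p is never exactly zero).
    """
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValueError("need at least one paired difference")
    rng = np.random.default_rng(seed)
    obs = diffs.mean()
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    perm = (signs * diffs).mean(axis=1)
    if alternative == "greater":
        extreme = np.count_nonzero(perm >= obs)
    elif alternative == "less":
        extreme = np.count_nonzero(perm <= obs)
    elif alternative == "two-sided":
        extreme = np.count_nonzero(np.abs(perm) >= abs(obs))
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return float((extreme + 1) / (n_perm + 1))
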