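"""Permutation tests and the Holm-Bonferroni step-down correction.

Two resampling tests are used throughout the pipeline: a one-sided
two-sample permutation test on the difference of means (the per-participant
"above the noise floor" gate) and a one-sided paired sign-flip permutation
test on participant-mean differences (the adjacent-SNR comparisons).  Both
report add-one p-values, p = (1 + #{T_perm >= T_obs}) / (1 + n_perm), which
are valid finite-sample p-values.  Sign-flip tests enumerate all 2^n
patterns exactly when n <= 14.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "permutation_test_two_sample",
    "sign_flip_test",
    "holm_bonferroni",
]


def permutation_test_two_sample(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided two-sample permutation test of mean(a) > mean(b).

    Group labels are permuted; the statistic is the difference of group
    means.  Returns the add-one p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = a.size
    observed = a.mean() - b.mean()
    # vectorized label permutations: argsort of uniforms = random permutation
    u = rng.random((n_permutations, pooled.size))
    idx = np.argsort(u, axis=1)
    perm = pooled[idx]
    stat = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    count = int(np.sum(stat >= observed - 1e-12))
    return (1 + count) / (1 + n_permutations)


def sign_flip_test(
    diffs: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
    exact_max_n: int = 14,
) -> float:
    """One-sided paired sign-flip test of mean(diffs) > 0.

    Under the null the paired differences are symmetric about zero, so
    their signs are exchangeable.  All 2^n sign patterns are enumerated
    exactly when n <= ``exact_max_n``; otherwise ``n_permutations`` random
    patterns are drawn and the add-one p-value is returned.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    observed = diffs.mean()
    if n <= exact_max_n:
        signs = np.array(list(product([1.0, -1.0], repeat=n)))
        stat = signs @ diffs / n
        count = int(np.sum(stat >= observed - 1e-12))
        return count / len(signs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(n_permutations, n))
    stat = signs @ diffs / n
    count = int(np.sum(stat >= observed - 1e-12))
    return (1 + count) / (1 + n_permutations)


def holm_bonferroni(p_values, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Bonferroni decisions at family-wise level ``alpha``.

    Sort the m p-values ascending; reject the k-th smallest while
    p_(k) <= alpha / (m - k + 1), stopping at the first failure.  Returns
    a boolean rejection array in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for k, i in enumerate(order):
        if p[i] <= alpha / (m - k):
            reject[i] = True
        else:
            break
    return reject
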