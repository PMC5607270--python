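"""Statistical primitives shared across the ASE pipeline.

The workhorse is the exact two-sided binomial test of allelic balance
(null: each read carries either allele with probability 0.5).  Multiple
testing is handled with Benjamini-Hochberg, and evidence is pooled
across biological replicates with Fisher's combined probability test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "binom_test_two_sided",
    "bh_adjust",
    "fisher_combine",
]

# Relative tolerance when comparing outcome probabilities; mirrors the
# conventional minlike construction, where outcomes whose probability is
# "equal" to the observed one (up to float noise) are included in the tail.
_REL_TOL = 1e-7


def binom_test_two_sided(k, n):
    """Exact two-sided binomial p-value(s) for ``k`` successes in ``n`` trials
    under a null success probability of 0.5.

    The two-sided p-value is the sum of the probabilities of all outcomes
    whose probability does not exceed that of the observed outcome
    (minimum-likelihood method).  Vectorised over ``k`` and ``n``.

    Parameters
    ----------
    k, n : int or array-like
        Observed count(s) and total trial count(s); ``0 <= k <= n``,
        ``n >= 1``.

    Returns
    -------
    float or ndarray
    """
    k_arr = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n_arr = np.atleast_1d(np.asarray(n, dtype=np.int64))
    k_arr, n_arr = np.broadcast_arrays(k_arr, n_arr)
    if n_arr.size == 0:
        return np.empty(0, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("binomial test undefined for zero total count")
    if np.any((k_arr < 0) | (k_arr > n_arr)):
        raise ValueError("observed count outside [0, n]")

    out = np.empty(k_arr.shape, dtype=float)
    for nv in np.unique(n_arr):
        idx = np.nonzero(n_arr == nv)[0]
        pmf = sps.binom.pmf(np.arange(nv + 1), nv, 0.5)
        obs = pmf[k_arr.ravel()[idx]]
        include = pmf[None, :] <= obs[:, None] * (1.0 + _REL_TOL)
        out.ravel()[idx] = np.minimum((pmf[None, :] * include).sum(axis=1), 1.0)
    if np.isscalar(k) and np.isscalar(n):
        return float(out.ravel()[0])
    return out


def bh_adjust(pvalues):
    """Benjamini-Hochberg adjusted p-values (step-up FDR control).

    Returns an array the same length as the input; NaNs are not allowed.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-value passed to BH adjustment")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(pvalues, *, clamp=None):
    """Fisher's combined probability test.

    chi2 = -2 * sum(ln p_i), referred to a chi-square distribution with
    2k degrees of freedom.  Zero p-values are clamped to the smallest
    positive normal float (``clamp`` overrides).

    Returns
    -------
    (chi_square, dof, combined_p)
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    tiny = clamp if clamp is not None else np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0)
    chi2 = float(-2.0 * np.log(p).sum())
    dof = 2 * p.size
    return chi2, dof, float(sps.chi2.sf(chi2, dof))
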