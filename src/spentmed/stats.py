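"""Many-to-one significance testing shared by the depletion, growth and
untargeted stages.

The workhorse is Dunnett's test: several treatment groups compared against
one shared control with familywise error control.  For comparisons against
a common control the test statistics are equicorrelated in the product form
rho_ij = lambda_i * lambda_j with lambda_i = sqrt(n_i / (n_i + n_c)), which
lets the two-sided familywise p-value

    p_j = 1 - P( max_i |T_i| <= |t_j| )

be evaluated exactly as a two-dimensional quadrature: conditioning on the
standardized control mean z and on the pooled standard-deviation factor
u = s / sigma (with nu * u^2 ~ chi^2_nu), the comparisons decouple into a
product of normal probabilities.  This is deterministic and fast for
families of any size, unlike randomized quasi-Monte Carlo integration of
the multivariate t, and it is validated against ``scipy.stats.dunnett`` in
the test suite.

Degenerate families (zero variance in every group) fall back to an exact
equality rule: p = 1 when a treatment mean equals the control mean, p = 0
when it differs with literally no scatter.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats
from scipy.special import ndtr

_N_Z_NODES = 64
_N_U_NODES = 40

_Z_NODES, _Z_WEIGHTS = hermegauss(_N_Z_NODES)
_Z_WEIGHTS = _Z_WEIGHTS / np.sqrt(2.0 * np.pi)


@lru_cache(maxsize=256)
def _u_nodes(df: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for u = s/sigma, nu u^2 ~ chi2_nu."""
    chi = stats.chi(df, scale=1.0 / np.sqrt(df))
    lo, hi = chi.ppf(1e-12), chi.ppf(1.0 - 1e-12)
    x, w = np.polynomial.legendre.leggauss(_N_U_NODES)
    u = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    wu = 0.5 * (hi - lo) * w * chi.pdf(u)
    return u, wu


def _max_abs_t_cdf(t: np.ndarray, n_treat: np.ndarray, n_control: int,
                   df: int) -> np.ndarray:
    """P(max_i |T_i| <= t) under H0 for Dunnett statistics with group sizes
    ``n_treat`` against a control of size ``n_control``.

    For large batches of t-values the smooth, monotone CDF is evaluated on
    a dense grid once and cubic-spline interpolated.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.size > 384:
        from scipy.interpolate import CubicSpline

        t_hi = 40.0  # p < 1e-12 for any family size beyond this
        grid = np.linspace(0.0, t_hi, 384)
        cdf_grid = _max_abs_t_cdf(grid, n_treat, n_control, df)
        out = CubicSpline(grid, cdf_grid)(np.clip(t, 0.0, t_hi))
        out[t >= t_hi] = 1.0
        return np.clip(out, 0.0, 1.0)
    u, wu = _u_nodes(df)
    z = _Z_NODES
    # distinct treatment sizes factorize as powers
    sizes, counts = np.unique(n_treat, return_counts=True)
    # grids: (t, u, z)
    tu = t[:, None, None] * u[None, :, None]
    prod = np.ones_like(tu * np.ones((1, 1, z.size)))
    for n_i, c in zip(sizes, counts):
        a = np.sqrt(n_i / n_control) * z[None, None, :]
        b = tu * np.sqrt(1.0 + n_i / n_control)
        factor = ndtr(a + b) - ndtr(a - b)
        prod *= factor**c
    inner = prod @ _Z_WEIGHTS  # integrate over z -> (t, u)
    return np.clip(inner @ wu, 0.0, 1.0)


def dunnett_pvalues(
    treatments: list[np.ndarray],
    control: np.ndarray,
) -> np.ndarray:
    """Two-sided Dunnett p-values for each treatment group vs. the control.

    Parameters
    ----------
    treatments
        One replicate vector per treatment group (each length >= 2).
    control
        Replicate vector of the shared control group (length >= 2).

    Returns
    -------
    Familywise-adjusted p-values, one per treatment group, in input order.
    """
    control = np.asarray(control, dtype=float)
    treatments = [np.asarray(t, dtype=float) for t in treatments]
    return dunnett_pvalues_rows(
        [t[None, :] for t in treatments], control[None, :]
    )[0]


def dunnett_pvalues_rows(
    treatments: list[np.ndarray],
    control: np.ndarray,
) -> np.ndarray:
    """Row-wise Dunnett p-values when many features share one family design.

    Each treatment is a (features x replicates) matrix and ``control`` is
    the (features x replicates) control matrix; every row is an independent
    family with the same group sizes.  Returns (features x groups).
    """
    control = np.asarray(control, dtype=float)
    treatments = [np.asarray(t, dtype=float) for t in treatments]
    if control.shape[1] < 2 or any(t.shape[1] < 2 for t in treatments):
        raise ValueError("Dunnett test requires >=2 replicates per group")
    n_feat = control.shape[0]
    n_c = control.shape[1]
    n_t = np.array([t.shape[1] for t in treatments])
    n_total = n_c + int(n_t.sum())
    df = n_total - len(treatments) - 1

    scale = np.abs(control).max(axis=1)
    for t in treatments:
        scale = np.maximum(scale, np.abs(t).max(axis=1))
    scale = np.maximum(scale, 1e-300)

    pooled_ss = ((control - control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    for t in treatments:
        pooled_ss = pooled_ss + ((t - t.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    degenerate = pooled_ss <= (1e-11 * scale) ** 2 * n_total

    cmean = control.mean(axis=1)
    means = np.stack([t.mean(axis=1) for t in treatments], axis=1)
    p = np.empty((n_feat, len(treatments)))

    ok = ~degenerate
    if ok.any():
        s2 = pooled_ss[ok] / df
        se = np.sqrt(s2[:, None] * (1.0 / n_t + 1.0 / n_c)[None, :])
        t_obs = np.abs(means[ok] - cmean[ok, None]) / se
        p[ok] = 1.0 - _max_abs_t_cdf(t_obs.ravel(), n_t, n_c, df).reshape(t_obs.shape)
    if degenerate.any():
        eq = np.abs(means[degenerate] - cmean[degenerate, None]) <= (
            1e-9 * scale[degenerate, None]
        )
        p[degenerate] = np.where(eq, 1.0, 0.0)
    return p


def welch_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value, with the same zero-variance fallback."""
    return float(welch_pvalues_rows(np.atleast_2d(a), np.atleast_2d(b))[0])


def welch_pvalues_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch p-values for two replicate matrices.

    ``a`` and ``b`` are (rows x replicates); each row is one independent
    comparison.  Rows where both groups are constant to rounding get the
    exact-equality fallback (1 if means agree, 0 otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("Welch test requires >=2 replicates per group")
    scale = np.maximum(
        np.maximum(np.abs(a).max(axis=1), np.abs(b).max(axis=1)), 1e-300
    )
    degenerate = (np.ptp(a, axis=1) <= 1e-11 * scale) & (
        np.ptp(b, axis=1) <= 1e-11 * scale
    )
    p = np.ones(a.shape[0])
    if (~degenerate).any():
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                a[~degenerate], b[~degenerate], axis=1, equal_var=False
            )
        p[~degenerate] = np.nan_to_num(res.pvalue, nan=1.0)
    if degenerate.any():
        equal = (
            np.abs(a.mean(axis=1) - b.mean(axis=1)) <= 1e-9 * scale
        )
        p[degenerate] = np.where(equal[degenerate], 1.0, 0.0)
    return p
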