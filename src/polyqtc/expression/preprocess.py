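"""Background correction, normalization and probe summarization.

The chain follows standard two-channel practice: normexp background
correction per channel per array with an offset of 20 (which shrinks the
log-ratios of weak probes towards zero), M/A computation, within-array loess
normalization of M on A to remove intensity-dependent dye bias, and Tukey
median polish over each gene's probes x arrays block to obtain one log-ratio
value per gene per array.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "NormexpParams",
    "normexp_fit",
    "normexp_correct",
    "compute_MA",
    "loess_normalize",
    "median_polish",
    "medianpolish_summarize",
    "preprocess_arrays",
]

DEFAULT_OFFSET = 20.0
DEFAULT_SPAN = 0.3


@dataclass(frozen=True)
class NormexpParams:
    """Parameters of the normal + exponential convolution model.

    Observed intensity X = B + S with background B ~ N(mu, sigma^2) and
    signal S ~ Exp(mean alpha).
    """

    mu: float
    sigma: float
    alpha: float


def _normexp_nll(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    z = (x - mu - sigma**2 / alpha) / sigma
    ll = -log_alpha + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + special.log_ndtr(z)
    return -float(ll.sum())


def _normexp_nll_grad(theta: np.ndarray, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient in (mu, log sigma, log alpha)."""
    mu, log_sigma, log_alpha = theta
    sigma = np.exp(log_sigma)
    alpha = np.exp(log_alpha)
    with np.errstate(all="ignore"):
        z = (x - mu) / sigma - sigma / alpha
        ll = -log_alpha + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + special.log_ndtr(z)
        # hazard ratio phi(z)/Phi(z), stable at both tails
        r = math.sqrt(2.0 / math.pi) / special.erfcx(-z / math.sqrt(2.0))
        d_mu = 1.0 / alpha - r / sigma
        d_sigma = sigma / alpha**2 + r * (-(x - mu) / sigma**2 - 1.0 / alpha)
        d_alpha = -1.0 / alpha - (mu - x) / alpha**2 - sigma**2 / alpha**3 + r * sigma / alpha**2
        grad = -np.array([d_mu.sum(), sigma * d_sigma.sum(), alpha * d_alpha.sum()])
    return -float(ll.sum()), grad


def _normexp_moment_init(x: np.ndarray) -> np.ndarray:
    """Method-of-moments start: mean = mu + alpha, var = sigma^2 + alpha^2,
    third central moment = 2 alpha^3."""
    m1 = float(x.mean())
    v = float(x.var())
    m3 = float(((x - m1) ** 3).mean())
    alpha0 = max((max(m3, 1e-12) / 2.0) ** (1.0 / 3.0), 1e-2)
    sigma0 = math.sqrt(max(v - alpha0**2, 1e-4))
    mu0 = m1 - alpha0
    return np.array([mu0, np.log(sigma0), np.log(alpha0)])


def _normexp_quantile_init(x: np.ndarray) -> np.ndarray:
    q05, q25 = np.quantile(x, [0.05, 0.25])
    low = x[x <= q25]
    sigma0 = max(float(low.std()), 1e-2)
    alpha0 = max(float(x.mean() - q05), 1e-2)
    return np.array([q05, np.log(sigma0), np.log(alpha0)])


def normexp_fit(x: np.ndarray) -> NormexpParams:
    """Maximum-likelihood fit of the normexp convolution to intensities.

    Starts Nelder-Mead from a method-of-moments and a quantile-based
    initialization and keeps the solution with the better likelihood.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 intensities to fit normexp")
    best = None
    for theta0 in (_normexp_moment_init(x), _normexp_quantile_init(x)):
        res = optimize.minimize(
            _normexp_nll_grad, theta0, args=(x,), method="L-BFGS-B", jac=True
        )
        if not np.isfinite(res.fun):
            res = optimize.minimize(
                _normexp_nll, theta0, args=(x,), method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 1000},
            )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma, log_alpha = best.x
    return NormexpParams(
        mu=float(mu), sigma=float(np.exp(log_sigma)), alpha=float(np.exp(log_alpha))
    )


def _normexp_signal_mean(x: np.ndarray, p: NormexpParams) -> np.ndarray:
    """E[signal | observed] under the fitted convolution.

    Uses phi(z)/Phi(z) = sqrt(2/pi) / erfcx(-z/sqrt(2)), which stays finite
    for arbitrarily extreme z (including the sigma -> 0 noiseless limit,
    where the correction degenerates to x - mu).
    """
    mu_sf = x - p.mu - p.sigma**2 / p.alpha
    z = mu_sf / max(p.sigma, 1e-300)
    ratio = math.sqrt(2.0 / math.pi) / special.erfcx(-z / math.sqrt(2.0))
    return mu_sf + p.sigma * ratio


def normexp_correct(
    x: np.ndarray, offset: float = DEFAULT_OFFSET, params: NormexpParams | None = None
) -> np.ndarray:
    """Background-correct intensities with the normexp model plus an offset.

    Falls back to subtracting the minimum when the fit degenerates (zero
    background variance or non-finite parameters); output is strictly > 0
    for offset > 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensities must be >= 0")
    if params is None and x.std() > 0:
        try:
            params = normexp_fit(x)
        except Exception:
            params = None
    if params is None or not np.isfinite([params.mu, params.sigma, params.alpha]).all():
        # degenerate fit (e.g. zero-variance input): subtract the minimum
        warnings.warn("degenerate normexp fit; subtracting the minimum instead", stacklevel=2)
        corrected = x - x.min()
    else:
        # sigma -> 0 is the valid noiseless limit (corrected ~ x - mu)
        corrected = _normexp_signal_mean(x, params)
    return np.maximum(corrected, 0.0) + offset


def compute_MA(test: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """M = log2(test/reference), A = mean log2 intensity of the two channels."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(test <= 0) or np.any(reference <= 0):
        raise ValueError("channel intensities must be > 0 (background-correct first)")
    m = np.log2(test / reference)
    a = 0.5 * np.log2(test * reference)
    return m, a


def loess_normalize(
    m: np.ndarray, a: np.ndarray, span: float = DEFAULT_SPAN, iterations: int = 3
) -> np.ndarray:
    """Within-array loess normalization: M' = M - loess(M ~ A).

    Locally weighted linear regression of M on A with robustifying
    iterations; requires enough probes for the window (span * n >= 4).
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if m.shape != a.shape:
        raise ValueError("M and A must have the same shape")
    n = m.size
    if span * n < 4:
        raise ValueError(f"span {span} too small for {n} probes")
    spread = float(a.max() - a.min())
    fitted = lowess(
        m, a, frac=span, it=iterations, delta=0.005 * spread, return_sorted=False
    )
    return m - fitted


def median_polish(
    mat: np.ndarray, tol: float = 1e-6, max_iter: int = 10
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D block (rows x columns).

    Alternates removal of row and column medians until the change in the
    absolute residual sum falls below ``tol`` (or ``max_iter`` sweeps).
    Returns (overall, row_effects, col_effects, residuals); NaNs are ignored.
    """
    z = np.array(mat, dtype=float)
    if z.ndim != 2:
        raise ValueError("median polish expects a 2-D block")
    nr, nc = z.shape
    # nanmedian is markedly slower than median; skip it for complete blocks
    med = np.nanmedian if np.isnan(z).any() else np.median
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    for _ in range(max_iter):
        rmed = med(z, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        z -= rmed[:, None]
        row += rmed
        cmed_of_row = med(row)
        overall += cmed_of_row
        row -= cmed_of_row

        cmed = med(z, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        z -= cmed[None, :]
        col += cmed
        rmed_of_col = med(col)
        overall += rmed_of_col
        col -= rmed_of_col

        # converged once row and column medians of the residuals vanish
        rres = np.max(np.abs(np.nan_to_num(med(z, axis=1))))
        cres = np.max(np.abs(np.nan_to_num(med(z, axis=0))))
        if max(rres, cres) <= tol:
            break
    return overall, row, col, z


def medianpolish_summarize(block: pd.DataFrame) -> pd.Series:
    """Summarize one gene's probes x arrays block to one value per array.

    The gene value per array is the overall effect plus the column (array)
    effect of the median polish fit.
    """
    if block.shape[0] == 0 or block.isna().all().all():
        raise ValueError("cannot summarize an all-missing probe block")
    if block.shape[0] == 1:
        return block.iloc[0]
    overall, _, col, _ = median_polish(block.to_numpy())
    return pd.Series(overall + col, index=block.columns)


def preprocess_arrays(
    long: pd.DataFrame,
    offset: float = DEFAULT_OFFSET,
    span: float = DEFAULT_SPAN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pre-processing chain on a probe-level long table.

    Expects columns ``probe_id, gene_id, array_id, slide_id, cellline,
    time_h, replicate, cy3, cy5``.  Returns ``(expr, meta)`` where ``expr``
    is the gene x array matrix of summarized, normalized log2 ratios and
    ``meta`` the per-array metadata (indexed by array_id, in expr's column
    order).
    """
    required = {"probe_id", "gene_id", "array_id", "slide_id", "cellline", "time_h", "cy3", "cy5"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    meta = (
        long[["array_id", "slide_id", "cellline", "time_h", "replicate"]]
        .drop_duplicates("array_id")
        .set_index("array_id")
        .sort_index()
    )
    cy3 = long.pivot(index="probe_id", columns="array_id", values="cy3")
    cy5 = long.pivot(index="probe_id", columns="array_id", values="cy5")
    probe_gene = long[["probe_id", "gene_id"]].drop_duplicates().set_index("probe_id")["gene_id"]

    m_cols = {}
    for array_id in cy3.columns:
        t = normexp_correct(cy3[array_id].to_numpy(), offset=offset)
        r = normexp_correct(cy5[array_id].to_numpy(), offset=offset)
        m, a = compute_MA(t, r)
        m_cols[array_id] = loess_normalize(m, a, span=span)
    m_mat = pd.DataFrame(m_cols, index=cy3.index)

    genes_of = probe_gene.reindex(m_mat.index)
    rows = {}
    for gene, block in m_mat.groupby(genes_of.to_numpy(), sort=True):
        rows[gene] = medianpolish_summarize(block)
    expr = pd.DataFrame(rows).T
    expr = expr[meta.index]  # align column order with metadata
    expr.index.name = "gene_id"
    return expr, meta
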