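"""Gene-wise linear models, contrasts and empirical-Bayes moderation.

Each gene's summarized log-ratios are modelled by ordinary least squares with
a condition factor (all cell-line x time combinations, reference level C_0)
and a slide factor.  Contrasts of interest are, per time point t:

- within-line changes  C_t - C_0  and  HD_t - HD_0;
- the disease-specific double difference  (HD_t - HD_0) - (C_t - C_0),
  which cancels responses shared by both lines (doxycycline exposure,
  culture time) and baseline differences between the lines.

Gene-wise residual variances are shrunk towards a common prior estimated by
method of moments on log s^2 (an F-distribution fit); moderated t statistics
use df + d0 degrees of freedom, and an overall moderated F across the eight
post-induction double-difference contrasts flags genes that respond
disease-specifically at any time.  P-values are Benjamini-Hochberg adjusted
within each contrast family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DesignInfo",
    "LinearFit",
    "ContrastResult",
    "build_design",
    "build_contrasts",
    "fit_models",
    "squeeze_var",
    "trigamma_inverse",
    "moderate_and_test",
]

_D0_CAP = 1e10  # numerical stand-in for an infinite prior df (no-moderation limit)


@dataclass
class DesignInfo:
    """Design matrix with named columns for condition and slide factors."""

    matrix: np.ndarray  # arrays x p
    colnames: list[str]
    array_ids: list[str]
    condition: pd.Series  # per-array condition label, e.g. "HD_24"
    slide: pd.Series
    reference: str = "C_0"
    dropped_slide_cols: list[str] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))

    def col_index(self, name: str) -> int:
        return self.colnames.index(name)


def _condition_label(cellline: str, time_h: float) -> str:
    return f"{cellline}_{time_h:g}"


def build_design(meta: pd.DataFrame, reference: str = "C_0") -> DesignInfo:
    """Build the condition + slide design from per-array metadata.

    ``meta`` is indexed by array_id with columns cellline, time_h, slide_id.
    Condition uses reference coding with ``reference`` (the control line's
    pre-induction state) as baseline; slide uses the first slide as baseline.
    Slide columns aliased with the condition block are dropped with a warning.
    """
    condition = pd.Series(
        [_condition_label(r.cellline, r.time_h) for r in meta.itertuples()],
        index=meta.index,
        name="condition",
    )
    if reference not in set(condition):
        raise ValueError(f"reference condition {reference!r} absent from the design")
    cond_levels = sorted(set(condition) - {reference})
    slide = meta["slide_id"].astype(str)
    slide_levels = sorted(set(slide))[1:]  # first level is baseline

    n = len(meta)
    cols = [np.ones(n)]
    names = ["intercept"]
    for lev in cond_levels:
        cols.append((condition == lev).to_numpy(dtype=float))
        names.append(f"cond_{lev}")
    base_rank = np.linalg.matrix_rank(np.column_stack(cols))
    dropped = []
    for lev in slide_levels:
        cand = (slide == lev).to_numpy(dtype=float)
        trial = np.column_stack(cols + [cand])
        r = np.linalg.matrix_rank(trial)
        if r > base_rank:
            cols.append(cand)
            names.append(f"slide_{lev}")
            base_rank = r
        else:
            dropped.append(f"slide_{lev}")
    if dropped:
        warnings.warn(f"dropping aliased slide columns: {dropped}", stacklevel=2)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignInfo(
        matrix=x,
        colnames=names,
        array_ids=list(meta.index),
        condition=condition,
        slide=slide,
        reference=reference,
        dropped_slide_cols=dropped,
    )


@dataclass
class LinearFit:
    """Per-gene OLS results on a shared design."""

    coef: pd.DataFrame  # genes x coefficients
    sigma2: pd.Series  # residual variances
    df_resid: int
    xtx_inv: np.ndarray
    design: DesignInfo


def fit_models(expr: pd.DataFrame, design: DesignInfo) -> LinearFit:
    """Ordinary least squares for every gene on the shared design matrix."""
    if list(expr.columns) != design.array_ids:
        expr = expr[design.array_ids]
    x = design.matrix
    n, p = x.shape
    if np.linalg.matrix_rank(x) < p:
        raise ValueError("design matrix is rank deficient")
    y = expr.to_numpy().T  # arrays x genes
    coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = n - p
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    return LinearFit(
        coef=pd.DataFrame(coef.T, index=expr.index, columns=design.colnames),
        sigma2=pd.Series(sigma2, index=expr.index, name="s2"),
        df_resid=df,
        xtx_inv=xtx_inv,
        design=design,
    )


def _unit(design: DesignInfo, name: str) -> np.ndarray:
    v = np.zeros(len(design.colnames))
    v[design.col_index(name)] = 1.0
    return v


def build_contrasts(design: DesignInfo) -> dict[str, pd.DataFrame]:
    """Contrast matrices for the three families, one column per time point.

    Families: "C" (C_t - C_0), "HD" (HD_t - HD_0) and "DD", the
    disease-specific double difference (HD_t - HD_0) - (C_t - C_0).
    With C_0 as the reference level, C_t - C_0 is the cond_C_t coefficient
    and HD_t - HD_0 is cond_HD_t - cond_HD_0.
    """
    times = sorted(
        {
            float(lbl.split("_", 1)[1])
            for lbl in set(design.condition)
        }
        - {0.0}
    )
    p = len(design.colnames)
    fams: dict[str, pd.DataFrame] = {}
    for fam in ("C", "HD", "DD"):
        mat = np.zeros((p, len(times)))
        for j, t in enumerate(times):
            c_t = _unit(design, f"cond_{_condition_label('C', t)}")
            hd_t = _unit(design, f"cond_{_condition_label('HD', t)}")
            hd_0 = _unit(design, f"cond_{_condition_label('HD', 0.0)}")
            if fam == "C":
                mat[:, j] = c_t
            elif fam == "HD":
                mat[:, j] = hd_t - hd_0
            else:
                mat[:, j] = (hd_t - hd_0) - c_t
        fams[fam] = pd.DataFrame(mat, index=design.colnames, columns=times)
    return fams


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (monotone decreasing)."""
    if y <= 0:
        return np.inf
    f = lambda x: float(special.polygamma(1, x)) - y
    lo, hi = 1e-8, 1e8
    if f(lo) < 0:  # y above trigamma(1e-8): effectively x -> 0
        return lo
    if f(hi) > 0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def squeeze_var(sigma2: np.ndarray, df: int) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes shrinkage of gene-wise variances.

    Fits a scaled F prior to the s^2 by method of moments on log s^2:
    solving trigamma(d0/2) = var(e) - trigamma(df/2) with
    e = log s^2 - digamma(df/2) + log(df/2) gives the prior df d0, and the
    prior variance follows from the mean of e.  Returns
    ``(d0, s0^2, posterior s~^2)`` with
    s~^2 = (d0 s0^2 + df s^2) / (d0 + df).  d0 = inf (all variances alike)
    degenerates to no moderation.
    """
    s2 = np.asarray(sigma2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("variances must be >= 0")
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(s2.mean()), np.full_like(s2, s2.mean())
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    emean = float(np.mean(e))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    d0_eff = min(d0, _D0_CAP)
    post = (d0_eff * s02 + df * s2) / (d0_eff + df)
    return d0, s02, post


@dataclass
class ContrastResult:
    """Moderated contrast statistics for all families.

    ``per_timepoint`` holds a tidy table per family ("C", "HD", "DD") with
    columns gene_id, time_h, logFC, t, p, adj_p (BH within each contrast);
    ``overall`` holds the moderated F across the double-difference contrasts
    with columns gene_id, F, p, adj_p (BH within the F family).
    """

    per_timepoint: dict[str, pd.DataFrame]
    overall: pd.DataFrame
    d0: float
    s02: float
    df_resid: int
    s2: pd.Series
    s2_post: pd.Series

    def table(self, family: str, time_h: float) -> pd.DataFrame:
        tab = self.per_timepoint[family]
        return tab[tab["time_h"] == float(time_h)].set_index("gene_id")


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def moderated_t_single(
    fit: LinearFit, contrast: np.ndarray, d0: float, s2_post: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t for one contrast vector; returns (logFC, t, p)."""
    c = np.asarray(contrast, dtype=float)
    logfc = fit.coef.to_numpy() @ c
    var_factor = float(c @ fit.xtx_inv @ c)
    df_total = fit.df_resid + min(d0, _D0_CAP)
    if var_factor <= 0:
        # zero contrast (e.g. a t - t self-contrast): no effect, no evidence
        if not np.allclose(c, 0):
            raise ValueError("contrast is not estimable")
        t = np.zeros_like(logfc)
        return logfc, t, np.ones_like(logfc)
    se = np.sqrt(var_factor * s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return logfc, t, p


def moderate_and_test(
    fit: LinearFit, contrasts: dict[str, pd.DataFrame] | None = None
) -> ContrastResult:
    """Empirical-Bayes moderated t/F statistics with BH adjustment.

    The overall moderated F per gene is computed across the columns of the
    "DD" family: F = b' V^{-1} b / (r s~^2) with b the contrast estimates,
    V = C' (X'X)^{-1} C and r the number of contrasts, on (r, df + d0)
    degrees of freedom.
    """
    contrasts = contrasts or build_contrasts(fit.design)
    d0, s02, s2_post = squeeze_var(fit.sigma2.to_numpy(), fit.df_resid)
    s2_post_s = pd.Series(s2_post, index=fit.sigma2.index, name="s2_post")
    genes = fit.coef.index
    df_total = fit.df_resid + min(d0, _D0_CAP)

    per_tp: dict[str, pd.DataFrame] = {}
    for fam, cmat in contrasts.items():
        frames = []
        for t_h in cmat.columns:
            logfc, tstat, p = moderated_t_single(fit, cmat[t_h].to_numpy(), d0, s2_post)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "time_h": float(t_h),
                        "logFC": logfc,
                        "t": tstat,
                        "p": p,
                        "adj_p": _bh(p),
                    }
                )
            )
        per_tp[fam] = pd.concat(frames, ignore_index=True)

    cdd = contrasts["DD"].to_numpy()
    r = cdd.shape[1]
    v = cdd.T @ fit.xtx_inv @ cdd
    v_inv = np.linalg.inv(v)
    b = fit.coef.to_numpy() @ cdd  # genes x r
    quad = np.einsum("gi,ij,gj->g", b, v_inv, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = np.where(s2_post > 0, quad / (r * s2_post), 0.0)
    pf = stats.f.sf(fstat, r, df_total)
    overall = pd.DataFrame(
        {"gene_id": genes, "F": fstat, "p": pf, "adj_p": _bh(pf)}
    )
    return ContrastResult(
        per_timepoint=per_tp,
        overall=overall,
        d0=d0,
        s02=s02,
        df_resid=fit.df_resid,
        s2=fit.sigma2,
        s2_post=s2_post_s,
    )
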