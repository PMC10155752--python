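"""Dual-analyte differential expression.

Two inference routes over log2 SNR:

* :func:`ttest_de` — per-target two-sided Welch (unequal-variance) t-test
  between two groups of AOIs, Benjamini-Hochberg adjusted within analyte;
* :func:`mixed_model_de` — per-target linear mixed model
  ``log2 SNR ~ intercept + segment`` with a per-tissue random intercept
  (REML), for designs where several ROI/AOI segments are sampled from each
  tissue; the segment-contrast p-value uses a t statistic with
  Satterthwaite-approximated degrees of freedom (a normal-approximation
  z-test is available as a fallback flag).

Fold changes are additive on the log2 scale: the t-test reports the
difference of group means of log2 SNR, the mixed model the segment
fixed-effect coefficient, so the two are directly comparable.

Significance tiers follow the three-level convention: p05 (raw P < 0.05),
fdr05 (FDR < 0.05), fdr001 (FDR < 0.001), else ns.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .normalize import SnrMatrix

logger = logging.getLogger(__name__)

DE_COLUMNS = [
    "target_id",
    "analyte",
    "log2fc",
    "p",
    "fdr",
    "tier",
    "method",
    "n1",
    "n2",
    "re_var",
    "resid_var",
    "flag",
]


def assign_tier(p: float, fdr: float) -> str:
    """Tier from (raw p, BH-adjusted p): fdr001 < fdr05 < p05 < ns."""
    if np.isnan(p) or np.isnan(fdr):
        return "ns"
    if fdr < 0.001:
        return "fdr001"
    if fdr < 0.05:
        return "fdr05"
    if p < 0.05:
        return "p05"
    return "ns"


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if ok.any():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    return out


def _finalize(rows: list[dict], per_analyte_bh: bool = True) -> pd.DataFrame:
    de = pd.DataFrame(rows)
    if de.empty:
        return pd.DataFrame(columns=DE_COLUMNS)
    if per_analyte_bh:
        de["fdr"] = np.nan
        for analyte, idx in de.groupby("analyte").groups.items():
            de.loc[idx, "fdr"] = bh_adjust(de.loc[idx, "p"].to_numpy())
    else:
        de["fdr"] = bh_adjust(de["p"].to_numpy())
    de["tier"] = [assign_tier(p, q) for p, q in zip(de["p"], de["fdr"])]
    return de.reindex(columns=DE_COLUMNS)  # t-test rows carry no variance components


# ---------------------------------------------------------------------------
# Welch t-test route
# ---------------------------------------------------------------------------


def ttest_de(
    snr: SnrMatrix,
    groups: Mapping[str, int],
    per_analyte_bh: bool = True,
) -> pd.DataFrame:
    """Per-target Welch t-test on log2 SNR between groups 1 and 2.

    ``groups`` maps aoi_id -> {1, 2}. log2fc is mean(group1) - mean(group2)
    of log2 SNR. BH adjustment is applied within each analyte by default
    (set ``per_analyte_bh=False`` for pooled adjustment). Targets where both
    groups have zero variance get p = 1 (equal means) or p = 0, flagged
    "degenerate".
    """
    g1 = [a for a in snr.values.columns if groups.get(a) == 1]
    g2 = [a for a in snr.values.columns if groups.get(a) == 2]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 AOIs")
    x1 = np.log2(snr.values[g1].to_numpy())
    x2 = np.log2(snr.values[g2].to_numpy())

    rows = []
    for i, tid in enumerate(snr.values.index):
        a, b = x1[i], x2[i]
        flag = ""
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
            flag = "degenerate"
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        rows.append(
            {
                "target_id": tid,
                "analyte": snr.targets.loc[tid, "analyte"],
                "log2fc": float(a.mean() - b.mean()),
                "p": p,
                "method": "ttest",
                "n1": len(g1),
                "n2": len(g2),
                "flag": flag,
            }
        )
    return _finalize(rows, per_analyte_bh)


# ---------------------------------------------------------------------------
# Linear mixed model route
# ---------------------------------------------------------------------------


def _reml_neg2(theta: np.ndarray, y, X, group_idx, n_groups) -> float:
    """-2 x restricted log-likelihood of a random-intercept model.

    theta = (sigma2_g, sigma2_e); V = sigma2_e I + sigma2_g Z Z' is block
    diagonal by group, so everything factors per group.
    """
    s2g, s2e = theta
    if s2e <= 0:
        return np.inf
    s2g = max(s2g, 0.0)  # boundary of the feasible region, still a valid model
    p = X.shape[1]
    logdet_v = 0.0
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    for g in range(n_groups):
        m = group_idx == g
        ng = int(m.sum())
        Xg, yg = X[m], y[m]
        # V_g^-1 = (I - c J)/s2e with c = s2g / (s2e + ng*s2g)
        c = s2g / (s2e + ng * s2g)
        logdet_v += (ng - 1) * np.log(s2e) + np.log(s2e + ng * s2g)
        xs, ys_ = Xg.sum(axis=0), yg.sum()
        xtvx += (Xg.T @ Xg - c * np.outer(xs, xs)) / s2e
        xtvy += (Xg.T @ yg - c * xs * ys_) / s2e
        ytvy += (yg @ yg - c * ys_**2) / s2e
    beta = np.linalg.solve(xtvx, xtvy)
    quad = ytvy - xtvy @ beta
    sign, logdet_x = np.linalg.slogdet(xtvx)
    return logdet_v + logdet_x + quad


def _contrast_var(theta, X, group_idx, n_groups, j) -> float:
    """Var(beta_j) = [(X' V^-1 X)^-1]_jj at variance components theta."""
    s2g, s2e = theta
    s2g = max(s2g, 0.0)
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    for g in range(n_groups):
        m = group_idx == g
        ng = int(m.sum())
        Xg = X[m]
        c = s2g / (s2e + ng * s2g)
        xs = Xg.sum(axis=0)
        xtvx += (Xg.T @ Xg - c * np.outer(xs, xs)) / s2e
    return float(np.linalg.inv(xtvx)[j, j])


def _satterthwaite_df(theta, y, X, group_idx, n_groups, j) -> float:
    """Satterthwaite df for the contrast on coefficient j.

    df = 2 g^2 / (grad g' A grad g), with g(theta) = Var(beta_j), the
    gradient taken numerically, and A the inverse observed information of
    the REML criterion (also numerical). Falls back to the residual df when
    the information matrix is not usable.
    """
    n, p = X.shape
    resid_df = n - p

    def g(th):
        return _contrast_var(th, X, group_idx, n_groups, j)

    def ll(th):
        return -0.5 * _reml_neg2(th, y, X, group_idx, n_groups)

    h = np.maximum(1e-4 * np.abs(theta), 1e-8)
    lower = np.array([0.0, 1e-12])
    grad = np.zeros(2)
    hess = np.zeros((2, 2))
    try:
        for k in range(2):
            e = np.zeros(2)
            e[k] = h[k]
            lo = np.maximum(theta - e, lower)
            grad[k] = (g(theta + e) - g(lo)) / (theta[k] + h[k] - lo[k])
        for k in range(2):
            for l in range(k, 2):
                ek, el = np.zeros(2), np.zeros(2)
                ek[k], el[l] = h[k], h[l]
                fpp = ll(theta + ek + el)
                fpm = ll(theta + ek - el)
                fmp = ll(theta - ek + el)
                fmm = ll(theta - ek - el)
                hess[k, l] = hess[l, k] = (fpp - fpm - fmp + fmm) / (4 * h[k] * h[l])
        A = np.linalg.inv(-hess)
        denom = grad @ A @ grad
        if denom <= 0:
            return float(resid_df)
        df = 2.0 * g(theta) ** 2 / denom
        return float(np.clip(df, 1.0, resid_df))
    except (np.linalg.LinAlgError, FloatingPointError):
        return float(resid_df)


def mixed_model_de(
    snr: SnrMatrix,
    fixed: Mapping[str, str] | str,
    grouping: Mapping[str, str] | str = "tissue_id",
    contrast: tuple[str, str] | None = None,
    per_analyte_bh: bool = True,
    df_method: str = "satterthwaite",
) -> pd.DataFrame:
    """Per-target mixed model: log2 SNR ~ intercept + segment + (1 | tissue).

    ``fixed`` is the segment factor (an AOI-annotation column name or an
    aoi_id -> label mapping); ``grouping`` likewise for the tissue factor.
    ``contrast=(g1, g2)`` fixes the direction: log2fc estimates g1 - g2
    (defaults to the two labels in reverse-sorted AOI order matching
    group 1 - group 2 of the t-test convention: first label seen is g2's
    reference only if explicitly given; by default labels are sorted and
    log2fc = second - first). REML fit via statsmodels MixedLM; singular
    fits (random-effect variance at 0) fall back to the fixed-effects-only
    OLS t-test for that target, flagged "fixed_only"; non-convergence yields
    a missing p, flagged "no_convergence". ``df_method`` is "satterthwaite"
    or "normal" (z-test).
    """
    aois = snr.aois
    if isinstance(fixed, str):
        fixed_map = aois[fixed].to_dict()
    else:
        fixed_map = dict(fixed)
    if isinstance(grouping, str):
        group_map = aois[grouping].to_dict()
    else:
        group_map = dict(grouping)

    cols = list(snr.values.columns)
    labels = sorted(set(fixed_map[a] for a in cols))
    if len(labels) != 2:
        raise ValueError(f"segment factor must have exactly 2 levels, got {labels}")
    if contrast is None:
        contrast = (labels[1], labels[0])
    g1, g2 = contrast
    if {g1, g2} != set(labels):
        raise ValueError(f"contrast {contrast} does not match levels {labels}")

    tissues = sorted(set(group_map[a] for a in cols))
    if len(tissues) < 2:
        raise ValueError("mixed model needs >= 2 tissues")
    group_idx = np.array([tissues.index(group_map[a]) for a in cols])
    x_ind = np.array([1.0 if fixed_map[a] == g1 else 0.0 for a in cols])
    X = np.column_stack([np.ones(len(cols)), x_ind])
    n_groups = len(tissues)
    logy = np.log2(snr.values.to_numpy())

    rows = []
    for i, tid in enumerate(snr.values.index):
        y = logy[i]
        flag = ""
        est = p = np.nan
        s2g_out = s2e_out = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(y, X, groups=group_idx)
                fit = model.fit(reml=True)
            s2g = float(np.asarray(fit.cov_re)[0, 0])
            s2e = float(fit.scale)
            est = float(np.asarray(fit.fe_params)[1])
            s2g_out, s2e_out = s2g, s2e
            if s2g <= 1e-8 * max(s2e, 1e-12):
                # singular fit: fixed-effects-only model
                flag = "fixed_only"
                ols = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ ols[0]
                dfr = len(y) - 2
                s2 = resid @ resid / dfr
                se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
                est = float(ols[0][1])
                t = est / se if se > 0 else np.inf * np.sign(est)
                p = float(2 * stats.t.sf(abs(t), dfr))
            else:
                theta = np.array([s2g, s2e])
                var = _contrast_var(theta, X, group_idx, n_groups, 1)
                se = np.sqrt(var)
                t = est / se
                if df_method == "normal":
                    p = float(2 * stats.norm.sf(abs(t)))
                else:
                    df = _satterthwaite_df(theta, y, X, group_idx, n_groups, 1)
                    p = float(2 * stats.t.sf(abs(t), df))
        except Exception:  # non-convergence or numerical failure
            flag = "no_convergence"
            logger.warning("mixed model failed for target %s", tid)
        rows.append(
            {
                "target_id": tid,
                "analyte": snr.targets.loc[tid, "analyte"],
                "log2fc": est,
                "p": p,
                "method": "mixed_model",
                "n1": int(x_ind.sum()),
                "n2": int(len(cols) - x_ind.sum()),
                "re_var": s2g_out,
                "resid_var": s2e_out,
                "flag": flag,
            }
        )
    return _finalize(rows, per_analyte_bh)


# ---------------------------------------------------------------------------
# Post-processing
# ---------------------------------------------------------------------------


def significant_targets(
    de: pd.DataFrame, fdr_cut: float = 0.001, fc_cut: float = 2.0
) -> list:
    """Targets with FDR < fdr_cut and |fold change| strictly > fc_cut."""
    if de.empty:
        return []
    mask = (de["fdr"] < fdr_cut) & (de["log2fc"].abs() > np.log2(fc_cut))
    return list(de.loc[mask, "target_id"])


def combined_volcano_table(
    de_rna: pd.DataFrame, de_protein: pd.DataFrame
) -> pd.DataFrame:
    """Merge RNA and protein DE tables into one plottable volcano table.

    Adds -log10(p); errors on duplicated (target, analyte) pairs. Row count
    equals the sum of the inputs.
    """
    merged = pd.concat([de_rna, de_protein], ignore_index=True)
    if merged.duplicated(subset=["target_id", "analyte"]).any():
        dups = merged[merged.duplicated(subset=["target_id", "analyte"], keep=False)]
        raise ValueError(
            f"duplicated (target, analyte) pairs: "
            f"{sorted(set(zip(dups['target_id'], dups['analyte'])))}"
        )
    with np.errstate(divide="ignore"):
        merged["neg_log10_p"] = -np.log10(merged["p"])
    return merged
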