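"""Consensus differential transcription between phosphate conditions.

A gene is called differentially transcribed only when at least two of
three count-based tests agree at a Benjamini-Hochberg adjusted
p < 0.01, with no fold-change cutoff. The three tests are native
analogues of the classic count-based toolkit:

* an exact conditional negative-binomial test (two group sums
  conditioned on their total, edgeR-style);
* a Wald test on the negative-binomial GLM log fold change
  (DESeq2-style);
* an empirical-Bayes moderated t-statistic on log2 counts
  (limma-style), with the residual-variance prior fitted by moments.

All three consume the marker-normalized rescaled pseudo-counts
rounded half-up to integers; marker normalization already equalizes
effective library sizes, so no further size factors are applied.

Negative-binomial convention throughout: variance = mu + phi * mu^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, polygamma
from scipy.stats import norm
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .types import Contrast, CountMatrix, SampleSheet, ValidationError

#: pseudo-mean added to zero group means to keep fold changes finite
PSEUDO_MEAN = 0.125
#: offset for the log2 transform of the moderated t
LOG_OFFSET = 0.5
#: above this conditional total the exact test switches to a Laplace
#: approximation of its log-concave conditional distribution
EXACT_ENUMERATION_LIMIT = 10_000


def _group_arrays(values: pd.DataFrame, contrast: Contrast) -> tuple[np.ndarray, np.ndarray]:
    missing = (set(contrast.group_a) | set(contrast.group_b)) - set(values.columns)
    if missing:
        raise ValidationError(f"contrast samples missing from matrix: {sorted(missing)}")
    a = values[list(contrast.group_a)].to_numpy(dtype=float)
    b = values[list(contrast.group_b)].to_numpy(dtype=float)
    return a, b


def make_contrast(
    sheet: SampleSheet,
    phase: str,
    condition_a: str = "low_p",
    condition_b: str = "high_p",
) -> Contrast:
    """Two-condition contrast within one reactor phase; group A is the
    test condition (positive log2fc = up in A)."""
    a = tuple(sheet.samples_in(condition=condition_a, phase=phase))
    b = tuple(sheet.samples_in(condition=condition_b, phase=phase))
    return Contrast(group_a=a, group_b=b, label=f"{condition_a} vs {condition_b}, {phase}")


# ----------------------------------------------------------- dispersion


def estimate_dispersions(
    values: pd.DataFrame,
    contrast: Contrast,
    d0: float = 10.0,
) -> pd.Series:
    """Method-of-moments NB dispersion per gene, shrunk to the median.

    phi_g = max(0, (v - m) / m^2) pooled across the two groups
    (weighted by degrees of freedom), then squeezed toward the
    across-gene median with prior weight d0:
    phi~ = (d0 * phi_med + n_g * phi_g) / (d0 + n_g).
    """
    a, b = _group_arrays(values, contrast)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples to estimate dispersion")

    phis = np.zeros(len(values))
    weights = np.zeros(len(values))
    for g in (a, b):
        n = g.shape[1]
        m = g.mean(axis=1)
        v = g.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(m > 0, (v - m) / np.square(m), 0.0)
        phis += (n - 1) * phi
        weights += n - 1
    phi_g = np.maximum(0.0, phis / weights)
    phi_med = float(np.median(phi_g))
    n_g = a.shape[1] + b.shape[1]
    shrunk = (d0 * phi_med + n_g * phi_g) / (d0 + n_g)
    return pd.Series(shrunk, index=values.index, name="dispersion")


# ------------------------------------------------------------ exact test


def _nb_logpmf(k: np.ndarray | float, mean: float, phi: float) -> np.ndarray:
    """NB(mean, phi) log-pmf via gamma functions; phi=0 is Poisson.

    Accepts non-integer k (the analytic continuation is used by the
    large-count Laplace approximation).
    """
    k = np.asarray(k, dtype=float)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if phi == 0.0:
        return k * np.log(mean) - mean - gammaln(k + 1.0)
    r = 1.0 / phi
    return (
        gammaln(k + r)
        - gammaln(r)
        - gammaln(k + 1.0)
        + r * np.log(r / (r + mean))
        + k * np.log(mean / (r + mean))
    )


def _exact_p_one(s_a: float, s_b: float, n_a: int, n_b: int, phi: float) -> float:
    """Conditional two-sided exact p for one gene.

    The group sums are modeled as S_a ~ NB(n_a*mu, phi/n_a) and
    S_b ~ NB(n_b*mu, phi/n_b) with mu = T/(n_a+n_b); conditioning on
    T = S_a + S_b removes mu up to the dispersion. The p-value sums the
    conditional probabilities of all splits no more likely than the
    observed one.
    """
    T = s_a + s_b
    if T <= 0:
        return 1.0
    mu = T / (n_a + n_b)
    mean_a, mean_b = n_a * mu, n_b * mu
    phi_a, phi_b = phi / n_a, phi / n_b

    if T <= EXACT_ENUMERATION_LIMIT:
        k = np.arange(int(T) + 1)
        logf = _nb_logpmf(k, mean_a, phi_a) + _nb_logpmf(T - k, mean_b, phi_b)
        logf -= logf.max()
        f = np.exp(logf)
        obs = f[int(s_a)]
        # 1e-12 relative tolerance absorbs float ties at the observed level
        p = f[f <= obs * (1.0 + 1e-12)].sum() / f.sum()
        return float(min(1.0, p))

    # Laplace: the conditional pmf is log-concave; approximate it by a
    # Gaussian centered on the conditional mean with curvature-matched sd.
    # d^2/dk^2 log nbinom(k; mu, phi) = psi1(k + 1/phi) - psi1(k + 1)
    # analytically, avoiding cancellation in finite differences.
    k0 = T * n_a / (n_a + n_b)

    def d2(k: float, phi_grp: float) -> float:
        if phi_grp == 0.0:  # Poisson limit
            return -float(polygamma(1, k + 1.0))
        return float(polygamma(1, k + 1.0 / phi_grp) - polygamma(1, k + 1.0))

    curv = d2(k0, phi_a) + d2(T - k0, phi_b)
    if curv >= 0:  # numerically flat; no evidence either way
        return 1.0
    sd = np.sqrt(-1.0 / curv)
    z = (abs(s_a - k0) - 0.5) / sd  # 0.5: continuity correction
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    return np.log2((mean_a + PSEUDO_MEAN) / (mean_b + PSEUDO_MEAN))


def exact_test_nb(
    values: pd.DataFrame,
    contrast: Contrast,
    dispersion: pd.Series,
) -> pd.DataFrame:
    """Exact conditional NB test per gene; returns log2fc and p."""
    a, b = _group_arrays(values, contrast)
    n_a, n_b = a.shape[1], b.shape[1]
    s_a = a.sum(axis=1)
    s_b = b.sum(axis=1)
    phi = dispersion.loc[values.index].to_numpy(dtype=float)
    p = np.array(
        [_exact_p_one(sa, sb, n_a, n_b, ph) for sa, sb, ph in zip(s_a, s_b, phi)]
    )
    return pd.DataFrame(
        {"log2fc": _log2fc(s_a / n_a, s_b / n_b), "p": p}, index=values.index
    )


# -------------------------------------------------------------- NB Wald


def glm_wald_nb(
    values: pd.DataFrame,
    contrast: Contrast,
    dispersion: pd.Series,
) -> pd.DataFrame:
    """Wald test on the NB log fold change with known dispersion.

    Group means are the MLEs under a two-group NB model; the delta-
    method standard error of ln(mu_a/mu_b) is
    sqrt((1/n_a)(1/mu_a + phi) + (1/n_b)(1/mu_b + phi)).
    """
    a, b = _group_arrays(values, contrast)
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    phi = dispersion.loc[values.index].to_numpy(dtype=float)

    mu_a = np.where(mean_a > 0, mean_a, PSEUDO_MEAN)
    mu_b = np.where(mean_b > 0, mean_b, PSEUDO_MEAN)
    lfc = np.log2(mu_a / mu_b)
    se_ln = np.sqrt((1.0 / mu_a + phi) / n_a + (1.0 / mu_b + phi) / n_b)
    se = se_ln / np.log(2.0)
    with np.errstate(invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    p[(mean_a == 0) & (mean_b == 0)] = 1.0
    lfc[(mean_a == 0) & (mean_b == 0)] = 0.0
    return pd.DataFrame({"log2fc": lfc, "p": p}, index=values.index)


# --------------------------------------------------------- moderated t


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (s0^2, d0) to
    observed residual variances on the log scale.

    Under the hierarchical model, log s^2 has variance
    trigamma(df/2) + trigamma(d0/2); the excess spread of log s^2 over
    the pure sampling term identifies d0, and the mean identifies s0^2.
    """
    s2 = s2[s2 > 0]
    if len(s2) < 2:
        return float(s2.mean() if len(s2) else 1.0), 1e8
    z = np.log(s2)
    e_bias = float(polygamma(0, df / 2.0)) - np.log(df / 2.0)
    var_z = float(np.var(z, ddof=1))
    excess = var_z - float(polygamma(1, df / 2.0))
    if excess <= 0:
        d0 = 1e8  # variances are exchangeable; prior dominates
        s0_sq = float(np.exp(np.mean(z) - e_bias))
        return s0_sq, d0
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(
        np.exp(np.mean(z) - e_bias + float(polygamma(0, d0 / 2.0)) - np.log(d0 / 2.0))
    )
    return s0_sq, d0


def moderated_t_log(
    values: pd.DataFrame,
    contrast: Contrast,
    d0: float | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t on y = log2(value + 0.5).

    Per-gene pooled variances are squeezed toward a fitted prior
    (s~^2 = (d0*s0^2 + d*s^2)/(d0 + d)) and the t statistic gains
    d0 extra degrees of freedom. ``d0=0`` reduces to the ordinary
    two-sample t-test.
    """
    a, b = _group_arrays(values, contrast)
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValidationError("moderated t needs >= 2 samples per group")
    ya = np.log2(a + LOG_OFFSET)
    yb = np.log2(b + LOG_OFFSET)
    diff = ya.mean(axis=1) - yb.mean(axis=1)
    df = n_a + n_b - 2
    ss = ya.var(axis=1, ddof=1) * (n_a - 1) + yb.var(axis=1, ddof=1) * (n_b - 1)
    s2 = ss / df

    if d0 is None:
        s0_sq, d0 = fit_variance_prior(s2, df)
    elif d0 > 0:
        s0_sq, _ = fit_variance_prior(s2, df)
    else:
        s0_sq = 0.0
    s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df) if d0 > 0 else s2

    denom = np.sqrt(s2_tilde * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    t[(denom == 0) & (diff != 0)] = np.inf * np.sign(diff[(denom == 0) & (diff != 0)])
    df_total = min(d0 + df, 1e8)
    p = 2.0 * t_dist.sf(np.abs(t), df_total)
    return pd.DataFrame({"log2fc": diff, "p": p}, index=values.index)


# ------------------------------------------------- adjustment, consensus


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consensus_de(
    table: pd.DataFrame,
    alpha: float = 0.01,
    min_methods: int = 2,
) -> pd.DataFrame:
    """Vote across the three methods' adjusted p-values.

    Adds n_significant_methods and the consensus flag; no fold-change
    restriction is applied.
    """
    cols = ["padj_exact", "padj_glm", "padj_modt"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValidationError(f"missing adjusted p columns: {missing}")
    out = table.copy()
    out["n_significant_methods"] = (out[cols] < alpha).sum(axis=1).astype(int)
    out["consensus"] = out["n_significant_methods"] >= min_methods
    return out


def de_pipeline(
    rescaled: CountMatrix | pd.DataFrame,
    sheet: SampleSheet,
    contrast: Contrast,
    alpha: float = 0.01,
    min_methods: int = 2,
) -> pd.DataFrame:
    """Round pseudo-counts, run the three tests, adjust, and vote.

    The returned table carries one row per gene: the NB log2 fold
    change (group A over group B), per-method raw and BH-adjusted
    p-values, the vote count, the consensus flag, and the direction
    ("up_a"/"up_b"/"ns") spelled with the contrast's group labels.
    """
    values = rescaled.values if isinstance(rescaled, CountMatrix) else rescaled
    ints = pd.DataFrame(
        np.floor(values.to_numpy(dtype=float) + 0.5),  # round half-up
        index=values.index,
        columns=values.columns,
    )
    phi = estimate_dispersions(ints, contrast)
    exact = exact_test_nb(ints, contrast, phi)
    wald = glm_wald_nb(ints, contrast, phi)
    modt = moderated_t_log(ints, contrast)

    table = pd.DataFrame(
        {
            "log2fc": exact["log2fc"],
            "p_exact": exact["p"],
            "p_glm": wald["p"],
            "p_modt": modt["p"],
        },
        index=ints.index,
    )
    for method in ("exact", "glm", "modt"):
        table[f"padj_{method}"] = bh_adjust(table[f"p_{method}"])
    table = consensus_de(table, alpha=alpha, min_methods=min_methods)
    table["direction"] = np.where(
        ~table["consensus"], "ns", np.where(table["log2fc"] > 0, "up_a", "up_b")
    )
    table.attrs["contrast"] = contrast.label
    return table
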