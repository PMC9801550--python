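"""Per-feature differential analysis with empirical-Bayes variance moderation.

Each feature (CpG on the M-value scale, or gene on the log2-expression
scale) is fitted with an ordinary two-group or paired one-sample linear
model.  Residual variances are then shrunk toward a global prior
estimated by closed-form moment matching on log variances: if
s2_g ~ s0^2 * chi2_d / d scaled by a scaled-inverse-chi-square prior with
d0 degrees of freedom and scale s0^2, then

    e_g = log(s2_g) - digamma(d_g/2) + log(d_g/2)

has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance
trigamma(d0/2) beyond the sampling term trigamma(d_g/2).  Matching the
first two moments of e_g yields d0 and s0^2; the posterior variance is
the precision-weighted blend

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated t-statistic coef / (u * sqrt(s2_post)) has d0 + d_g
degrees of freedom.  Effect sizes are always reported on the beta scale
(delta beta), never back-transformed from the M-scale coefficient.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    BetaMatrix,
    ExpressionMatrix,
    MValueMatrix,
    SampleSheet,
    ValidationError,
)

logger = logging.getLogger("regmeth")


@dataclass
class ModelFit:
    """Per-feature ordinary fit plus the estimated global variance prior."""

    feature_ids: list[str]
    coef: np.ndarray               # group difference (M or log2-expression units)
    stdev_unscaled: float          # u: sd of coef per unit residual sd
    sigma2: np.ndarray             # residual variance s2_g
    df_residual: float             # d_g (equal across features here)
    df_prior: float                # d0, may be inf
    s2_prior: float                # s0^2
    s2_post: np.ndarray            # moderated variance


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def fit_variance_prior(sigma2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Moment-matching estimate of (d0, s0^2) from residual variances.

    Returns df_prior = inf (with s0^2 the plain geometric-mean-based
    scale) when the excess-variance equation has no positive solution.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if (sigma2 <= 0).any():
        # zero residual variance: nudge to smallest positive observed value
        floor = sigma2[sigma2 > 0].min() if (sigma2 > 0).any() else 1e-12
        sigma2 = np.maximum(sigma2, floor * 1e-6)
    half_d = df_residual / 2.0
    e = np.log(sigma2) - special.digamma(half_d) + math.log(half_d)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, half_d))
    if e_var > 0:
        d0 = 2.0 * trigamma_inverse(e_var)
        s20 = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        logger.info("non-positive excess variance of log s2; prior df set to infinity")
        d0 = math.inf
        s20 = math.exp(e_mean)
    return d0, s20


def _posterior_variance(
    sigma2: np.ndarray, df_residual: float, d0: float, s20: float
) -> np.ndarray:
    if math.isinf(d0):
        return np.full_like(sigma2, s20)
    return (d0 * s20 + df_residual * sigma2) / (d0 + df_residual)


def fit_moderated_model(
    matrix: MValueMatrix | ExpressionMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    paired: bool = False,
    on: str = "group",
    df_prior_override: float | None = None,
) -> tuple[ModelFit, pd.DataFrame]:
    """Moderated two-group (or paired one-sample) t-test per feature.

    ``contrast = (A, B)`` tests A minus B; labels are matched against the
    sample-sheet column ``on``.  With ``paired=True`` the per-patient
    A-minus-B differences are tested against zero.  ``df_prior_override``
    forces d0 (0 recovers the ordinary t-test; a huge value approaches
    complete shrinkage to the prior variance).

    Returns the fit and a stats frame with columns coef, t, p.
    """
    group_a, group_b = contrast
    samples_a = sheet.samples_in(group_a, on=on)
    samples_b = sheet.samples_in(group_b, on=on)
    if not samples_a or not samples_b:
        raise ValidationError(f"empty contrast group in {contrast} (column {on!r})")
    values = matrix.frame

    if paired:
        sub = sheet.frame.set_index("sample_id")
        patients_a = {sub.loc[s, "patient_id"]: s for s in samples_a}
        patients_b = {sub.loc[s, "patient_id"]: s for s in samples_b}
        shared = sorted(set(patients_a) & set(patients_b))
        if len(shared) < 2:
            raise ValidationError(
                f"paired contrast {contrast} needs >=2 complete pairs, got {len(shared)}"
            )
        diffs = (
            values[[patients_a[p] for p in shared]].to_numpy()
            - values[[patients_b[p] for p in shared]].to_numpy()
        )
        n = len(shared)
        coef = diffs.mean(axis=1)
        sigma2 = diffs.var(axis=1, ddof=1)
        df_residual = float(n - 1)
        stdev_unscaled = 1.0 / math.sqrt(n)
    else:
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise ValidationError(f"both groups in {contrast} need >=2 samples")
        a = values[samples_a].to_numpy()
        b = values[samples_b].to_numpy()
        na, nb = a.shape[1], b.shape[1]
        coef = a.mean(axis=1) - b.mean(axis=1)
        rss = a.var(axis=1, ddof=1) * (na - 1) + b.var(axis=1, ddof=1) * (nb - 1)
        df_residual = float(na + nb - 2)
        sigma2 = rss / df_residual
        stdev_unscaled = math.sqrt(1.0 / na + 1.0 / nb)
    if df_residual < 1:
        raise ValidationError("zero residual degrees of freedom")

    if df_prior_override is not None:
        d0 = float(df_prior_override)
        _, s20 = fit_variance_prior(sigma2, df_residual)
        if d0 == 0.0:
            s2_post = sigma2.copy()
        else:
            s2_post = _posterior_variance(sigma2, df_residual, d0, s20)
    else:
        d0, s20 = fit_variance_prior(sigma2, df_residual)
        s2_post = _posterior_variance(sigma2, df_residual, d0, s20)

    df_total = df_residual + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / (stdev_unscaled * np.sqrt(s2_post))
    t = np.where(np.isfinite(t), t, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    fit = ModelFit(
        feature_ids=list(values.index),
        coef=coef,
        stdev_unscaled=stdev_unscaled,
        sigma2=sigma2,
        df_residual=df_residual,
        df_prior=d0,
        s2_prior=s20,
        s2_post=s2_post,
    )
    stats_frame = pd.DataFrame({"coef": coef, "t": t, "p": p}, index=values.index)
    return fit, stats_frame


def compute_delta_beta(
    beta: BetaMatrix, sheet: SampleSheet, contrast: tuple[str, str], on: str = "group"
) -> pd.Series:
    """Delta beta = mean beta(A) - mean beta(B), on the untransformed scale."""
    samples_a = sheet.samples_in(contrast[0], on=on)
    samples_b = sheet.samples_in(contrast[1], on=on)
    if not samples_a or not samples_b:
        raise ValidationError(f"empty contrast group in {contrast}")
    delta = beta.frame[samples_a].mean(axis=1) - beta.frame[samples_b].mean(axis=1)
    delta.name = "delta_beta"
    return delta


def adjust_fdr_bh(p: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    arr = np.asarray(p, dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("NaN p-values passed to BH adjustment")
    q = multipletests(arr, method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(q, index=p.index, name="q")
    return q


def call_dm_cpgs(
    stats_frame: pd.DataFrame,
    delta_threshold: float = 0.2,
    fdr_threshold: float = 0.05,
    use_raw_p: bool = False,
) -> pd.Series:
    """Classify CpGs as hyper / hypo / ns.

    hyper requires delta_beta >= +delta_threshold and q < fdr_threshold
    (hypo symmetric).  ``use_raw_p`` switches the significance column to
    the raw p-value for sensitivity analyses at relaxed thresholds
    (e.g. p < 0.001, |delta beta| > 0.05).
    """
    needed = {"delta_beta", "p" if use_raw_p else "q"}
    missing = needed - set(stats_frame.columns)
    if missing:
        raise ValidationError(f"stats frame missing columns {sorted(missing)}")
    sig = stats_frame["p" if use_raw_p else "q"] < fdr_threshold
    call = pd.Series("ns", index=stats_frame.index, name="call")
    call[sig & (stats_frame["delta_beta"] >= delta_threshold)] = "hyper"
    call[sig & (stats_frame["delta_beta"] <= -delta_threshold)] = "hypo"
    return call


def differential_methylation(
    beta: BetaMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    paired: bool = False,
    on: str = "group",
    epsilon: float = 1e-3,
    delta_threshold: float = 0.2,
    fdr_threshold: float = 0.05,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Full per-CpG DM table: coef, t, p, q, delta_beta, call.

    Testing runs on M-values; the reported effect size is delta beta.
    """
    from .containers import beta_to_mvalue

    m = beta_to_mvalue(beta, epsilon=epsilon)
    _, frame = fit_moderated_model(m, sheet, contrast, paired=paired, on=on)
    frame["q"] = adjust_fdr_bh(frame["p"])
    frame["delta_beta"] = compute_delta_beta(beta, sheet, contrast, on=on)
    frame["call"] = call_dm_cpgs(
        frame,
        delta_threshold=delta_threshold,
        fdr_threshold=fdr_threshold,
        use_raw_p=use_raw_p,
    )
    return frame


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalisation across columns.

    After normalisation every column shares the identical sorted value
    vector (the cross-column means of the order statistics); ties within
    a column receive the mean of their tied rank means.
    """
    frame = x.frame
    if frame.shape[1] < 2:
        return ExpressionMatrix(frame.copy())
    arr = frame.to_numpy()
    rank_means = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = 0.5 * (rank_means[lo] + rank_means[hi])
    return ExpressionMatrix(pd.DataFrame(out, index=frame.index, columns=frame.columns))


def differential_expression(
    x: ExpressionMatrix,
    sheet: SampleSheet,
    contrast: tuple[str, str],
    paired: bool = False,
    on: str = "group",
    logfc_threshold: float = 0.6,
    fdr_threshold: float = 0.2,
) -> pd.DataFrame:
    """Moderated differential expression with up/down/ns calls.

    Reuses the moderated engine on log2 expression; the coefficient is
    the log2 fold change.  Defaults: |log2FC| > 0.6 and FDR < 0.2.
    """
    _, frame = fit_moderated_model(x, sheet, contrast, paired=paired, on=on)
    frame = frame.rename(columns={"coef": "log2fc"})
    frame["q"] = adjust_fdr_bh(frame["p"])
    sig = frame["q"] < fdr_threshold
    call = pd.Series("ns", index=frame.index, name="call")
    call[sig & (frame["log2fc"] > logfc_threshold)] = "up"
    call[sig & (frame["log2fc"] < -logfc_threshold)] = "down"
    frame["call"] = call
    return frame
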