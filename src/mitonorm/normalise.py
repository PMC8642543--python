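"""Mitochondrial-content-aware normalisation.

This module implements:

* **MPE** — mitochondrial protein enrichment: the percent of a sample's
  summed raw intensity attributable to annotated mitochondrial proteins,
  computed on the full matrix before any filtering, with missing values
  contributing 0 to the sums.
* **BESt chain** — the biochemical-enrichment + statistical-correction
  normalisation for isolate proteomics, in fixed order: marker-flag removal
  (at ingestion) -> valid-value filter -> mitochondrial subsetting ->
  variance-stabilising transform -> left-censored imputation.
* **VSN** — a per-sample affine-calibrated generalised-log transform
  ``h_s(x) = glog2(a_s + b_s x)`` fitted by maximum profile likelihood with
  least-trimmed-squares robustness, output anchored to a log2-compatible
  scale.
* **QRILC-style imputation** — missing values drawn from a per-sample normal
  estimated by quantile regression of the observed order statistics, truncated
  above at the sample's observed minimum.
* **Compositional lipid normalisation** — every species scaled by the
  sample's total anchor-class (cardiolipin) concentration.
* **content_normalise** — the classical single-scalar ratio normalisation
  (e.g. by citrate synthase activity or by MPE).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import (
    KNOWN_MITO,
    AnnotationTable,
    IntensityMatrix,
    LipidMatrix,
    MPEProfile,
    NormalisedMatrix,
    ValidationError,
)

logger = logging.getLogger("mitonorm")

__all__ = [
    "best_normalise",
    "compute_mpe",
    "content_normalise",
    "filter_valid_values",
    "glog2",
    "impute_left_censored",
    "normalise_lipids_by_class",
    "subset_mitochondrial",
    "vsn_transform",
]

_LN2 = np.log(2.0)


def glog2(z):
    """Generalised log2: ``log2(z + sqrt(z**2 + 1)) - 1``.

    The offset of 1 makes the transform match plain ``log2`` asymptotically:
    for large ``z``, ``z + sqrt(z**2+1) -> 2z``, so ``glog2(z) -> log2(z)``.
    Defined and strictly increasing for all real ``z``.
    """
    return np.arcsinh(np.asarray(z, dtype=float)) / _LN2 - 1.0


def compute_mpe(
    matrix: IntensityMatrix,
    annotation: AnnotationTable | None = None,
    level: str = KNOWN_MITO,
) -> MPEProfile:
    """Per-sample mitochondrial protein enrichment (percent).

    ``MPE_s = 100 * (sum of raw intensity of mitochondrial features in s)
    / (sum of raw intensity of all features in s)``, with missing values
    contributing 0. Uses raw intensities, on the full (unfiltered) matrix.
    """
    conf = _confidence(matrix, annotation)
    if level == "Known+Predicted":
        mito = conf.isin({KNOWN_MITO, "Predicted Mitochondrial"})
    else:
        mito = conf == level
    if not mito.any():
        raise ValidationError(
            f"no feature annotated at level {level!r} present in the matrix"
        )
    raw = matrix.values.fillna(0.0)
    total = raw.sum(axis=0)
    if (total <= 0).any():
        bad = total.index[total <= 0].tolist()
        raise ValidationError(f"sample(s) with zero total intensity: {bad}")
    percent = 100.0 * raw.loc[mito.to_numpy()].sum(axis=0) / total
    percent.name = "mpe_percent"
    return MPEProfile(percent=percent, level=level, intensity_column="raw")


def _confidence(matrix: IntensityMatrix,
                annotation: AnnotationTable | None) -> pd.Series:
    if annotation is not None:
        return annotation.confidence.reindex(matrix.features).fillna("none")
    if matrix.annotation is not None:
        return matrix.annotation
    raise ValidationError("no annotation joined or supplied")


def filter_valid_values(matrix: IntensityMatrix,
                        min_fraction: float = 0.70) -> IntensityMatrix:
    """Retain features quantified in at least ``min_fraction`` of samples.

    The boundary is inclusive: a feature observed in exactly the threshold
    fraction of samples is retained (features *below* the threshold are
    removed).
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValidationError("min_fraction must be in (0, 1]")
    n = len(matrix.samples)
    counts = matrix.observed.sum(axis=1)
    keep = counts.to_numpy() >= min_fraction * n - 1e-9
    logger.info("valid-value filter (>=%.0f%%): retained %d / %d features",
                100 * min_fraction, int(keep.sum()), len(keep))
    return matrix.subset(matrix.features[keep])


def subset_mitochondrial(
    matrix: IntensityMatrix,
    annotation: AnnotationTable | None = None,
    level: str = KNOWN_MITO,
) -> IntensityMatrix:
    """Retain only features annotated at the requested confidence level."""
    conf = _confidence(matrix, annotation)
    if level == "Known+Predicted":
        mask = conf.isin({KNOWN_MITO, "Predicted Mitochondrial"})
    else:
        mask = conf == level
    if not mask.any():
        raise ValidationError(f"no features at confidence level {level!r}")
    logger.info("mitochondrial subset (%s): retained %d / %d features",
                level, int(mask.sum()), len(mask))
    return matrix.subset(matrix.features[mask.to_numpy()])


# ---------------------------------------------------------------------------
# variance-stabilising transform
# ---------------------------------------------------------------------------

def _joint_nll(theta: np.ndarray, x: np.ndarray, mask: np.ndarray):
    """Negative profile log-likelihood and gradient for all samples jointly.

    ``theta`` stacks (a_1..a_S, log b_1..log b_S); per-feature means and the
    noise variance are profiled out analytically. ``mask`` marks the entries
    (kept features x observed) that inform the fit. The Jacobian term of the
    transform keeps the scale coefficients away from degenerate collapse.
    """
    n_samp = x.shape[1]
    a = theta[:n_samp]
    b = np.exp(theta[n_samp:])
    z = a[None, :] + b[None, :] * x
    z = np.where(mask, z, 0.0)
    h = np.arcsinh(z) / _LN2 - 1.0
    counts = mask.sum(axis=1)
    rows = counts > 0
    m = np.zeros(x.shape[0])
    hsum = np.where(mask, h, 0.0).sum(axis=1)
    m[rows] = hsum[rows] / counts[rows]
    r = np.where(mask, h - m[:, None], 0.0)
    rss = float((r * r).sum())
    rss = max(rss, 1e-300)
    n_used = int(mask.sum())
    one_pz2 = 1.0 + z * z
    jac = (mask * (np.log(b)[None, :] - np.log(_LN2)
                   - 0.5 * np.log(one_pz2))).sum()
    nll = 0.5 * n_used * np.log(rss) - jac
    h_z = 1.0 / (_LN2 * np.sqrt(one_pz2))
    common = (n_used / rss) * (r * h_z) + np.where(mask, z / one_pz2, 0.0)
    grad_a = common.sum(axis=0)
    grad_logb = (common * np.where(mask, x, 0.0)).sum(axis=0) * b \
        - mask.sum(axis=0)
    return nll, np.concatenate([grad_a, grad_logb])


def vsn_transform(
    matrix: IntensityMatrix,
    lts_quantile: float = 0.9,
    max_iter: int = 20,
) -> NormalisedMatrix:
    """Variance-stabilising transform with per-sample affine calibration.

    Fits ``h_s(x) = glog2(a_s + b_s x)`` so that transformed values are as
    close as possible to common per-feature means, by maximum profile
    likelihood (per-feature means and the noise variance are profiled out;
    the Jacobian term prevents degenerate collapse of the scale
    coefficients). Robustness is least-trimmed-squares: the optimisation is
    repeated while restricting to the ``lts_quantile`` fraction of features
    with the smallest residual sums until the trimmed set stabilises.

    The output is anchored so that the transform of the cohort-median sample
    matches plain ``log2`` for large intensities; differences between
    transformed values are therefore log2 fold changes.

    Missing entries are ignored during fitting and stay missing.
    """
    if len(matrix.samples) < 2:
        raise ValidationError("VSN needs at least 2 samples")
    if not 0.0 < lts_quantile <= 1.0:
        raise ValidationError("lts_quantile must be in (0, 1]")
    x = matrix.values.to_numpy(dtype=float)
    obs = np.isfinite(x)
    n_feat, n_samp = x.shape
    if (obs.sum(axis=0) < 3).any():
        bad = matrix.samples[obs.sum(axis=0) < 3].tolist()
        raise ValidationError(f"sample(s) with <3 observed values: {bad}")
    x_filled = np.where(obs, x, 0.0)

    # init: a = 0, b ~ 1 / median observed intensity per sample
    theta = np.zeros(2 * n_samp)
    for j in range(n_samp):
        theta[n_samp + j] = -np.log(np.median(x[obs[:, j], j]))

    keep = np.ones(n_feat, dtype=bool)
    converged = False
    opt = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mask = keep[:, None] & obs
        opt = optimize.minimize(
            _joint_nll, theta, args=(x_filled, mask), jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-15, "gtol": 1e-10},
        )
        theta = opt.x
        if lts_quantile >= 1.0:
            converged = True
            break
        a_fit = theta[:n_samp]
        b_fit = np.exp(theta[n_samp:])
        z = a_fit[None, :] + b_fit[None, :] * x_filled
        h = np.arcsinh(z) / _LN2 - 1.0
        counts = obs.sum(axis=1)
        m = np.where(obs, h, 0.0).sum(axis=1) / np.maximum(counts, 1)
        rss_feat = np.where(obs, (h - m[:, None]) ** 2, 0.0).sum(axis=1)
        new_keep = rss_feat <= np.quantile(rss_feat, lts_quantile)
        if np.array_equal(new_keep, keep):
            converged = True
            break
        keep = new_keep

    diagnostics = {"iterations": iterations, "converged": converged,
                   "lts_quantile": lts_quantile,
                   "trimmed_features": int((~keep).sum()),
                   "nll": float(opt.fun) if opt is not None else np.nan}
    if not converged:
        raise ValidationError(
            f"VSN trimming did not stabilise after {max_iter} rounds; "
            f"diagnostics={diagnostics}"
        )

    a = theta[:n_samp]
    b = np.exp(theta[n_samp:])
    if (b <= 0).any():  # pragma: no cover - b = exp(.) is always positive
        raise ValidationError("non-positive scale coefficient fitted")

    # anchor: the cohort-median scale coefficient maps to asymptotic log2(x)
    anchor = float(np.median(np.log2(b)))
    h = np.empty_like(x)
    for j in range(n_samp):
        z = a[j] + b[j] * x[:, j]
        h[:, j] = np.arcsinh(z) / _LN2 - 1.0 - anchor
    h[~obs] = np.nan

    values = pd.DataFrame(h, index=matrix.features, columns=matrix.samples)
    par = pd.DataFrame({"a": a, "b": b}, index=matrix.samples)
    diagnostics["anchor_log2"] = anchor
    return NormalisedMatrix(values=values, params=par,
                            diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# left-censored imputation
# ---------------------------------------------------------------------------

def impute_left_censored(
    matrix: NormalisedMatrix,
    seed: int | np.random.Generator = 0,
    quantile_range: tuple[float, float] = (0.25, 1.0),
    min_observed: int = 10,
) -> NormalisedMatrix:
    """Impute missing values as draws from each sample's censored lower tail.

    Per sample, the mean and sd of the complete underlying intensity
    distribution are estimated by least-squares regression of the observed
    order statistics against standard-normal quantiles, using only order
    statistics whose overall quantile (accounting for the left-censored
    missing mass) falls inside ``quantile_range`` — the upper, uncensored
    part of the distribution. Missing entries are then drawn from that
    normal truncated above at the sample's observed minimum.

    Deterministic for a fixed ``seed``. A complete matrix is returned
    unchanged (apart from a fresh copy).
    """
    qlo, qhi = quantile_range
    if not 0.0 <= qlo < qhi <= 1.0:
        raise ValidationError("invalid quantile_range")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    values = matrix.values.copy()
    imputed = matrix.imputed.copy()
    n_total = len(values.index)
    for s in values.columns:
        col = values[s]
        obs = col.dropna()
        if len(obs) < min_observed:
            raise ValidationError(
                f"sample {s!r} has only {len(obs)} observed values "
                f"(< {min_observed}); too few to fit the censored model"
            )
        n_miss = n_total - len(obs)
        if n_miss == 0:
            continue
        y = np.sort(obs.to_numpy())
        # overall quantiles of the observed order statistics, assuming the
        # missing mass sits below them (left censoring)
        p = (n_miss + np.arange(1, len(y) + 1) - 0.5) / n_total
        use = (p >= qlo) & (p <= qhi)
        if use.sum() < 3:
            use = p >= np.quantile(p, 0.5)  # fall back to the upper half
        q = stats.norm.ppf(p[use])
        slope, intercept = np.polyfit(q, y[use], 1)
        if slope <= 0:
            raise ValidationError(
                f"sample {s!r}: non-positive spread estimate in censored fit"
            )
        upper = (y[0] - intercept) / slope  # truncate at observed minimum
        draws = stats.truncnorm.rvs(
            -np.inf, upper, loc=intercept, scale=slope,
            size=n_miss, random_state=rng,
        )
        miss_index = col.index[col.isna()]
        values.loc[miss_index, s] = draws
        imputed.loc[miss_index, s] = True
    diagnostics = dict(matrix.diagnostics)
    diagnostics["imputation_quantile_range"] = quantile_range
    return NormalisedMatrix(values=values, params=matrix.params,
                            imputed=imputed, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# lipid + scalar normalisation
# ---------------------------------------------------------------------------

def normalise_lipids_by_class(lipids: LipidMatrix,
                              anchor_class: str = "CL") -> LipidMatrix:
    """Scale every species by the sample's summed anchor-class concentration.

    Values are then rescaled by the cohort-mean anchor total so the output
    keeps the original concentration units. After normalisation every
    sample's anchor-class total is identical, and within-sample ratios of
    any two species are unchanged (a single common divisor per sample).
    """
    members = lipids.class_members(anchor_class)
    if len(members) == 0:
        raise ValidationError(f"anchor class {anchor_class!r} not present")
    totals = lipids.values.loc[members].sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValidationError(
            f"zero total {anchor_class} in sample(s): {bad}"
        )
    factor = totals.mean() / totals
    return LipidMatrix(values=lipids.values.mul(factor, axis=1),
                       classes=lipids.classes)


def content_normalise(values: pd.Series, scaler: pd.Series) -> pd.Series:
    """Elementwise ratio of a per-sample scalar marker by a per-sample
    content proxy (e.g. citrate synthase activity, or MPE).

    Returns per-sample ratios in value-units per scaler-unit; any
    aggregation (e.g. group means) is the caller's responsibility, because
    the ratio of group means is not the mean of ratios.
    """
    scaler = scaler.reindex(values.index)
    if scaler.isna().any():
        raise ValidationError("scaler missing for some samples")
    if (scaler <= 0).any():
        bad = scaler.index[scaler <= 0].tolist()
        raise ValidationError(f"non-positive scaler for sample(s): {bad}")
    return values / scaler


# ---------------------------------------------------------------------------
# BESt chain
# ---------------------------------------------------------------------------

def best_normalise(
    matrix: IntensityMatrix,
    annotation: AnnotationTable | None = None,
    min_fraction: float = 0.70,
    level: str = KNOWN_MITO,
    vsn_scope: str = "mito",
    lts_quantile: float = 0.9,
    seed: int | np.random.Generator = 0,
) -> NormalisedMatrix:
    """Run the fixed BESt normalisation chain.

    Order: valid-value filter -> mitochondrial subsetting -> VSN ->
    left-censored imputation (marker-flagged rows are removed at ingestion).
    ``vsn_scope="all"`` instead fits the transform on all retained features
    and subsets afterwards — an alternative reading of the published chain,
    exposed for sensitivity analysis.
    """
    if vsn_scope not in {"mito", "all"}:
        raise ValidationError("vsn_scope must be 'mito' or 'all'")
    filtered = filter_valid_values(matrix, min_fraction)
    if vsn_scope == "mito":
        subset = subset_mitochondrial(filtered, annotation, level)
        transformed = vsn_transform(subset, lts_quantile=lts_quantile)
    else:
        transformed = vsn_transform(filtered, lts_quantile=lts_quantile)
        conf = _confidence(filtered, annotation)
        if level == "Known+Predicted":
            mask = conf.isin({KNOWN_MITO, "Predicted Mitochondrial"})
        else:
            mask = conf == level
        idx = transformed.values.index[mask.to_numpy()]
        transformed = NormalisedMatrix(
            values=transformed.values.loc[idx],
            params=transformed.params,
            imputed=transformed.imputed.loc[idx],
            diagnostics=transformed.diagnostics,
        )
    return impute_left_censored(transformed, seed=seed)
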