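"""Moderated differential-abundance statistics.

Two-tier testing scheme:

1. A per-feature ordinary-least-squares fit on the timepoint factor with
   participant as a fixed blocking factor, followed by empirical-Bayes
   variance shrinkage (moderated t per contrast and moderated F over the
   contrast set) and Benjamini–Hochberg adjustment. The *global* set is
   defined by the adjusted moderated-F p-value.
2. Pairwise two-sample Welch t-tests between timepoints with
   permutation-based FDR q-values; the per-comparison sets are intersected
   with the global set (the conservative two-tier approach).

The empirical-Bayes step shrinks each feature's residual variance towards a
prior estimated from all features by matching the first two moments of
``log s^2`` under the scaled chi-square model (prior df ``d0`` found by
numerical trigamma inversion); the posterior variance is
``s2_post = (d0*s02 + d*s2) / (d0 + d)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .containers import NormalisedMatrix, SampleDesign, ValidationError

__all__ = [
    "CONTRAST_SCHEMES",
    "LinearFits",
    "ModeratedStats",
    "PermutationFdrResult",
    "adjust_bh",
    "differential_features",
    "empirical_bayes_moderation",
    "fit_linear_models",
    "pairwise_permutation_fdr",
]

#: Contrast schemes over the ordered timepoints (BL, PN, PH, PR by default):
#: successive training phases, or every timepoint against baseline.
CONTRAST_SCHEMES = {
    "phase": [(1, 0), (2, 1), (3, 2)],
    "vs-baseline": [(1, 0), (2, 0), (3, 0)],
}


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, NormalisedMatrix):
        return matrix.values
    return matrix


@dataclass
class LinearFits:
    """Per-feature OLS results for a set of contrasts."""

    coefficients: pd.DataFrame  # features x contrasts, log2 units
    s2: pd.Series  # residual variance per feature
    df_residual: float
    stdev_unscaled: pd.Series  # sqrt of c' (X'X)^-1 c per contrast
    contrast_cov: np.ndarray  # C (X'X)^-1 C', contrasts x contrasts
    contrast_names: list[str] = field(default_factory=list)


def fit_linear_models(
    matrix,
    design: SampleDesign,
    contrast_scheme: str = "phase",
    block_participant: bool = True,
) -> LinearFits:
    """Fit a fixed-effects linear model per feature.

    The design is an intercept + timepoint factor (+ participant factor when
    ``block_participant``); contrasts are differences of timepoint effects
    per the requested scheme. The matrix must be complete (impute first).
    """
    values = _as_frame(matrix)
    if values.isna().any().any():
        raise ValidationError("matrix contains missing values; impute first")
    if contrast_scheme not in CONTRAST_SCHEMES:
        raise ValidationError(
            f"unknown contrast scheme {contrast_scheme!r}; "
            f"expected one of {sorted(CONTRAST_SCHEMES)}"
        )
    sub = design.table[design.table["sample"].isin(values.columns)]
    if set(values.columns) - set(sub["sample"]):
        missing = sorted(set(values.columns) - set(sub["sample"]))
        raise ValidationError(f"design does not cover sample(s): {missing}")
    sub = sub.set_index("sample").loc[values.columns]

    timepoints = [t for t in design.timepoints if t in set(sub["timepoint"])]
    participants = sorted(sub["participant"].unique())
    n = len(values.columns)

    cols: list[str] = ["(intercept)"]
    blocks = [np.ones((n, 1))]
    tp_pos: dict[str, int] = {}
    for t in timepoints[1:]:
        tp_pos[t] = len(cols)
        cols.append(f"timepoint[{t}]")
        blocks.append((sub["timepoint"] == t).to_numpy(dtype=float)[:, None])
    if block_participant:
        for p in participants[1:]:
            cols.append(f"participant[{p}]")
            blocks.append((sub["participant"] == p).to_numpy(float)[:, None])
    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via the QR residual diagonal (best effort)
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        aliased = [cols[j] for j in range(X.shape[1])
                   if j >= diag.size or diag[j] < 1e-8] or cols
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")

    pairs = CONTRAST_SCHEMES[contrast_scheme]
    names, C = [], []
    for i_b, i_a in pairs:
        if i_b >= len(timepoints) or i_a >= len(timepoints):
            continue
        t_b, t_a = timepoints[i_b], timepoints[i_a]
        row = np.zeros(X.shape[1])
        if t_b in tp_pos:
            row[tp_pos[t_b]] = 1.0
        if t_a in tp_pos:
            row[tp_pos[t_a]] = -1.0
        C.append(row)
        names.append(f"{t_b}-{t_a}")
    if not names:
        raise ValidationError("contrast scheme yields no estimable contrasts")
    C = np.vstack(C)

    Y = values.to_numpy(dtype=float).T  # samples x features
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # params x features
    resid = Y - X @ beta
    df_resid = n - X.shape[1]
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    s2 = (resid ** 2).sum(axis=0) / df_resid
    contrast_cov = C @ xtx_inv @ C.T
    coef = (C @ beta).T  # features x contrasts
    return LinearFits(
        coefficients=pd.DataFrame(coef, index=values.index, columns=names),
        s2=pd.Series(s2, index=values.index, name="s2"),
        df_residual=float(df_resid),
        stdev_unscaled=pd.Series(np.sqrt(np.diag(contrast_cov)), index=names),
        contrast_cov=contrast_cov,
        contrast_names=names,
    )


def trigamma_inverse(x: float) -> float:
    """Solve ``polygamma(1, y) == x`` for ``y > 0`` by Newton iteration."""
    if x <= 0:
        raise ValidationError("trigamma_inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(75):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-12 * y:
            break
    return y


@dataclass
class ModeratedStats:
    """Empirical-Bayes moderated statistics for a contrast set."""

    table: pd.DataFrame  # per feature: coef/t/p/adj_p per contrast, F, p, adj_p
    df_prior: float
    s2_prior: float
    s2_posterior: pd.Series
    df_residual: float
    contrast_names: list[str] = field(default_factory=list)

    @property
    def df_total(self) -> float:
        return self.df_residual + self.df_prior


def empirical_bayes_moderation(fits: LinearFits) -> ModeratedStats:
    """Shrink per-feature variances and compute moderated t and F.

    The prior ``(d0, s02)`` is estimated by moment matching on
    ``e = log s2 - digamma(d/2) + log(d/2)``: the excess variance of ``e``
    over ``trigamma(d/2)`` equals ``trigamma(d0/2)``, inverted numerically.
    Non-positive excess variance means the observed variances are no more
    dispersed than chi-square sampling alone explains, giving an infinite
    prior df (all posterior variances equal ``s02``). A huge excess
    (``d0 -> 0``) recovers the ordinary, unmoderated t.
    """
    s2 = fits.s2.to_numpy(dtype=float)
    if s2.size < 2:
        raise ValidationError("need >= 2 features to estimate the prior")
    d = fits.df_residual
    positive = np.maximum(s2, 1e-300)
    e = np.log(positive) - digamma(d / 2.0) + math.log(d / 2.0)
    e_bar = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(polygamma(1, d / 2.0))
    if excess > 1e-12:
        d0 = 2.0 * trigamma_inverse(excess)
        s02 = math.exp(e_bar + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(e_bar)

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    coef = fits.coefficients.to_numpy(dtype=float)
    names = fits.contrast_names
    table = pd.DataFrame(index=fits.coefficients.index)
    t_dist = stats.norm if math.isinf(df_total) else stats.t(df_total)
    for j, name in enumerate(names):
        se = np.sqrt(s2_post) * fits.stdev_unscaled.iloc[j]
        t = coef[:, j] / se
        p = 2.0 * t_dist.sf(np.abs(t))
        table[f"coef[{name}]"] = coef[:, j]
        table[f"t[{name}]"] = t
        table[f"p[{name}]"] = p
        table[f"adj_p[{name}]"] = adjust_bh(p)

    # moderated F over the contrast set
    vinv = np.linalg.inv(fits.contrast_cov)
    r = len(names)
    quad = np.einsum("gi,ij,gj->g", coef, vinv, coef)
    F = quad / (r * s2_post)
    if math.isinf(df_total):
        p_f = stats.chi2.sf(r * F, r)
    else:
        p_f = stats.f.sf(F, r, df_total)
    table["F"] = F
    table["p[F]"] = p_f
    table["adj_p[F]"] = adjust_bh(p_f)

    return ModeratedStats(
        table=table,
        df_prior=d0,
        s2_prior=s02,
        s2_posterior=pd.Series(s2_post, index=fits.coefficients.index),
        df_residual=d,
        contrast_names=list(names),
    )


def adjust_bh(pvalues) -> np.ndarray | pd.Series:
    """Benjamini–Hochberg step-up adjustment.

    Sorts ascending, multiplies ``p_(i)`` by ``m/i``, takes the cumulative
    minimum from the largest rank down, caps at 1 and restores the input
    order. Missing p-values propagate as missing and are excluded from
    ``m``. Invariant to input order.
    """
    ser = isinstance(pvalues, pd.Series)
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        restored = np.empty(m)
        restored[order] = adj
        out[valid] = restored
    if ser:
        return pd.Series(out, index=pvalues.index)
    return out


@dataclass
class PermutationFdrResult:
    """Permutation-FDR q-values for one pairwise timepoint comparison."""

    table: pd.DataFrame  # per feature: t_obs, q
    comparison: tuple[str, str]
    n_permutations: int
    exhaustive: bool
    mode: str = "unpaired"


def _welch_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t for b - a; a, b are features x samples."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (mb - ma) / se


def pairwise_permutation_fdr(
    matrix,
    design: SampleDesign,
    comparison: tuple[str, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    mode: str = "unpaired",
) -> PermutationFdrResult:
    """Two-sample t-test between two timepoints with permutation FDR.

    ``comparison = (later, earlier)`` tests later - earlier. The null
    distribution comes from group-label permutations (unpaired Welch t) or
    within-participant sign flips (paired one-sample t on differences).
    Relabelings are enumerated exhaustively when there are at most
    ``20 * n_perm`` of them, otherwise ``n_perm`` distinct relabelings are
    sampled without replacement.

    ``FDR(c) = E_perm[#{|t_null| >= c}] / max(1, #{|t_obs| >= c})`` and each
    feature's q-value is the minimum FDR over thresholds at or below its own
    |t|, clipped to [0, 1] (step-down monotonisation).
    """
    if mode not in {"unpaired", "paired"}:
        raise ValidationError("mode must be 'unpaired' or 'paired'")
    values = _as_frame(matrix)
    if values.isna().any().any():
        raise ValidationError("matrix contains missing values; impute first")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    later, earlier = comparison
    tp = design.timepoint_of().reindex(values.columns)
    cols_a = values.columns[(tp == earlier).to_numpy()]
    cols_b = values.columns[(tp == later).to_numpy()]
    if len(cols_a) < 3 or len(cols_b) < 3:
        raise ValidationError("need >= 3 samples per group")

    if mode == "unpaired":
        pool = values[cols_a.append(cols_b)].to_numpy(dtype=float)
        na, nb = len(cols_a), len(cols_b)
        n = na + nb
        t_obs = _welch_t(pool[:, :na], pool[:, na:])
        n_distinct = math.comb(n, nb)
        exhaustive = n_distinct <= 20 * n_perm
        if exhaustive:
            relabelings = list(itertools.combinations(range(n), nb))
        else:
            chosen: set[tuple[int, ...]] = set()
            while len(chosen) < n_perm:
                pick = tuple(sorted(rng.choice(n, size=nb, replace=False)))
                chosen.add(pick)
            relabelings = sorted(chosen)
        null_ts = []
        idx_all = np.arange(n)
        for comb in relabelings:
            b_idx = np.asarray(comb)
            a_idx = np.setdiff1d(idx_all, b_idx, assume_unique=True)
            null_ts.append(_welch_t(pool[:, a_idx], pool[:, b_idx]))
    else:
        part = design.participant_of().reindex(values.columns)
        by_a = {part[c]: c for c in cols_a}
        by_b = {part[c]: c for c in cols_b}
        shared = sorted(set(by_a) & set(by_b))
        if len(shared) < 3:
            raise ValidationError("need >= 3 complete participant pairs")
        diffs = np.column_stack([
            values[by_b[p]].to_numpy(float) - values[by_a[p]].to_numpy(float)
            for p in shared
        ])
        npairs = diffs.shape[1]

        def paired_t(signs: np.ndarray) -> np.ndarray:
            d = diffs * signs[None, :]
            return d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(npairs))

        t_obs = paired_t(np.ones(npairs))
        n_distinct = 2 ** npairs
        exhaustive = n_distinct <= 20 * n_perm
        if exhaustive:
            sign_sets = [np.array(s) for s in
                         itertools.product((1.0, -1.0), repeat=npairs)]
        else:
            chosen = set()
            while len(chosen) < n_perm:
                chosen.add(tuple(rng.choice([1.0, -1.0], size=npairs)))
            sign_sets = [np.array(s) for s in sorted(chosen)]
        null_ts = [paired_t(s) for s in sign_sets]

    n_used = len(null_ts)
    null_abs = np.sort(np.abs(np.concatenate(null_ts)))
    abs_obs = np.abs(t_obs)
    order = np.argsort(-abs_obs, kind="stable")  # descending |t|
    thresholds = abs_obs[order]
    n_obs_ge = np.arange(1, thresholds.size + 1)
    n_null_ge = null_abs.size - np.searchsorted(null_abs, thresholds,
                                                side="left")
    fdr = (n_null_ge / n_used) / np.maximum(1, n_obs_ge)
    # q at rank i = min FDR over thresholds <= threshold_i (ranks >= i)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    table = pd.DataFrame({"t": t_obs, "q": q}, index=values.index)
    return PermutationFdrResult(
        table=table, comparison=comparison, n_permutations=n_used,
        exhaustive=exhaustive, mode=mode,
    )


def differential_features(
    stats_result: ModeratedStats,
    perm: PermutationFdrResult | dict | None,
    alpha_global: float = 0.01,
    alpha_pairwise: float = 0.05,
) -> dict[str, set[str]]:
    """Two-tier differential feature sets.

    The *global* set contains features whose BH-adjusted moderated-F p-value
    is below ``alpha_global``. Each per-comparison set contains features with
    permutation q below ``alpha_pairwise`` **and** membership in the global
    set (the conservative intersection).
    """
    for alpha in (alpha_global, alpha_pairwise):
        if not 0.0 < alpha <= 1.0:
            raise ValidationError("alpha must be in (0, 1]")
    adj = stats_result.table["adj_p[F]"]
    global_set = set(adj.index[(adj < alpha_global).to_numpy()])
    sets: dict[str, set[str]] = {"global": global_set}
    if perm is None:
        perm_map: dict[str, PermutationFdrResult] = {}
    elif isinstance(perm, PermutationFdrResult):
        perm_map = {f"{perm.comparison[0]}-{perm.comparison[1]}": perm}
    else:
        perm_map = dict(perm)
    for name, res in perm_map.items():
        below = set(res.table.index[(res.table["q"] < alpha_pairwise).to_numpy()])
        sets[name] = below & global_set
    return sets
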