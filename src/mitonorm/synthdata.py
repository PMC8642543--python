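"""Synthetic multi-omics cohort generator with recorded ground truth.

The generator emulates the statistical structure of label-free proteomics and
targeted lipidomics performed on mitochondria-enriched fractions from a
repeated-measures training study:

* a *global mitochondrial-content multiplier* ``c_t`` per timepoint that
  scales every mitochondrial feature,
* an *equal-protein-loading closure* that rescales each sample column to a
  constant total — the mechanism that turns a content change into an apparent
  per-protein abundance change (the enrichment artefact the normalisation
  chain is designed to remove),
* *feature-specific deviations* ``delta[g, t]`` (log2) from the global trend,
  organised into effect classes (e.g. a six-class structure mimicking
  divergent pathway prioritisation),
* mean–variance-dependent measurement noise (multiplicative log-normal plus
  non-negative additive background),
* intensity-dependent left-censored (MNAR) missingness plus a small MCAR
  floor, and
* a lipidome in which the cardiolipin (CL) class tracks the content
  multiplier while other classes do not.

Every latent quantity is returned in a :class:`SyntheticTruth` so that
downstream stages can be scored for recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .containers import (
    KNOWN_MITO,
    NOT_MITO,
    TIMEPOINTS,
    AnnotationTable,
    IntensityMatrix,
    LipidMatrix,
    SampleDesign,
    ValidationError,
)

__all__ = [
    "CohortConfig",
    "EffectClass",
    "MissingnessModel",
    "NoiseModel",
    "SyntheticTruth",
    "apply_missingness",
    "expected_mpe",
    "generate_cohort",
    "six_cluster_effects",
    "two_group_effects",
]

#: Default group-mean MPE trajectory targeted by the calibrated content
#: multipliers, percent at BL/PN/PH/PR.
DEFAULT_TARGET_MPE: tuple[float, ...] = (24.5, 31.5, 39.3, 34.5)

_LIPID_CLASS_VOCAB = ("PC", "PE", "TG", "SM", "PI", "PS", "DG", "CE", "LPC", "PG")

# Fixed offsets for the per-component RNG streams (seeded from config.seed).
_STREAM = {
    "features": 1,
    "participants": 2,
    "protein_noise": 3,
    "lipids": 4,
    "protein_missing": 5,
    "lipid_missing": 6,
    "enrichment": 7,
    "effects": 8,
}


@dataclass(frozen=True)
class EffectClass:
    """A class of mitochondrial features sharing a true deviation profile.

    ``fraction`` is the fraction of mitochondrial features assigned to the
    class; ``delta`` is the per-timepoint true log2 deviation from the global
    content trend, re-anchored so the first timepoint is 0.
    """

    name: str
    fraction: float
    delta: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValidationError(f"effect fraction {self.fraction} outside [0,1]")

    def anchored_delta(self, n_timepoints: int) -> np.ndarray:
        d = np.asarray(self.delta, dtype=float)
        if d.shape != (n_timepoints,):
            raise ValidationError(
                f"effect class {self.name!r}: delta length {d.size} != "
                f"{n_timepoints} timepoints"
            )
        return d - d[0]


@dataclass(frozen=True)
class NoiseModel:
    """Two-component measurement noise: y = x * exp(eps_m) + |eps_a|.

    ``cv`` is the sd of the multiplicative log-normal component (natural-log
    scale, so approximately the coefficient of variation); ``sd_additive`` is
    the sd of the additive background on the raw intensity scale, truncated
    at zero (half-normal). Together they produce the mean–variance dependence
    that the variance-stabilising transform is designed to remove.
    """

    cv: float = 0.2
    sd_additive: float = 2e4

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sd_additive < 0:
            raise ValidationError("noise parameters must be non-negative")

    @property
    def silent(self) -> bool:
        return self.cv == 0.0 and self.sd_additive == 0.0


@dataclass(frozen=True)
class MissingnessModel:
    """Left-censored (MNAR) + completely-at-random (MCAR) missingness.

    The MNAR location ``tau_s`` is set per sample at the ``tau_quantile``
    quantile of that sample's log2 intensities; ``gamma`` is the logistic
    scale in log2 units; ``mcar_rate`` is an intensity-independent floor.
    """

    tau_quantile: float = 0.05
    gamma: float = 0.4
    mcar_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValidationError("MNAR scale gamma must be > 0")
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValidationError("mcar_rate must be in [0,1)")
        if not 0.0 <= self.tau_quantile < 1.0:
            raise ValidationError("tau_quantile must be in [0,1)")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    The defaults define the reference study conditions: 10 participants,
    four timepoints, 1500 quantified proteins of which 40% are mitochondrial,
    content multipliers calibrated to a group-mean MPE trajectory of
    24.5/31.5/39.3/34.5 percent, and no feature-specific effects
    (pure content change).
    """

    n_participants: int = 10
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_features: int = 1500
    mito_fraction: float = 0.40
    content_multiplier: tuple[float, ...] | None = None
    target_mpe: tuple[float, ...] = DEFAULT_TARGET_MPE
    effect_spec: tuple[EffectClass, ...] = ()
    baseline_log2_mean: float = 25.0
    baseline_log2_sd: float = 2.5
    participant_sd: float = 0.10
    enrichment_sd: float = 0.10
    noise: NoiseModel = field(default_factory=NoiseModel)
    missingness: MissingnessModel | None = field(default_factory=MissingnessModel)
    n_lipid_species: int = 300
    cl_fraction: float = 0.10
    lipid_log2_mean: float = 10.0
    lipid_log2_sd: float = 2.0
    lipid_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValidationError("n_participants must be >= 2")
        if not 0.0 < self.mito_fraction < 1.0:
            raise ValidationError("mito_fraction must be in (0,1)")
        if not 0.0 < self.cl_fraction < 1.0:
            raise ValidationError("cl_fraction must be in (0,1)")
        if self.content_multiplier is not None:
            c = np.asarray(self.content_multiplier, dtype=float)
            if c.shape != (len(self.timepoints),):
                raise ValidationError(
                    "content_multiplier length must match timepoints"
                )
            if (c <= 0).any():
                raise ValidationError("content multipliers must be > 0")
        else:
            t = np.asarray(self.target_mpe, dtype=float)
            if t.shape != (len(self.timepoints),):
                raise ValidationError("target_mpe length must match timepoints")
            if ((t <= 0) | (t >= 100)).any():
                raise ValidationError("target MPE values must be in (0,100)")
        total = sum(ec.fraction for ec in self.effect_spec)
        if total > 1.0 + 1e-12:
            raise ValidationError(
                f"effect class fractions sum to {total:.3f} > 1"
            )

    # -- (de)serialisation -------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["effect_spec"] = [dataclasses.asdict(ec) for ec in self.effect_spec]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("effect_spec"):
            d["effect_spec"] = tuple(
                EffectClass(
                    name=e["name"],
                    fraction=e["fraction"],
                    delta=tuple(e["delta"]),
                )
                for e in d["effect_spec"]
            )
        else:
            d["effect_spec"] = ()
        if d.get("noise") is not None:
            d["noise"] = NoiseModel(**d["noise"])
        if d.get("missingness") is not None:
            d["missingness"] = MissingnessModel(**d["missingness"])
        for key in ("timepoints", "target_mpe", "content_multiplier"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Latent quantities behind a generated cohort, for recovery scoring."""

    content_multiplier: pd.Series  # timepoint -> c_t actually used
    delta: pd.DataFrame  # features x timepoints, true log2 deviations
    is_mitochondrial: pd.Series  # feature -> bool
    effect_class: pd.Series  # feature -> class name ("stoichiometric" if none)
    realised_mpe: pd.Series  # proteomics sample -> percent, pre-missingness
    mito_mass_ratio: float  # baseline mito/non-mito summed-intensity ratio
    missingness: dict = field(default_factory=dict)  # tau per sample, gamma, mcar

    def true_positive_features(self) -> set[str]:
        """Features with any non-zero true deviation."""
        nonzero = (self.delta.abs() > 1e-12).any(axis=1)
        return set(self.delta.index[nonzero])


def expected_mpe(content_multiplier: float, mito_mass_ratio: float) -> float:
    """Closed-form MPE (percent) for a noise-free, delta-free cohort.

    With ``R`` the realised baseline ratio of summed mitochondrial to summed
    non-mitochondrial intensity and ``c`` the content multiplier,
    ``MPE = 100 * R*c / (R*c + 1)``. The equal-loading closure rescales both
    sums identically, so it drops out of the ratio.
    """
    rc = mito_mass_ratio * content_multiplier
    return 100.0 * rc / (rc + 1.0)


def six_cluster_effects(fraction_per_class: float = 0.04,
                        amplitude: float = 2.0) -> tuple[EffectClass, ...]:
    """Six effect classes with distinct timepoint profiles.

    The shapes mimic divergent pathway prioritisation: sustained late
    up/down regulation (translation- and OXPHOS-like), a mid-intervention
    peak or dip (TCA/FAO-like transients), and phase-alternating responses.
    Their mean-centred profiles form an orthogonal +/- design (pairwise
    correlation 0 or -1), so the classes are maximally separated after
    per-feature z-scoring — as befits classes that are meant to be
    recoverable by clustering.
    """
    a = amplitude
    shapes = {
        "late_up": (0.0, 0.0, a, a),
        "late_down": (0.0, 0.0, -a, -a),
        "mid_peak": (0.0, a, a, 0.0),
        "mid_dip": (0.0, -a, -a, 0.0),
        "alternating_up": (0.0, a, 0.0, a),
        "alternating_down": (0.0, -a, 0.0, -a),
    }
    return tuple(
        EffectClass(name, fraction_per_class, delta)
        for name, delta in shapes.items()
    )


def two_group_effects(n_up: int = 30, n_down: int = 30, n_mito: int = 600,
                      amplitude: float = 1.0) -> tuple[EffectClass, ...]:
    """Balanced up/down effect classes with |delta| = `amplitude` at every
    post-baseline timepoint; fractions sized so that `n_up` + `n_down`
    mitochondrial features carry an effect."""
    a = amplitude
    return (
        EffectClass("shifted_up", n_up / n_mito, (0.0, a, a, a)),
        EffectClass("shifted_down", n_down / n_mito, (0.0, -a, -a, -a)),
    )


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAM[stream]])


def generate_cohort(
    config: CohortConfig,
) -> tuple[IntensityMatrix, LipidMatrix, AnnotationTable, SampleDesign, SyntheticTruth]:
    """Generate one synthetic cohort.

    Returns the protein intensity matrix (post-closure, post-missingness),
    the lipid concentration matrix, the mitochondrial annotation, the sample
    design covering both omics layers, and the ground truth.

    The protein signal for feature ``g`` in sample ``s = (participant p,
    timepoint t)`` is ``base_g * c_t**mito_g * 2**(delta[g,t] + u[g,p])``
    followed by measurement noise, a per-sample rescaling to a constant
    column total (equal protein loaded), and missingness.
    """
    cfg = config
    n_t = len(cfg.timepoints)

    # --- features ---------------------------------------------------------
    rng_f = _rng(cfg.seed, "features")
    feature_ids = pd.Index([f"PROT{i:04d}" for i in range(cfg.n_features)],
                           name="feature")
    base_log2 = rng_f.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd,
                             cfg.n_features)
    base = np.exp2(base_log2)
    n_mito = int(round(cfg.n_features * cfg.mito_fraction))
    if n_mito == 0 or n_mito == cfg.n_features:
        raise ValidationError("mito_fraction leaves no features in one class")
    order = rng_f.permutation(cfg.n_features)
    mito_idx = np.sort(order[:n_mito])
    is_mito = np.zeros(cfg.n_features, dtype=bool)
    is_mito[mito_idx] = True

    # --- effect classes ---------------------------------------------------
    rng_e = _rng(cfg.seed, "effects")
    delta = np.zeros((cfg.n_features, n_t))
    effect_class = np.full(cfg.n_features, "stoichiometric", dtype=object)
    assignable = rng_e.permutation(mito_idx)
    cursor = 0
    for ec in cfg.effect_spec:
        n_class = int(round(ec.fraction * n_mito))
        chosen = assignable[cursor:cursor + n_class]
        cursor += n_class
        delta[chosen, :] = ec.anchored_delta(n_t)
        effect_class[chosen] = ec.name
    effect_class[~is_mito] = "non_mitochondrial"

    # --- content multipliers ----------------------------------------------
    mass_ratio = float(base[is_mito].sum() / base[~is_mito].sum())
    if cfg.content_multiplier is not None:
        c = np.asarray(cfg.content_multiplier, dtype=float)
    else:
        target = np.asarray(cfg.target_mpe, dtype=float)
        odds = target / (100.0 - target)
        c = odds / mass_ratio  # expected_mpe(c_t, R) == target_t exactly

    # --- samples ----------------------------------------------------------
    participants = [f"P{i + 1:02d}" for i in range(cfg.n_participants)]
    prot_samples, lip_samples, design_rows = [], [], []
    for p in participants:
        for t in cfg.timepoints:
            prot_samples.append(f"{p}_{t}")
            design_rows.append((f"{p}_{t}", p, t, "proteomics"))
    for p in participants:
        for t in cfg.timepoints:
            lip_samples.append(f"{p}_{t}_lip")
            design_rows.append((f"{p}_{t}_lip", p, t, "lipidomics"))
    design = SampleDesign(
        pd.DataFrame(design_rows,
                     columns=["sample", "participant", "timepoint", "layer"]),
        cfg.timepoints,
    )

    rng_p = _rng(cfg.seed, "participants")
    part_effect = rng_p.normal(0.0, cfg.participant_sd,
                               (cfg.n_features, cfg.n_participants))

    rng_enr = _rng(cfg.seed, "enrichment")
    enr_prot = np.exp2(rng_enr.normal(0.0, cfg.enrichment_sd, len(prot_samples)))
    enr_lip = np.exp2(rng_enr.normal(0.0, cfg.enrichment_sd, len(lip_samples)))

    # --- protein signal ---------------------------------------------------
    tp_index = {t: j for j, t in enumerate(cfg.timepoints)}
    x = np.empty((cfg.n_features, len(prot_samples)))
    for s_i, sample in enumerate(prot_samples):
        p_i = s_i // n_t
        t_i = tp_index[sample.rsplit("_", 1)[1]]
        mult = np.where(is_mito, c[t_i] * enr_prot[s_i], 1.0)
        x[:, s_i] = base * mult * np.exp2(delta[:, t_i] + part_effect[:, p_i])

    rng_n = _rng(cfg.seed, "protein_noise")
    if not cfg.noise.silent:
        eps_m = rng_n.normal(0.0, cfg.noise.cv, x.shape) if cfg.noise.cv else 0.0
        eps_a = (np.abs(rng_n.normal(0.0, cfg.noise.sd_additive, x.shape))
                 if cfg.noise.sd_additive else 0.0)
        x = x * np.exp(eps_m) + eps_a

    # equal-loading closure: constant column total (baseline summed mass)
    total = base.sum()
    x *= total / x.sum(axis=0, keepdims=True)

    realised_mpe = pd.Series(
        100.0 * x[is_mito].sum(axis=0) / x.sum(axis=0),
        index=pd.Index(prot_samples, name="sample"),
        name="mpe_percent",
    )

    values = pd.DataFrame(x, index=feature_ids, columns=prot_samples)
    proteins = IntensityMatrix(
        values=values,
        lfq=values.copy(),
        flags=pd.DataFrame(
            False, index=feature_ids,
            columns=["reverse", "contaminant", "site_only"],
        ),
    )

    miss_info: dict = {"gamma": None, "mcar_rate": 0.0, "tau": {}}
    if cfg.missingness is not None:
        m = cfg.missingness
        log2x = np.log2(values.to_numpy())
        tau = pd.Series(
            np.quantile(log2x, m.tau_quantile, axis=0), index=values.columns
        )
        proteins = apply_missingness(
            proteins, tau=tau, gamma=m.gamma, mcar_rate=m.mcar_rate,
            seed=_rng(cfg.seed, "protein_missing"),
        )
        miss_info = {"gamma": m.gamma, "mcar_rate": m.mcar_rate,
                     "tau": tau.to_dict()}

    # --- annotation -------------------------------------------------------
    confidence = pd.Series(
        np.where(is_mito, KNOWN_MITO, NOT_MITO), index=feature_ids,
        name="confidence",
    )
    pathways = {
        f"pathway:{ec.name}": set(feature_ids[effect_class == ec.name])
        for ec in cfg.effect_spec
    }
    annotation = AnnotationTable(confidence=confidence, pathways=pathways)

    # --- lipids -----------------------------------------------------------
    rng_l = _rng(cfg.seed, "lipids")
    n_cl = int(round(cfg.n_lipid_species * cfg.cl_fraction))
    lipid_classes = np.array(
        ["CL"] * n_cl
        + list(rng_l.choice(_LIPID_CLASS_VOCAB, cfg.n_lipid_species - n_cl)),
        dtype=object,
    )
    lipid_ids = pd.Index(
        [f"{cls}({i:03d})" for i, cls in enumerate(lipid_classes)],
        name="species",
    )
    lbase = np.exp2(rng_l.normal(cfg.lipid_log2_mean, cfg.lipid_log2_sd,
                                 cfg.n_lipid_species))
    is_cl = lipid_classes == "CL"
    lx = np.empty((cfg.n_lipid_species, len(lip_samples)))
    for s_i, sample in enumerate(lip_samples):
        t_i = tp_index[sample.rsplit("_", 2)[1]]
        mult = np.where(is_cl, c[t_i] * enr_lip[s_i], 1.0)
        lx[:, s_i] = lbase * mult
    if cfg.lipid_cv > 0:
        lx = lx * np.exp(rng_l.normal(0.0, cfg.lipid_cv, lx.shape))
    lipids = LipidMatrix(
        values=pd.DataFrame(lx, index=lipid_ids, columns=lip_samples),
        classes=pd.Series(lipid_classes, index=lipid_ids, name="class"),
    )

    truth = SyntheticTruth(
        content_multiplier=pd.Series(c, index=list(cfg.timepoints), name="c"),
        delta=pd.DataFrame(delta, index=feature_ids,
                           columns=list(cfg.timepoints)),
        is_mitochondrial=pd.Series(is_mito, index=feature_ids, name="is_mito"),
        effect_class=pd.Series(effect_class, index=feature_ids, name="class"),
        realised_mpe=realised_mpe,
        mito_mass_ratio=mass_ratio,
        missingness=miss_info,
    )
    return proteins, lipids, annotation, design, truth


def apply_missingness(
    matrix: IntensityMatrix,
    tau,
    gamma: float,
    mcar_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> IntensityMatrix:
    """Mask entries of a complete matrix with left-censored + MCAR missingness.

    Each value ``x`` in sample ``s`` is masked with probability
    ``logistic((tau_s - log2 x) / gamma) + mcar_rate``, capped at 1.

    Parameters
    ----------
    tau
        MNAR location per sample in log2-intensity units: a scalar, or a
        mapping / Series keyed by sample id. ``-inf`` disables MNAR masking.
    gamma
        Logistic scale in log2 units; must be > 0 (use a small value for a
        near-step censor at ``tau``).
    """
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    if not 0.0 <= mcar_rate <= 1.0:
        raise ValidationError("mcar_rate must be in [0,1]")
    if matrix.values.isna().any().any():
        raise ValidationError("apply_missingness expects a complete matrix")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = matrix.values.to_numpy(dtype=float)
    if np.isscalar(tau) or isinstance(tau, (int, float)):
        tau_vec = np.full(x.shape[1], float(tau))
    else:
        tau_ser = pd.Series(tau).reindex(matrix.samples)
        if tau_ser.isna().any():
            missing = tau_ser.index[tau_ser.isna()].tolist()
            raise ValidationError(f"tau missing for sample(s): {missing}")
        tau_vec = tau_ser.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        z = (tau_vec[None, :] - np.log2(x)) / gamma
    p = np.clip(expit(z) + mcar_rate, 0.0, 1.0)
    mask = rng.random(x.shape) < p
    masked = matrix.values.where(~mask)
    return IntensityMatrix(
        values=masked,
        lfq=None if matrix.lfq is None else matrix.lfq.where(~mask),
        flags=matrix.flags,
        annotation=matrix.annotation,
    )
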