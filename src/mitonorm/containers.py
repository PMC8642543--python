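"""In-memory data model shared across the pipeline.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`.
Features are rows, samples are columns, and missing intensities are encoded
explicitly as NaN — never as 0 (the on-disk protein-group dialect uses 0 for
"not quantified"; ingestion converts on read, writers convert back).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mitonorm")

#: Canonical ordered biopsy timepoints: baseline, post normal-volume,
#: post high-volume, post reduced-volume training.
TIMEPOINTS: tuple[str, ...] = ("BL", "PN", "PH", "PR")

#: Canonical mitochondrial-annotation confidence vocabulary.
KNOWN_MITO = "Known Mitochondrial"
PREDICTED_MITO = "Predicted Mitochondrial"
NOT_MITO = "none"
CONFIDENCE_LEVELS: tuple[str, ...] = (KNOWN_MITO, PREDICTED_MITO, NOT_MITO)

LAYERS: tuple[str, ...] = ("proteomics", "lipidomics")


class ValidationError(ValueError):
    """Raised when an input table violates the data-model invariants."""


@dataclass
class SampleDesign:
    """Maps each sample to (participant, timepoint, omics layer).

    Parameters
    ----------
    table
        DataFrame with columns ``sample``, ``participant``, ``timepoint``,
        ``layer``, one row per sample.
    timepoints
        Ordered timepoint labels; defaults to BL < PN < PH < PR.
    """

    table: pd.DataFrame
    timepoints: tuple[str, ...] = TIMEPOINTS

    def __post_init__(self) -> None:
        required = {"sample", "participant", "timepoint", "layer"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"design table missing columns: {sorted(missing)}")
        self.table = self.table.reset_index(drop=True).copy()
        bad_tp = set(self.table["timepoint"]) - set(self.timepoints)
        if bad_tp:
            raise ValidationError(f"malformed timepoint label(s): {sorted(bad_tp)}")
        bad_layer = set(self.table["layer"]) - set(LAYERS)
        if bad_layer:
            raise ValidationError(f"unknown layer(s): {sorted(bad_layer)}")
        if self.table["sample"].duplicated().any():
            dups = self.table.loc[self.table["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        key = self.table[["participant", "timepoint", "layer"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                "duplicate (participant, timepoint, layer): "
                f"({dup['participant']}, {dup['timepoint']}, {dup['layer']})"
            )

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    def for_layer(self, layer: str) -> "SampleDesign":
        sub = self.table[self.table["layer"] == layer]
        if sub.empty:
            raise ValidationError(f"no samples for layer {layer!r}")
        return SampleDesign(sub, self.timepoints)

    def timepoint_of(self) -> pd.Series:
        """Sample id -> timepoint label."""
        return self.table.set_index("sample")["timepoint"]

    def participant_of(self) -> pd.Series:
        return self.table.set_index("sample")["participant"]

    def samples_at(self, timepoint: str, layer: str | None = None) -> list[str]:
        sub = self.table[self.table["timepoint"] == timepoint]
        if layer is not None:
            sub = sub[sub["layer"] == layer]
        return sub["sample"].tolist()


@dataclass
class AnnotationTable:
    """Feature id -> mitochondrial-annotation confidence, plus optional
    pathway memberships (pathway id -> set of feature ids)."""

    confidence: pd.Series
    pathways: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.confidence.index.duplicated().any():
            dups = self.confidence.index[self.confidence.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature id(s) in annotation: {dups}")
        bad = set(self.confidence.unique()) - set(CONFIDENCE_LEVELS)
        if bad:
            raise ValidationError(
                f"unknown confidence level(s): {sorted(bad)}; "
                f"expected one of {CONFIDENCE_LEVELS}"
            )

    def levels_for(self, level: str) -> set[str]:
        """Feature ids annotated at `level` ("Known Mitochondrial",
        "Known+Predicted", or any single vocabulary entry)."""
        if level == "Known+Predicted":
            wanted = {KNOWN_MITO, PREDICTED_MITO}
        else:
            if level not in CONFIDENCE_LEVELS:
                raise ValidationError(f"unknown confidence level {level!r}")
            wanted = {level}
        mask = self.confidence.isin(wanted)
        return set(self.confidence.index[mask])


@dataclass
class IntensityMatrix:
    """Features x samples raw-intensity matrix.

    ``values`` holds non-negative raw intensities with NaN for missing.
    ``lfq`` optionally holds the parallel LFQ-normalised intensities.
    ``flags`` holds the per-feature marker booleans (reverse / contaminant /
    site-only) — normally all False after ingestion, which drops them.
    ``annotation`` is the per-feature confidence level after joining with an
    :class:`AnnotationTable` (NOT_MITO when absent from the annotation).
    """

    values: pd.DataFrame
    lfq: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None
    annotation: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature id(s): {dups}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample columns")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("negative intensities are not allowed")
        if (arr[np.isfinite(arr)] == 0).any():
            raise ValidationError(
                "zero intensities found; encode missing values as NaN"
            )

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def observed(self) -> pd.DataFrame:
        """Boolean mask of quantified entries."""
        return self.values.notna()

    def with_annotation(self, annotation: AnnotationTable) -> "IntensityMatrix":
        """Join the annotation; features absent from it become non-mitochondrial."""
        conf = annotation.confidence.reindex(self.features).fillna(NOT_MITO)
        return IntensityMatrix(self.values, self.lfq, self.flags, conf)

    def subset(self, feature_ids) -> "IntensityMatrix":
        idx = self.features.intersection(pd.Index(feature_ids))
        idx = self.features[self.features.isin(set(idx))]  # preserve order
        return IntensityMatrix(
            self.values.loc[idx],
            None if self.lfq is None else self.lfq.loc[idx],
            None if self.flags is None else self.flags.loc[idx],
            None if self.annotation is None else self.annotation.loc[idx],
        )


@dataclass
class LipidMatrix:
    """Lipid species x samples concentration matrix with per-species class labels."""

    values: pd.DataFrame
    classes: pd.Series  # species id -> lipid class label, e.g. "CL", "PC"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate lipid species ids")
        missing = self.values.index.difference(self.classes.index)
        if len(missing):
            raise ValidationError(
                f"species without a class label: {missing.tolist()[:5]}"
            )
        self.classes = self.classes.reindex(self.values.index)
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("negative concentrations are not allowed")

    @property
    def species(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def class_members(self, lipid_class: str) -> pd.Index:
        return self.species[self.classes == lipid_class]


@dataclass
class MPEProfile:
    """Per-sample mitochondrial protein enrichment, in percent of summed raw
    intensity attributable to annotated mitochondrial proteins."""

    percent: pd.Series  # sample id -> MPE in (0, 100]
    level: str = KNOWN_MITO
    intensity_column: str = "raw"

    def group_means(self, design: SampleDesign) -> pd.Series:
        """Group-mean MPE per timepoint, in the design's timepoint order."""
        tp = design.timepoint_of().reindex(self.percent.index)
        means = self.percent.groupby(tp).mean()
        return means.reindex(list(design.timepoints)).dropna()


@dataclass
class NormalisedMatrix:
    """Feature x sample matrix on the calibrated glog2 scale.

    ``params`` has one row per sample with the fitted affine coefficients
    (offset ``a``, scale ``b``); ``imputed`` marks entries filled in by
    left-censored imputation; ``diagnostics`` carries the fit metadata.
    """

    values: pd.DataFrame
    params: pd.DataFrame | None = None
    imputed: pd.DataFrame | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )

    @property
    def complete(self) -> bool:
        return not self.values.isna().any().any()
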