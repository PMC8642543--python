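"""Readers and writers for the external table formats.

The protein table follows the label-free "proteinGroups" TSV dialect: one row
per protein group, per-sample ``Intensity <sample>`` and ``LFQ intensity
<sample>`` columns, and ``+``-marked ``Reverse`` / ``Potential contaminant`` /
``Only identified by site`` columns. In that dialect an intensity of 0 means
"not quantified"; ingestion converts zeros to explicit missing values and
never alters any other number. All readers accept gzip-compressed files
(pandas infers compression from the filename).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    CONFIDENCE_LEVELS,
    NOT_MITO,
    AnnotationTable,
    IntensityMatrix,
    LipidMatrix,
    SampleDesign,
    ValidationError,
)

logger = logging.getLogger("mitonorm")

#: Dialect marker columns and the flags they map to.
MARKER_COLUMNS = {
    "Only identified by site": "site_only",
    "Reverse": "reverse",
    "Potential contaminant": "contaminant",
}

#: Default per-sample column prefixes; configurable because dialect headers
#: vary between search-engine versions.
DEFAULT_PREFIXES = {"raw": "Intensity ", "lfq": "LFQ intensity "}

GENE_COLUMN = "Gene names"
ID_COLUMN = "Protein IDs"


def read_design(path) -> SampleDesign:
    """Read a sample-design CSV (columns sample, participant, timepoint, layer)."""
    return SampleDesign(pd.read_csv(path, dtype=str))


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, index=False)


def _canonical_confidence(label: str) -> str:
    """Normalise a confidence label to the canonical vocabulary,
    case-insensitively (e.g. 'known mitochondrial' -> 'Known Mitochondrial')."""
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return NOT_MITO
    text = str(label).strip()
    for canonical in CONFIDENCE_LEVELS:
        if text.lower() == canonical.lower():
            return canonical
    raise ValidationError(
        f"unknown confidence label {label!r}; expected one of {CONFIDENCE_LEVELS}"
    )


def read_annotation(path) -> AnnotationTable:
    """Read a mitochondrial-annotation CSV (columns feature, confidence,
    optional pathway). Unknown feature ids are kept: the annotation defines
    an outer universe that matrices are joined against later."""
    df = pd.read_csv(path, dtype=str)
    required = {"feature", "confidence"}
    if missing := required - set(df.columns):
        raise ValidationError(f"annotation missing columns: {sorted(missing)}")
    conf = pd.Series(
        [_canonical_confidence(v) for v in df["confidence"]],
        index=pd.Index(df["feature"], name="feature"),
        name="confidence",
    )
    pathways: dict[str, set[str]] = {}
    if "pathway" in df.columns:
        for pathway, grp in df.dropna(subset=["pathway"]).groupby("pathway"):
            for pw in str(pathway).split(";"):
                pathways.setdefault(pw, set()).update(grp["feature"])
    return AnnotationTable(confidence=conf, pathways=pathways)


def write_annotation(annotation: AnnotationTable, path) -> None:
    rows = annotation.confidence.rename_axis("feature").reset_index()
    inverted: dict[str, list[str]] = {}
    for pw, members in annotation.pathways.items():
        for m in members:
            inverted.setdefault(m, []).append(pw)
    rows["pathway"] = [
        ";".join(sorted(inverted.get(f, []))) or np.nan for f in rows["feature"]
    ]
    rows.to_csv(path, index=False)


def read_protein_table(
    path,
    design: SampleDesign,
    prefixes: dict[str, str] | None = None,
) -> IntensityMatrix:
    """Read a protein-group TSV into an :class:`IntensityMatrix`.

    Rows flagged in any of the three marker columns are removed (counts
    logged); zeros become missing; the feature key is the leading entry of
    the gene-name field, falling back to the protein-group id (logged when
    the fallback is used).
    """
    prefixes = prefixes or DEFAULT_PREFIXES
    df = pd.read_csv(path, sep="\t", dtype=str)
    samples = design.for_layer("proteomics").samples

    raw_cols = {s: f"{prefixes['raw']}{s}" for s in samples}
    for s, col in raw_cols.items():
        if col not in df.columns:
            raise ValidationError(f"missing sample column {col!r} in {path}")
    lfq_cols = {s: f"{prefixes['lfq']}{s}" for s in samples}
    have_lfq = all(c in df.columns for c in lfq_cols.values())

    # marker-flag removal, with per-flag provenance counts
    keep = pd.Series(True, index=df.index)
    removed = {}
    for col, flag in MARKER_COLUMNS.items():
        if col in df.columns:
            marked = df[col].fillna("").str.strip() == "+"
            removed[flag] = int((marked & keep).sum())
            keep &= ~marked
    df = df[keep]
    logger.info("flag removal: %s (retained %d rows)", removed, len(df))

    # feature identity: leading gene name, protein-group id as fallback
    ids = []
    n_fallback = 0
    for _, row in df.iterrows():
        gene = row.get(GENE_COLUMN)
        if isinstance(gene, str) and gene.strip():
            ids.append(gene.split(";")[0].strip())
        else:
            pid = str(row.get(ID_COLUMN, "")).split(";")[0].strip()
            ids.append(pid)
            n_fallback += 1
    if n_fallback:
        logger.info("feature id fallback to protein-group id for %d rows",
                    n_fallback)
    index = pd.Index(ids, name="feature")
    if index.duplicated().any():
        dups = index[index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature id(s): {dups}")

    def numeric(cols: dict[str, str]) -> pd.DataFrame:
        block = df[[cols[s] for s in samples]].apply(
            pd.to_numeric, errors="raise"
        )
        block.columns = samples
        block.index = index
        return block.where(block != 0)  # dialect: 0 == missing

    values = numeric(raw_cols)
    for s in samples:
        if values[s].isna().all():
            logger.warning("sample %s has no quantified values", s)
    flags = pd.DataFrame(
        False, index=index, columns=list(MARKER_COLUMNS.values())
    )
    return IntensityMatrix(
        values=values,
        lfq=numeric(lfq_cols) if have_lfq else None,
        flags=flags,
    )


def write_protein_table(matrix: IntensityMatrix, path,
                        prefixes: dict[str, str] | None = None) -> None:
    """Write an :class:`IntensityMatrix` in the protein-group TSV dialect
    (missing encoded as 0, marker columns emitted empty)."""
    prefixes = prefixes or DEFAULT_PREFIXES
    out = pd.DataFrame(index=matrix.features)
    out[ID_COLUMN] = matrix.features
    out[GENE_COLUMN] = matrix.features
    for col in MARKER_COLUMNS:
        out[col] = ""
    raw = matrix.values.fillna(0.0)
    for s in matrix.samples:
        out[f"{prefixes['raw']}{s}"] = raw[s].to_numpy()
    lfq = (matrix.lfq if matrix.lfq is not None else matrix.values).fillna(0.0)
    for s in matrix.samples:
        out[f"{prefixes['lfq']}{s}"] = lfq[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_lipid_table(path, design: SampleDesign) -> LipidMatrix:
    """Read a lipid-species CSV (columns species, class, then one column per
    sample). Species without a class label are rejected."""
    df = pd.read_csv(path)
    if missing := {"species", "class"} - set(df.columns):
        raise ValidationError(f"lipid table missing columns: {sorted(missing)}")
    if df["class"].isna().any() or (df["class"].astype(str).str.strip() == "").any():
        bad = df.loc[
            df["class"].isna()
            | (df["class"].astype(str).str.strip() == ""), "species"
        ].tolist()
        raise ValidationError(f"species without class: {bad}")
    samples = design.for_layer("lipidomics").samples
    for s in samples:
        if s not in df.columns:
            raise ValidationError(f"missing sample column {s!r} in {path}")
    values = df.set_index("species")[samples].apply(pd.to_numeric,
                                                    errors="raise")
    classes = df.set_index("species")["class"].astype(str)
    return LipidMatrix(values=values, classes=classes)


def write_lipid_table(lipids: LipidMatrix, path) -> None:
    out = lipids.values.copy()
    out.insert(0, "class", lipids.classes)
    out.rename_axis("species").reset_index().to_csv(path, index=False)
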