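"""Matrix I/O, scale transforms, condition splitting and differential labelling.

Expression matrices hold TPM values (transcripts per million, one row per
ENSEMBL transcript/gene), methylation matrices hold beta values (fraction of
methylated signal per CpG probe, in [0, 1]).  Both are converted to an
implication-friendly scale before network inference: ``log2(TPM + pseudocount)``
for expression and the logit-scale M-value ``log2(beta / (1 - beta))`` for
methylation.

Condition groups (e.g. samples bearing a broad chromosome-20 copy-number gain
vs disomic samples) are described by a sample-info table mapping sample id to
group label, and a comparison table shaped like a limma model matrix: one row
per group, one column per contrast, entries in {-1, 0, +1} where +1 marks the
test side and -1 the reference side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

EXPRESSION = "expression"
METHYLATION = "methylation"
MODALITIES = (EXPRESSION, METHYLATION)

RAW = "raw"
LOG2TPM = "log2tpm"
MVALUE = "mvalue"
SCALES = (RAW, LOG2TPM, MVALUE)

#: positional classes of a CpG probe relative to its gene
REGION_CATEGORIES = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR")

OVER_T = "OVER_T"
DOWN_T = "DOWN_T"
NO_LABEL = "none"


class MatrixParseError(ValueError):
    """Raised for malformed matrix files (non-numeric cells, duplicate ids)."""


class DomainError(ValueError):
    """Raised when values fall outside the modality's admissible range."""


class ScaleStateError(RuntimeError):
    """Raised when a transform is applied on the wrong scale or modality."""


@dataclass
class FeatureMatrix:
    """A samples x features numeric matrix with feature metadata.

    ``values`` is indexed by sample id (rows) and feature id (columns).
    ``feature_meta`` is an optional table indexed by feature id with columns
    such as ``gene_id``, ``chromosome``, ``arm``, ``region_category``.
    """

    values: pd.DataFrame
    modality: str
    scale: str = RAW
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise MatrixParseError(f"duplicate sample id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise MatrixParseError(f"duplicate feature id {dup!r}")
        arr = self.values.to_numpy()
        if self.scale != RAW and not np.isfinite(arr).all():
            raise DomainError(f"non-finite values on scale {self.scale!r}")
        if self.modality == METHYLATION and self.scale == RAW:
            if np.nanmin(arr) < 0.0 or np.nanmax(arr) > 1.0:
                bad = np.unravel_index(
                    np.nanargmax(np.abs(arr - 0.5)), arr.shape
                )
                raise DomainError(
                    "beta value outside [0, 1] at feature "
                    f"{self.values.columns[bad[1]]!r}, sample "
                    f"{self.values.index[bad[0]]!r}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DELabel:
    """Differential expression/methylation call for one feature."""

    feature_id: str
    label: str  # OVER_T | DOWN_T | none
    log_fc: float
    adjusted_p: float


def load_matrix(path, modality: str, annotation: pd.DataFrame | None = None) -> FeatureMatrix:
    """Read a TSV matrix (rows = features, columns = samples) as raw values.

    The first column must hold feature ids, the header row sample ids.
    Non-numeric cells and duplicated feature ids are rejected with an error
    naming the offending row/column; methylation values must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise MatrixParseError(f"duplicate feature id {dup!r} in {path}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = df.index[bad.to_numpy().argmax()]
            raise MatrixParseError(
                f"non-numeric value {df.loc[row, col]!r} at feature {row!r}, "
                f"sample {col!r}"
            )
    values = df.T.astype(float)  # samples x features
    meta = None
    if annotation is not None:
        meta = annotation.reindex(values.columns)
    return FeatureMatrix(values=values, modality=modality, scale=RAW, feature_meta=meta)


def load_sample_info(path) -> pd.Series:
    """Read the sample-info table: columns (sample_id, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MatrixParseError("sample info needs columns (sample_id, group)")
    info = df.set_index(df.columns[0])[df.columns[1]]
    if info.isna().any() or (info.str.len() == 0).any():
        raise MatrixParseError("empty group label in sample info")
    return info


def load_comparison(path) -> pd.DataFrame:
    """Read the comparison table: rows = groups, columns = contrasts."""
    comp = pd.read_csv(path, sep="\t", index_col=0)
    validate_comparison(comp)
    return comp


def validate_comparison(comp: pd.DataFrame) -> None:
    vals = comp.to_numpy()
    if not np.isin(vals, (-1, 0, 1)).all():
        raise ValueError("comparison table entries must be in {-1, 0, +1}")
    for col in comp.columns:
        if not (comp[col] > 0).any() or not (comp[col] < 0).any():
            raise ValueError(
                f"contrast {col!r} needs at least one +1 and one -1 group"
            )


def load_annotation(path) -> pd.DataFrame:
    """Read a feature annotation table indexed by its first column."""
    return pd.read_csv(path, sep="\t", dtype=str).set_index("feature_id")


def log2_tpm(m: FeatureMatrix, pseudocount: float = 1.0) -> FeatureMatrix:
    """log2(TPM + pseudocount) transform of a raw expression matrix."""
    if m.modality != EXPRESSION or m.scale != RAW:
        raise ScaleStateError(
            f"log2_tpm needs raw expression input, got {m.modality}/{m.scale}"
        )
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    out = np.log2(m.values + pseudocount)
    return replace(m, values=out, scale=LOG2TPM)


def beta_to_m(m: FeatureMatrix, epsilon: float = 1e-6) -> FeatureMatrix:
    """Convert beta values to M-values: log2(beta / (1 - beta)).

    Betas are clipped to [epsilon, 1 - epsilon] so the M-value stays finite.
    """
    if m.modality != METHYLATION or m.scale != RAW:
        raise ScaleStateError(
            f"beta_to_m needs raw methylation input, got {m.modality}/{m.scale}"
        )
    b = m.values.clip(lower=epsilon, upper=1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    return replace(m, values=out, scale=MVALUE)


def m_to_beta(mvals):
    """Inverse of the M-value transform: beta = 2^M / (1 + 2^M)."""
    p = np.power(2.0, np.asarray(mvals, dtype=float))
    return p / (1.0 + p)


def split_groups(
    m: FeatureMatrix, info: pd.Series, comp: pd.DataFrame
) -> dict[str, tuple[FeatureMatrix, FeatureMatrix]]:
    """Split a matrix into per-contrast (test, reference) pairs.

    For each contrast column of ``comp``, samples whose group has entry +1 form
    the test matrix and those with -1 the reference matrix; sample order within
    groups follows the input matrix.  Samples listed in ``info`` but absent
    from the matrix are dropped with a warning; matrix samples missing from
    ``info`` are an error.
    """
    validate_comparison(comp)
    missing = [s for s in m.sample_ids if s not in info.index]
    if missing:
        raise ValueError(f"samples missing from sample info: {missing[:5]}")
    extra = [s for s in info.index if s not in m.values.index]
    if extra:
        log.warning("%d sample(s) in info absent from matrix; ignored", len(extra))
    groups = info.reindex(m.sample_ids)
    out: dict[str, tuple[FeatureMatrix, FeatureMatrix]] = {}
    for contrast in comp.columns:
        col = comp[contrast]
        absent = [g for g in col.index[col != 0] if g not in set(groups)]
        if absent:
            raise ValueError(
                f"contrast {contrast!r} references absent group(s) {absent}"
            )
        test_groups = set(col.index[col > 0])
        ref_groups = set(col.index[col < 0])
        test_ids = [s for s in m.sample_ids if groups[s] in test_groups]
        ref_ids = [s for s in m.sample_ids if groups[s] in ref_groups]
        if not test_ids or not ref_ids:
            raise ValueError(f"empty group after split for contrast {contrast!r}")
        out[contrast] = (
            replace(m, values=m.values.loc[test_ids]),
            replace(m, values=m.values.loc[ref_ids]),
        )
    return out


def label_differential(
    test: FeatureMatrix,
    ref: FeatureMatrix,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> list[DELabel]:
    """Per-feature Welch t-test with Benjamini-Hochberg adjustment.

    logFC is mean(test) - mean(ref) on the transformed scale.  A feature is
    labelled OVER_T when adjusted p <= alpha and logFC >= lfc_min (strictly
    positive), DOWN_T symmetrically; features with zero variance in both
    groups get p = 1 and no label.
    """
    if test.feature_ids != ref.feature_ids:
        raise ValueError("test and reference matrices must share feature ids")
    if test.n_samples < 2 or ref.n_samples < 2:
        raise ValueError("each group needs at least 2 samples")
    a = test.values.to_numpy()
    b = ref.values.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, equal_var=False, axis=0)
    p = np.asarray(p, dtype=float)
    flat = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    p[flat | np.isnan(p)] = 1.0
    adj = multipletests(p, method="fdr_bh")[1]
    logfc = a.mean(axis=0) - b.mean(axis=0)
    labels = []
    for fid, lfc, q in zip(test.feature_ids, logfc, adj):
        if q <= alpha and lfc >= lfc_min and lfc > 0:
            lab = OVER_T
        elif q <= alpha and lfc <= -lfc_min and lfc < 0:
            lab = DOWN_T
        else:
            lab = NO_LABEL
        labels.append(DELabel(fid, lab, float(lfc), float(q)))
    return labels
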