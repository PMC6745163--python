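"""Tissue-specificity scoring.

Samples are aggregated to per-tissue medians; RNAs whose median vector is
all-zero are dropped; each surviving RNA gets a Gini index over its
tissue-median vector and is classified as tissue-specific (>= 0.85 by
default), nonspecific (<= 0.15) or intermediate. A tissue-specific RNA is
assigned to the single tissue where its median expression is maximal.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedGiniError, ValidationError
from .expression_io import BIOTYPES, SampleExpressionMatrix, TissueRegistry

log = logging.getLogger(__name__)

CLASS_TISSUE_SPECIFIC = "tissue_specific"
CLASS_NONSPECIFIC = "nonspecific"
CLASS_INTERMEDIATE = "intermediate"
CLASS_LABELS = (CLASS_TISSUE_SPECIFIC, CLASS_NONSPECIFIC, CLASS_INTERMEDIATE)


@dataclass(frozen=True)
class SpecificityConfig:
    """Classification thresholds.

    ``ts_comparison`` selects whether the tissue-specific cut is inclusive
    (``">="``, default) or strict (``">"``).
    """

    ts_threshold: float = 0.85
    nonspecific_threshold: float = 0.15
    ts_comparison: str = ">="

    def __post_init__(self) -> None:
        if not (0.0 <= self.nonspecific_threshold < self.ts_threshold <= 1.0):
            raise ValidationError(
                "thresholds must satisfy 0 <= nonspecific < ts <= 1, got "
                f"{self.nonspecific_threshold} / {self.ts_threshold}"
            )
        if self.ts_comparison not in (">=", ">"):
            raise ValidationError("ts_comparison must be '>=' or '>'")


@dataclass(frozen=True)
class TissueMedianMatrix:
    """Per-(RNA, tissue) median expression with per-RNA biotypes."""

    values: pd.DataFrame  # rows = RNAs, columns = tissues
    biotype: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValidationError("need at least two tissues")
        if not self.biotype.index.equals(self.values.index):
            raise ValidationError("biotype index does not match RNA ids")
        arr = self.values.to_numpy()
        if arr.size and ((arr < 0).any() or not np.isfinite(arr).all()):
            raise ValidationError("median matrix must be finite and nonnegative")

    @property
    def rna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_rnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SpecificityCall:
    """Per-RNA score, class label, and (for TS calls only) the assigned tissue."""

    rna_id: str
    biotype: str
    gini: float
    class_label: str
    assigned_tissue: str | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValidationError(f"unknown class label {self.class_label!r}")
        if (self.class_label == CLASS_TISSUE_SPECIFIC) != (self.assigned_tissue is not None):
            raise ValidationError(
                "assigned_tissue must be present iff the call is tissue_specific"
            )


# ---------------------------------------------------------------------------
# Aggregation and filtering
# ---------------------------------------------------------------------------


def tissue_medians(
    matrix: SampleExpressionMatrix, registry: TissueRegistry | None = None
) -> TissueMedianMatrix:
    """Collapse samples to per-tissue medians (midpoint convention for
    even sample counts). Column order follows the registry."""
    registry = registry or TissueRegistry.from_matrix(matrix)
    cols = {}
    for tissue in registry.names:
        samples = matrix.tissue_samples(tissue)
        if not samples:
            raise ValidationError(f"tissue {tissue!r} has no samples")
        cols[tissue] = np.median(matrix.values[samples].to_numpy(dtype=float), axis=1)
    values = pd.DataFrame(cols, index=matrix.values.index)
    return TissueMedianMatrix(values=values, biotype=matrix.biotype.copy())


def drop_zero_median(tm: TissueMedianMatrix) -> TissueMedianMatrix:
    """Remove RNAs whose tissue-median vector is all zeros.

    A single nonzero tissue median is enough to keep an RNA — the maximally
    specific profiles must survive this filter.
    """
    arr = tm.values.to_numpy()
    keep_mask = (arr > 0).any(axis=1)
    removed = tm.biotype[~keep_mask]
    if len(removed):
        tally = Counter(removed)
        log.info(
            "drop_zero_median: removed %d RNAs (%s)",
            len(removed),
            ", ".join(f"{bt}={tally.get(bt, 0)}" for bt in BIOTYPES),
        )
    if not keep_mask.any():
        raise ValidationError("all RNAs have all-zero median vectors")
    return TissueMedianMatrix(
        values=tm.values.loc[keep_mask], biotype=tm.biotype.loc[keep_mask]
    )


def drop_zero_pooled_median(matrix: SampleExpressionMatrix) -> SampleExpressionMatrix:
    """Alternative pre-filter: remove RNAs whose median over all samples
    pooled (ignoring tissue) is zero. Stricter than :func:`drop_zero_median`
    on sparse profiles; offered behind config only."""
    med = np.median(matrix.values.to_numpy(dtype=float), axis=1)
    keep = list(matrix.values.index[med > 0])
    removed = matrix.n_rnas - len(keep)
    if removed:
        log.info("drop_zero_pooled_median: removed %d RNAs", removed)
    if not keep:
        raise ValidationError("all RNAs have zero pooled median")
    return matrix.subset_rnas(keep)


# ---------------------------------------------------------------------------
# Gini index
# ---------------------------------------------------------------------------


def _check_gini_input(x: np.ndarray) -> None:
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("gini_index needs a 1-D vector of length >= 2")
    if not np.isfinite(x).all():
        raise ValidationError("gini_index input must be finite")
    if (x < 0).any():
        raise ValidationError("gini_index input must be nonnegative")
    if not (x > 0).any():
        raise UndefinedGiniError("gini index is undefined for an all-zero vector")


def gini_index(x: Sequence[float]) -> float:
    """Gini index of a nonnegative vector.

    Sorts ascending into x', then returns
    ``(1/N) * (N + 1 - 2 * sum_i (N+1-i) x'_i / sum_i x'_i)``.
    0 for a uniform vector; (N-1)/N when a single entry is nonzero.
    """
    arr = np.asarray(x, dtype=float)
    _check_gini_input(arr)
    n = arr.size
    xs = np.sort(arr)
    weights = np.arange(n, 0, -1, dtype=float)  # N+1-i for i = 1..N
    gi = (n + 1 - 2.0 * (weights @ xs) / xs.sum()) / n
    # mathematically >= 0; clamp the float residue of uniform vectors
    return float(max(gi, 0.0))


def gini_matrix(values: pd.DataFrame) -> pd.Series:
    """Row-wise :func:`gini_index` over a median matrix (vectorised)."""
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValidationError("need at least two tissues")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValidationError("median matrix must be finite and nonnegative")
    sums = arr.sum(axis=1)
    if (sums == 0).any():
        bad = values.index[sums == 0][:5].tolist()
        raise UndefinedGiniError(f"all-zero rows (filter first): {bad}")
    n = arr.shape[1]
    xs = np.sort(arr, axis=1)
    weights = np.arange(n, 0, -1, dtype=float)
    gi = np.maximum((n + 1 - 2.0 * (xs @ weights) / sums) / n, 0.0)
    return pd.Series(gi, index=values.index, name="gini")


def gini_pairwise_oracle(x: Sequence[float]) -> float:
    """Mean-absolute-difference form of the Gini index:
    ``sum_ij |x_i - x_j| / (2 N^2 mean(x))``. Independent of
    :func:`gini_index`; intended for cross-checking it in tests."""
    arr = np.asarray(x, dtype=float)
    _check_gini_input(arr)
    n = arr.size
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += abs(arr[i] - arr[j])
    return float(total / (2.0 * n * n * arr.mean()))


# ---------------------------------------------------------------------------
# Classification and tissue assignment
# ---------------------------------------------------------------------------


def classify(gini: float, cfg: SpecificityConfig | None = None) -> str:
    """Map a Gini score to tissue_specific / nonspecific / intermediate."""
    cfg = cfg or SpecificityConfig()
    if not (0.0 <= gini <= 1.0):
        raise ValidationError(f"gini {gini} outside [0, 1]")
    is_ts = gini >= cfg.ts_threshold if cfg.ts_comparison == ">=" else gini > cfg.ts_threshold
    if is_ts:
        return CLASS_TISSUE_SPECIFIC
    if gini <= cfg.nonspecific_threshold:
        return CLASS_NONSPECIFIC
    return CLASS_INTERMEDIATE


def assign_tissue(row: Sequence[float], tissues: Sequence[str]) -> str:
    """Tissue of the maximal median; ties go to the earliest tissue in
    registry order with a logged warning."""
    arr = np.asarray(row, dtype=float)
    if len(arr) != len(tissues):
        raise ValidationError("row length does not match tissue count")
    if not (arr > 0).any():
        raise ValidationError("cannot assign a tissue for an all-zero row")
    top = int(np.argmax(arr))
    if int((arr == arr[top]).sum()) > 1:
        log.warning(
            "tie for maximal median; assigning first tissue %r in registry order",
            tissues[top],
        )
    return tissues[top]


def run_specificity(
    tm: TissueMedianMatrix, cfg: SpecificityConfig | None = None
) -> list[SpecificityCall]:
    """Score, classify and (for TS calls) tissue-assign every RNA."""
    cfg = cfg or SpecificityConfig()
    gi = gini_matrix(tm.values)
    arr = tm.values.to_numpy(dtype=float)
    argmax = arr.argmax(axis=1)
    tissues = tm.tissues
    calls: list[SpecificityCall] = []
    n_ties = 0
    for k, rna_id in enumerate(tm.rna_ids):
        label = classify(float(gi.iloc[k]), cfg)
        assigned = None
        if label == CLASS_TISSUE_SPECIFIC:
            top = int(argmax[k])
            if int((arr[k] == arr[k, top]).sum()) > 1:
                n_ties += 1
                log.debug("tie for maximal median on %r; using %r", rna_id, tissues[top])
            assigned = tissues[top]
        calls.append(
            SpecificityCall(
                rna_id=rna_id,
                biotype=str(tm.biotype.iloc[k]),
                gini=float(gi.iloc[k]),
                class_label=label,
                assigned_tissue=assigned,
            )
        )
    if n_ties:
        log.warning("%d TS-RNAs had tied maximal medians (registry-order tie-break)", n_ties)
    tally = Counter((c.biotype, c.class_label) for c in calls)
    for bt in BIOTYPES:
        log.info(
            "specificity[%s]: ts=%d nonspecific=%d intermediate=%d",
            bt,
            tally.get((bt, CLASS_TISSUE_SPECIFIC), 0),
            tally.get((bt, CLASS_NONSPECIFIC), 0),
            tally.get((bt, CLASS_INTERMEDIATE), 0),
        )
    return calls


# ---------------------------------------------------------------------------
# Tabulation helpers
# ---------------------------------------------------------------------------


def calls_to_frame(calls: Iterable[SpecificityCall]) -> pd.DataFrame:
    """Calls as a tidy frame (rna_id, biotype, gini, class, assigned_tissue)."""
    rows = [
        {
            "rna_id": c.rna_id,
            "biotype": c.biotype,
            "gini": c.gini,
            "class": c.class_label,
            "assigned_tissue": c.assigned_tissue if c.assigned_tissue is not None else "",
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=["rna_id", "biotype", "gini", "class", "assigned_tissue"])


def class_tallies(calls: Iterable[SpecificityCall]) -> pd.DataFrame:
    """Biotype x class count table."""
    tally = Counter((c.biotype, c.class_label) for c in calls)
    return pd.DataFrame(
        {label: [tally.get((bt, label), 0) for bt in BIOTYPES] for label in CLASS_LABELS},
        index=list(BIOTYPES),
    )


def ts_tissue_tallies(
    calls: Iterable[SpecificityCall], tissues: Sequence[str]
) -> pd.DataFrame:
    """Tissue x biotype table of TS-RNA counts (per-tissue analogue of the
    printed TS distribution tables)."""
    tally = Counter(
        (c.assigned_tissue, c.biotype)
        for c in calls
        if c.class_label == CLASS_TISSUE_SPECIFIC
    )
    return pd.DataFrame(
        {bt: [tally.get((t, bt), 0) for t in tissues] for bt in BIOTYPES},
        index=list(tissues),
    )
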