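"""Synthetic multi-tissue expression datasets with planted ground truth.

The generator plants four RNA roles per biotype — housekeeping (uniform
baseline across tissues), tissue-specific (expressed only, or mostly, in
one home tissue), intermediate (expressed in about half the tissues), and
pseudogene-flagged — plus latent-factor co-expression between chosen
same-tissue, cross-biotype TS pairs.

Expression model: log-normal baseline per RNA with multiplicative
log-normal noise per sample. A planted pair with target correlation r
shares a standard-normal latent factor per sample, added on the log scale
with loading ``sqrt(|r|) * sigma`` (sigma = per-sample log noise sd), so
the log-scale correlation is exactly r in expectation and the raw-scale
correlation is close for small sigma.

The planted structure (roles, home tissues, edge list) is derived
deterministically from the parameters and does not depend on the seed;
only sampled values do.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import TissueNetwork
from .errors import ValidationError
from .expression_io import BIOTYPES, SampleExpressionMatrix
from .specificity import CLASS_LABELS, CLASS_TISSUE_SPECIFIC, SpecificityCall

log = logging.getLogger(__name__)

ROLE_HOUSEKEEPING = "housekeeping"
ROLE_TISSUE_SPECIFIC = "tissue_specific"
ROLE_INTERMEDIATE = "intermediate"
ROLE_PSEUDOGENE = "pseudogene"
ROLES = (ROLE_HOUSEKEEPING, ROLE_TISSUE_SPECIFIC, ROLE_INTERMEDIATE, ROLE_PSEUDOGENE)

_ROLE_CODES = {
    ROLE_HOUSEKEEPING: "hk",
    ROLE_TISSUE_SPECIFIC: "ts",
    ROLE_INTERMEDIATE: "mid",
    ROLE_PSEUDOGENE: "pg",
}

#: Expected classification for each planted role (pseudogenes are filtered
#: out before scoring, so they carry no expectation).
EXPECTED_CLASS = {
    ROLE_HOUSEKEEPING: "nonspecific",
    ROLE_TISSUE_SPECIFIC: "tissue_specific",
    ROLE_INTERMEDIATE: "intermediate",
}


def default_rna_counts() -> dict[str, dict[str, int]]:
    """Small default census (~60 RNAs) sized for fast test runs."""
    return {
        "miRNA": {"housekeeping": 3, "tissue_specific": 10, "intermediate": 3, "pseudogene": 0},
        "lncRNA": {"housekeeping": 3, "tissue_specific": 10, "intermediate": 3, "pseudogene": 0},
        "mRNA": {"housekeeping": 6, "tissue_specific": 10, "intermediate": 4, "pseudogene": 2},
    }


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic dataset generator.

    ``ts_mode='pure'`` zeroes tissue-specific RNAs outside their home
    tissue (their Gini is then (N-1)/N by construction); ``'leaky'`` keeps
    a baseline everywhere and multiplies the home tissue by
    ``ts_enrichment``. ``planted_edges`` holds (rna_id, rna_id, target r)
    triples between same-home, cross-biotype TS-RNAs; RNA ids are
    deterministic (e.g. ``mRNA-ts-000`` has home tissue ``tissue00``).
    """

    n_tissues: int = 10
    samples_per_tissue: int | tuple[int, ...] = 20
    rna_counts: Mapping[str, Mapping[str, int]] = field(default_factory=default_rna_counts)
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 0.5
    ts_mode: str = "pure"
    ts_enrichment: float = 32.0
    noise_cv: float = 0.1
    planted_edges: tuple[tuple[str, str, float], ...] = ()
    cross_class_only: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tissues < 2:
            raise ValidationError("n_tissues must be >= 2")
        if self.ts_mode not in ("pure", "leaky"):
            raise ValidationError("ts_mode must be 'pure' or 'leaky'")
        if self.ts_mode == "leaky" and self.ts_enrichment <= 1.0:
            raise ValidationError("ts_enrichment must exceed 1 in leaky mode")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be nonnegative")
        if self.planted_edges and self.noise_cv == 0:
            raise ValidationError("planted edges need noise_cv > 0 (loadings scale with it)")
        for bt, roles in self.rna_counts.items():
            if bt not in BIOTYPES:
                raise ValidationError(f"unknown biotype {bt!r} in rna_counts")
            for role, n in roles.items():
                if role not in ROLES:
                    raise ValidationError(f"unknown role {role!r} in rna_counts")
                if int(n) < 0:
                    raise ValidationError("RNA counts must be >= 0")
        for a, b, r in self.planted_edges:
            if not (0.0 < abs(float(r)) < 1.0):
                raise ValidationError(f"target |r| for edge ({a}, {b}) must be in (0, 1)")

    def samples_per_tissue_list(self) -> list[int]:
        if isinstance(self.samples_per_tissue, int):
            return [self.samples_per_tissue] * self.n_tissues
        spt = list(self.samples_per_tissue)
        if len(spt) != self.n_tissues:
            raise ValidationError("samples_per_tissue list length must equal n_tissues")
        if any(n < 1 for n in spt):
            raise ValidationError("each tissue needs >= 1 sample")
        return spt

    def tissue_names(self) -> list[str]:
        return [f"tissue{j:02d}" for j in range(self.n_tissues)]


@dataclass(frozen=True)
class PlantedRNA:
    rna_id: str
    biotype: str
    role: str
    home_tissue: str | None  # TS RNAs only
    expressed_tissues: tuple[str, ...]  # where the baseline is present


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted roles, home tissues and edges, plus the generating params."""

    rnas: tuple[PlantedRNA, ...]
    planted_edges: tuple[tuple[str, str, float], ...]
    params: GeneratorParams

    def role_of(self) -> dict[str, str]:
        return {r.rna_id: r.role for r in self.rnas}

    def home_of(self) -> dict[str, str | None]:
        return {r.rna_id: r.home_tissue for r in self.rnas}

    def by_role(self, role: str) -> list[PlantedRNA]:
        return [r for r in self.rnas if r.role == role]

    def edge_pairs(self) -> set[frozenset[str]]:
        return {frozenset({a, b}) for a, b, _ in self.planted_edges}


# ---------------------------------------------------------------------------
# Structure planning (seed-independent)
# ---------------------------------------------------------------------------


def _plan_structure(params: GeneratorParams) -> list[PlantedRNA]:
    tissues = params.tissue_names()
    n = params.n_tissues
    k_mid = max(1, n // 2)
    rnas: list[PlantedRNA] = []
    for bt in BIOTYPES:
        roles = params.rna_counts.get(bt, {})
        for role in ROLES:
            for k in range(int(roles.get(role, 0))):
                rna_id = f"{bt}-{_ROLE_CODES[role]}-{k:03d}"
                if role == ROLE_TISSUE_SPECIFIC:
                    home = tissues[k % n]
                    expressed = (home,)
                    if params.ts_mode == "leaky":
                        expressed = tuple(tissues)
                    rnas.append(PlantedRNA(rna_id, bt, role, home, expressed))
                elif role == ROLE_INTERMEDIATE:
                    subset = tuple(tissues[(k + j) % n] for j in range(k_mid))
                    rnas.append(PlantedRNA(rna_id, bt, role, None, subset))
                else:  # housekeeping or pseudogene: everywhere
                    rnas.append(PlantedRNA(rna_id, bt, role, None, tuple(tissues)))
    return rnas


def _validate_planted_edges(params: GeneratorParams, rnas: Sequence[PlantedRNA]) -> None:
    by_id = {r.rna_id: r for r in rnas}
    loading_budget: dict[str, float] = {}
    for a, b, r in params.planted_edges:
        for rna_id in (a, b):
            if rna_id not in by_id:
                raise ValidationError(f"planted edge references unknown RNA {rna_id!r}")
            if by_id[rna_id].role != ROLE_TISSUE_SPECIFIC:
                raise ValidationError(f"planted edge endpoint {rna_id!r} is not tissue-specific")
        if a == b:
            raise ValidationError("planted edge endpoints must differ")
        ra, rb = by_id[a], by_id[b]
        if ra.home_tissue != rb.home_tissue:
            raise ValidationError(
                f"planted edge ({a}, {b}) joins different home tissues"
            )
        if params.cross_class_only and ra.biotype == rb.biotype:
            raise ValidationError(
                f"planted edge ({a}, {b}) joins two {ra.biotype}s but "
                "cross_class_only truth was requested"
            )
        for rna_id in (a, b):
            loading_budget[rna_id] = loading_budget.get(rna_id, 0.0) + abs(float(r))
    over = [rna_id for rna_id, s in loading_budget.items() if s >= 1.0]
    if over:
        raise ValidationError(
            f"sum of planted |r| must stay below 1 per RNA; violated by {over}"
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate(params: GeneratorParams) -> tuple[SampleExpressionMatrix, SyntheticTruth]:
    """Draw a dataset and its ground truth. Deterministic under the seed."""
    rnas = _plan_structure(params)
    if not rnas:
        raise ValidationError("rna_counts produced no RNAs")
    _validate_planted_edges(params, rnas)

    tissues = params.tissue_names()
    spt = params.samples_per_tissue_list()
    sample_ids: list[str] = []
    sample_tissue: list[str] = []
    for tissue, count in zip(tissues, spt):
        for i in range(count):
            sample_ids.append(f"s-{tissue}-{i:03d}")
            sample_tissue.append(tissue)
    n_samples = len(sample_ids)
    m = len(rnas)

    sigma = math.sqrt(math.log(1.0 + params.noise_cv**2))
    rng = np.random.default_rng(params.seed)

    # Draw order is fixed: baselines, then latent factors, then noise.
    mu = rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=m)
    factors = rng.standard_normal((len(params.planted_edges), n_samples))
    eps = rng.standard_normal((m, n_samples))

    idx_of = {r.rna_id: k for k, r in enumerate(rnas)}
    loadings = np.zeros((m, len(params.planted_edges)))
    for e, (a, b, r) in enumerate(params.planted_edges):
        lam = math.sqrt(abs(float(r))) * sigma
        loadings[idx_of[a], e] = lam
        loadings[idx_of[b], e] = math.copysign(lam, float(r))

    # Residual noise keeps total log-variance at sigma^2 per RNA.
    eps_sd = np.sqrt(np.maximum(sigma**2 - (loadings**2).sum(axis=1), 0.0))

    log_x = mu[:, None] + loadings @ factors + eps_sd[:, None] * eps
    if params.ts_mode == "leaky":
        home_boost = math.log(params.ts_enrichment)
        tissue_arr = np.asarray(sample_tissue)
        for k, rna in enumerate(rnas):
            if rna.role == ROLE_TISSUE_SPECIFIC:
                log_x[k, tissue_arr == rna.home_tissue] += home_boost
    values = np.exp(log_x)

    # Zero out tissues outside each RNA's expressed set.
    tissue_arr = np.asarray(sample_tissue)
    for k, rna in enumerate(rnas):
        if len(rna.expressed_tissues) < len(tissues):
            mask = ~np.isin(tissue_arr, rna.expressed_tissues)
            values[k, mask] = 0.0

    frame = pd.DataFrame(values, index=[r.rna_id for r in rnas], columns=sample_ids)
    matrix = SampleExpressionMatrix(
        values=frame,
        biotype=pd.Series([r.biotype for r in rnas], index=frame.index),
        is_pseudogene=pd.Series(
            [r.role == ROLE_PSEUDOGENE for r in rnas], index=frame.index
        ),
        tissue_of_sample=pd.Series(sample_tissue, index=sample_ids),
    )
    truth = SyntheticTruth(
        rnas=tuple(rnas),
        planted_edges=tuple(
            (a, b, float(r)) for a, b, r in params.planted_edges
        ),
        params=params,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Dataset export (pipeline-compatible TSVs)
# ---------------------------------------------------------------------------


def write_dataset(
    matrix: SampleExpressionMatrix, truth: SyntheticTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the dataset in the formats the pipeline reads, plus the truth.

    Emits expression.tsv, samples.tsv, annotation.tsv, truth_roles.tsv,
    truth_edges.tsv and params.json; returns the paths keyed by name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
        "truth_roles": out / "truth_roles.tsv",
        "truth_edges": out / "truth_edges.tsv",
        "params": out / "params.json",
    }
    expr = matrix.values.copy()
    expr.index.name = "rna_id"
    # %.17g round-trips float64 exactly through read_csv
    expr.to_csv(paths["expression"], sep="\t", float_format="%.17g")
    pd.DataFrame(
        {"sample_id": matrix.sample_ids, "tissue": list(matrix.tissue_of_sample)}
    ).to_csv(paths["samples"], sep="\t", index=False)
    pd.DataFrame(
        {
            "rna_id": matrix.rna_ids,
            "biotype": list(matrix.biotype),
            "is_pseudogene": [str(bool(v)).lower() for v in matrix.is_pseudogene],
        }
    ).to_csv(paths["annotation"], sep="\t", index=False)
    pd.DataFrame(
        {
            "rna_id": [r.rna_id for r in truth.rnas],
            "biotype": [r.biotype for r in truth.rnas],
            "role": [r.role for r in truth.rnas],
            "home_tissue": [r.home_tissue or "" for r in truth.rnas],
        }
    ).to_csv(paths["truth_roles"], sep="\t", index=False)
    pd.DataFrame(
        truth.planted_edges, columns=["rna_a", "rna_b", "target_r"]
    ).to_csv(paths["truth_edges"], sep="\t", index=False)
    with open(paths["params"], "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(truth.params), fh, indent=2, default=list)
    return paths


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


def recovery_report(
    calls: Iterable[SpecificityCall],
    networks: Iterable[TissueNetwork],
    truth: SyntheticTruth,
) -> dict:
    """Compare pipeline output against the planted truth.

    Returns a dict with a (planted role x called class) confusion table,
    per-role recalls, tissue-assignment accuracy among recovered TS-RNAs,
    and planted-edge precision/recall.
    """
    calls = list(calls)
    role_of = truth.role_of()
    home_of = truth.home_of()
    unknown = [c.rna_id for c in calls if c.rna_id not in role_of]
    if unknown:
        raise ValidationError(f"calls reference RNAs absent from truth: {unknown[:5]}")

    confusion: dict[str, dict[str, int]] = {
        role: {label: 0 for label in CLASS_LABELS} for role in EXPECTED_CLASS
    }
    n_ts_called = 0
    n_ts_correct_tissue = 0
    for c in calls:
        role = role_of[c.rna_id]
        if role == ROLE_PSEUDOGENE:
            continue  # should have been filtered upstream
        confusion[role][c.class_label] += 1
        if role == ROLE_TISSUE_SPECIFIC and c.class_label == CLASS_TISSUE_SPECIFIC:
            n_ts_called += 1
            if c.assigned_tissue == home_of[c.rna_id]:
                n_ts_correct_tissue += 1

    recalls = {}
    for role, expected in EXPECTED_CLASS.items():
        total = sum(confusion[role].values())
        recalls[role] = confusion[role][expected] / total if total else float("nan")

    planted = truth.edge_pairs()
    found: set[frozenset[str]] = set()
    for net in networks:
        for e in net.edges:
            found.add(e.pair)
    tp = len(planted & found)
    precision = tp / len(found) if found else float("nan")
    recall = tp / len(planted) if planted else float("nan")

    return {
        "confusion": confusion,
        "recall_by_role": recalls,
        "ts_assignment_accuracy": (
            n_ts_correct_tissue / n_ts_called if n_ts_called else float("nan")
        ),
        "edge_precision": precision,
        "edge_recall": recall,
        "n_planted_edges": len(planted),
        "n_found_edges": len(found),
    }
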