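"""Per-tissue cross-biotype Pearson co-expression networks.

For each tissue, correlations are computed over that tissue's samples
between tissue-specific RNAs assigned to it; an undirected edge is kept
when |r| strictly exceeds the threshold (default 0.7). Only cross-class
pairs (miRNA-lncRNA, miRNA-mRNA, mRNA-lncRNA) are considered by default.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .expression_io import SampleExpressionMatrix
    from .specificity import SpecificityCall

log = logging.getLogger(__name__)

#: Canonical precedence used to order edge endpoints deterministically.
BIOTYPE_RANK = {"miRNA": 0, "lncRNA": 1, "mRNA": 2}

#: The three cross-class pairings considered by default.
CROSS_CLASS_PAIRS = frozenset(
    {
        frozenset({"miRNA", "lncRNA"}),
        frozenset({"miRNA", "mRNA"}),
        frozenset({"mRNA", "lncRNA"}),
    }
)

ALL_PAIRS = CROSS_CLASS_PAIRS | frozenset(
    {frozenset({bt}) for bt in BIOTYPE_RANK}
)


@dataclass(frozen=True)
class NetworkConfig:
    """Knobs for network construction.

    ``corr_threshold`` is applied strictly (an edge needs |r| > threshold).
    ``min_samples`` guards against degenerate correlations (r is always
    +/-1 at n = 2); tissues with fewer samples yield an empty network
    rather than an error.
    """

    corr_threshold: float = 0.7
    min_samples: int = 3
    allowed_pairs: frozenset[frozenset[str]] = CROSS_CLASS_PAIRS
    log_transform: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.corr_threshold < 1.0):
            raise ValidationError("corr_threshold must be in (0, 1)")
        if self.min_samples < 2:
            raise ValidationError("min_samples must be >= 2")
        for pair in self.allowed_pairs:
            if not pair <= set(BIOTYPE_RANK):
                raise ValidationError(f"unknown biotype in allowed pair {set(pair)}")


@dataclass(frozen=True)
class CoexpressionEdge:
    """Undirected co-expression link between two same-tissue TS-RNAs."""

    tissue: str
    rna_a: str
    rna_b: str
    biotype_a: str
    biotype_b: str
    pearson_r: float
    n_samples: int

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.rna_a, self.rna_b})


@dataclass(frozen=True)
class TissueNetwork:
    """Edge set of one tissue plus bookkeeping about its TS candidates.

    ``candidate_counts`` tallies the TS-RNAs assigned to the tissue per
    biotype (whether or not they ended up in an edge); node tallies count
    only RNAs incident to at least one edge.
    """

    tissue: str
    edges: tuple[CoexpressionEdge, ...]
    candidate_counts: dict[str, int] = field(default_factory=dict)
    n_samples: int = 0

    def __post_init__(self) -> None:
        pairs = [e.pair for e in self.edges]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate unordered pairs in network")
        for e in self.edges:
            if e.rna_a == e.rna_b:
                raise ValidationError(f"self-loop on {e.rna_a!r}")

    @property
    def interaction_count(self) -> int:
        return len(self.edges)

    def rna_ids(self) -> set[str]:
        """RNAs incident to at least one edge."""
        out: set[str] = set()
        for e in self.edges:
            out.add(e.rna_a)
            out.add(e.rna_b)
        return out

    def node_tallies(self) -> dict[str, int]:
        """Per-biotype count of RNAs incident to >= 1 edge."""
        seen: dict[str, str] = {}
        for e in self.edges:
            seen[e.rna_a] = e.biotype_a
            seen[e.rna_b] = e.biotype_b
        counts = Counter(seen.values())
        return {bt: counts.get(bt, 0) for bt in BIOTYPE_RANK}

    def has_candidate_pairs(self, allowed_pairs: frozenset[frozenset[str]]) -> bool:
        """True if the TS candidates admit at least one allowed pair."""
        for pair in allowed_pairs:
            members = sorted(pair)
            if len(members) == 1:
                if self.candidate_counts.get(members[0], 0) >= 2:
                    return True
            else:
                a, b = members
                if (
                    self.candidate_counts.get(a, 0) >= 1
                    and self.candidate_counts.get(b, 0) >= 1
                ):
                    return True
        return False


def canonical_endpoints(
    rna_a: str, biotype_a: str, rna_b: str, biotype_b: str
) -> tuple[str, str, str, str]:
    """Order two endpoints by biotype precedence, then id."""
    ka = (BIOTYPE_RANK[biotype_a], rna_a)
    kb = (BIOTYPE_RANK[biotype_b], rna_b)
    if kb < ka:
        return rna_b, biotype_b, rna_a, biotype_a
    return rna_a, biotype_a, rna_b, biotype_b


def pearson(
    a: Sequence[float], b: Sequence[float], *, min_samples: int = 3
) -> float | None:
    """Pearson product-moment correlation, or None when undefined.

    Undefined cases: fewer than ``min_samples`` observations (warned) or
    zero variance in either vector.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < min_samples:
        log.warning("pearson: %d < min_samples=%d observations", x.size, min_samples)
        return None
    xm = x - x.mean()
    ym = y - y.mean()
    denom = float(np.dot(xm, xm)) * float(np.dot(ym, ym))
    if denom == 0.0:
        return None
    # explicit dot-product form: exactly symmetric in (a, b)
    r = float(np.dot(xm, ym)) / np.sqrt(denom)
    return float(min(1.0, max(-1.0, r)))


def build_network(
    matrix: "SampleExpressionMatrix",
    calls: Iterable["SpecificityCall"],
    tissue: str,
    cfg: NetworkConfig | None = None,
) -> TissueNetwork:
    """Build the co-expression network of one tissue.

    Restricts to the tissue's samples and to TS calls assigned to the
    tissue, computes all pairwise Pearson correlations among them, and
    keeps allowed-pair edges with |r| strictly above the threshold.
    Zero-variance profiles and undersized tissues produce no edges.
    """
    from .specificity import CLASS_TISSUE_SPECIFIC  # local import, no cycle at load

    cfg = cfg or NetworkConfig()
    ts = [
        c
        for c in calls
        if c.class_label == CLASS_TISSUE_SPECIFIC and c.assigned_tissue == tissue
    ]
    candidate_counts = dict(Counter(c.biotype for c in ts))
    samples = matrix.tissue_samples(tissue)
    n = len(samples)

    if n < cfg.min_samples:
        log.warning(
            "tissue %r has %d samples (< min_samples=%d); empty network",
            tissue, n, cfg.min_samples,
        )
        return TissueNetwork(tissue, (), candidate_counts, n_samples=n)
    if len(ts) < 2:
        return TissueNetwork(tissue, (), candidate_counts, n_samples=n)

    ids = [c.rna_id for c in ts]
    biotypes = [c.biotype for c in ts]
    X = matrix.values.loc[ids, samples].to_numpy(dtype=float)
    if cfg.log_transform:
        X = np.log2(X + 1.0)
    sd = X.std(axis=1)
    valid = sd > 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)

    codes = np.array([BIOTYPE_RANK[bt] for bt in biotypes])
    allowed_code_pairs = {
        frozenset(BIOTYPE_RANK[bt] for bt in pair) for pair in cfg.allowed_pairs
    }

    edges: list[CoexpressionEdge] = []
    p = len(ids)
    iu, ju = np.triu_indices(p, k=1)
    strong = np.abs(R[iu, ju]) > cfg.corr_threshold
    both_valid = valid[iu] & valid[ju]
    for i, j in zip(iu[strong & both_valid], ju[strong & both_valid]):
        if frozenset({int(codes[i]), int(codes[j])}) not in allowed_code_pairs:
            continue
        a, bta, b, btb = canonical_endpoints(ids[i], biotypes[i], ids[j], biotypes[j])
        edges.append(
            CoexpressionEdge(
                tissue=tissue,
                rna_a=a,
                rna_b=b,
                biotype_a=bta,
                biotype_b=btb,
                pearson_r=float(R[i, j]),
                n_samples=n,
            )
        )
    edges.sort(
        key=lambda e: (BIOTYPE_RANK[e.biotype_a], e.rna_a, BIOTYPE_RANK[e.biotype_b], e.rna_b)
    )
    return TissueNetwork(tissue, tuple(edges), candidate_counts, n_samples=n)


def build_all_networks(
    matrix: "SampleExpressionMatrix",
    calls: Iterable["SpecificityCall"],
    tissues: Sequence[str],
    cfg: NetworkConfig | None = None,
) -> dict[str, TissueNetwork]:
    """Build one network per tissue, in the given tissue order."""
    calls = list(calls)
    return {t: build_network(matrix, calls, t, cfg) for t in tissues}


def count_interactions(
    networks: Iterable[TissueNetwork],
    allowed_pairs: frozenset[frozenset[str]] = CROSS_CLASS_PAIRS,
):
    """Summarise networks into a per-tissue table plus grand totals.

    A tissue whose TS candidates admit no allowed pair at all is reported
    with a missing interaction count (the printed tables use an em-dash
    there), which stays distinguishable from an explicit 0.

    Returns
    -------
    (pandas.DataFrame, dict)
        Table indexed by tissue with columns ``interactions`` (nullable
        int), per-biotype node tallies, and ``n_ts_candidates``; totals
        dict with ``total_interactions`` and ``total_network_rnas``
        (distinct RNAs appearing in any network edge).
    """
    import pandas as pd

    networks = list(networks)
    rows = []
    all_rnas: set[str] = set()
    for net in networks:
        tallies = net.node_tallies()
        all_rnas |= net.rna_ids()
        has_pairs = net.has_candidate_pairs(allowed_pairs)
        rows.append(
            {
                "tissue": net.tissue,
                "interactions": net.interaction_count if has_pairs else pd.NA,
                "nodes_miRNA": tallies["miRNA"],
                "nodes_lncRNA": tallies["lncRNA"],
                "nodes_mRNA": tallies["mRNA"],
                "n_ts_candidates": sum(net.candidate_counts.values()),
            }
        )
    table = pd.DataFrame(rows).set_index("tissue")
    table["interactions"] = table["interactions"].astype("Int64")
    totals = {
        "total_interactions": int(sum(net.interaction_count for net in networks)),
        "total_network_rnas": len(all_rnas),
    }
    return table, totals
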