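"""Readers and writers for expression matrices, sample maps, annotation
tables, packaged reference-table fixtures, and network edge lists.

The sample-level expression matrix is the raw input of the whole pipeline:
rows are RNAs (miRNA / lncRNA / mRNA, with a pseudogene flag), columns are
samples, and every sample maps to exactly one tissue.

Two input dialects are supported: plain TSV (``rna_id`` + one column per
sample) and GCT v1.2 (two extra header lines declaring dimensions, plus a
``Description`` column that is ignored).
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import BIOTYPE_RANK, CoexpressionEdge, TissueNetwork
from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

#: Recognised RNA classes, in canonical precedence order.
BIOTYPES = ("miRNA", "lncRNA", "mRNA")

#: The em-dash used by the printed reference tables for "no entry".
EM_DASH = "—"

_EDGE_COLUMNS = (
    "tissue",
    "rna_a",
    "biotype_a",
    "rna_b",
    "biotype_b",
    "pearson_r",
    "n_samples",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleExpressionMatrix:
    """Nonnegative sample-level expression with biotype and tissue labels.

    Parameters
    ----------
    values
        RNAs x samples frame of finite, nonnegative abundances
        (unit-agnostic: RPKM, TPM, ...).
    biotype
        Per-RNA label, one of :data:`BIOTYPES`; indexed like ``values``.
    is_pseudogene
        Per-RNA boolean flag; indexed like ``values``.
    tissue_of_sample
        Per-sample tissue label; indexed like ``values.columns``.
    """

    values: pd.DataFrame
    biotype: pd.Series
    is_pseudogene: pd.Series
    tissue_of_sample: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate RNA identifiers: {dupes[:5]}")
        if v.columns.has_duplicates:
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = v.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("expression values must be numeric")
            bad = ~np.isfinite(arr)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValidationError(
                    f"non-finite expression value at RNA {v.index[i]!r}, "
                    f"sample {v.columns[j]!r}"
                )
            neg = arr < 0
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise ValidationError(
                    f"negative expression value {arr[i, j]} at RNA "
                    f"{v.index[i]!r}, sample {v.columns[j]!r}"
                )
        for name, series in (
            ("biotype", self.biotype),
            ("is_pseudogene", self.is_pseudogene),
        ):
            if not series.index.equals(v.index):
                raise ValidationError(f"{name} index does not match RNA ids")
        unknown = set(self.biotype.unique()) - set(BIOTYPES)
        if unknown:
            raise ValidationError(f"unknown biotypes: {sorted(unknown)}")
        if not self.tissue_of_sample.index.equals(v.columns):
            raise ValidationError("tissue_of_sample index does not match sample ids")
        if self.tissue_of_sample.isna().any():
            missing = self.tissue_of_sample.index[self.tissue_of_sample.isna()]
            raise ValidationError(f"samples with no tissue: {list(missing[:5])}")

    # -- convenience views --------------------------------------------------

    @property
    def rna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_rnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tissues(self) -> list[str]:
        """Tissue labels in order of first appearance among samples."""
        return list(dict.fromkeys(self.tissue_of_sample))

    def tissue_samples(self, tissue: str) -> list[str]:
        """Sample ids belonging to *tissue* (matrix column order)."""
        mask = self.tissue_of_sample == tissue
        return list(self.tissue_of_sample.index[mask])

    def subset_rnas(self, ids: Sequence[str]) -> "SampleExpressionMatrix":
        """Restrict to the given RNAs (order preserved as given)."""
        ids = list(ids)
        return SampleExpressionMatrix(
            values=self.values.loc[ids],
            biotype=self.biotype.loc[ids],
            is_pseudogene=self.is_pseudogene.loc[ids],
            tissue_of_sample=self.tissue_of_sample,
        )

    def biotype_tally(self) -> dict[str, int]:
        counts = Counter(self.biotype)
        return {bt: counts.get(bt, 0) for bt in BIOTYPES}


@dataclass(frozen=True)
class TissueRegistry:
    """Ordered tissue labels with per-tissue sample counts."""

    names: tuple[str, ...]
    sample_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.names) < 2:
            raise ValidationError("a registry needs at least two tissues")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("tissue names must be unique")
        for name in self.names:
            n = self.sample_counts.get(name)
            if n is None or int(n) < 0:
                raise ValidationError(f"bad sample count for tissue {name!r}: {n}")

    @classmethod
    def from_matrix(cls, matrix: SampleExpressionMatrix) -> "TissueRegistry":
        counts = Counter(matrix.tissue_of_sample)
        return cls(names=tuple(matrix.tissues), sample_counts=dict(counts))

    def validate_against(self, matrix: SampleExpressionMatrix) -> None:
        """Check the registry tally against the matrix's sample->tissue map."""
        observed = Counter(matrix.tissue_of_sample)
        for name in self.names:
            if observed.get(name, 0) != int(self.sample_counts[name]):
                raise ValidationError(
                    f"registry count for {name!r} ({self.sample_counts[name]}) "
                    f"does not match matrix tally ({observed.get(name, 0)})"
                )
        extra = set(observed) - set(self.names)
        if extra:
            raise ValidationError(f"samples from unregistered tissues: {sorted(extra)}")

    @property
    def n_tissues(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class PaperTableFixture:
    """A packaged transcription of one printed per-tissue reference table.

    ``rows`` keeps the printed row order; a cell is an ``int`` (count),
    a tuple of identifiers (identifier-list tables), or ``None`` for a
    printed em-dash. Dashes stay distinguishable from zero on read-back
    and only collapse to 0 inside :meth:`cell_sum`.
    """

    table_id: str
    rows: tuple[tuple[str, object], ...]
    printed_total: int

    def cell(self, tissue: str) -> object:
        for name, value in self.rows:
            if name == tissue:
                return value
        raise KeyError(tissue)

    def numeric_cells(self) -> list[int]:
        """Per-row numeric values, skipping dashes; id lists count as lengths."""
        out: list[int] = []
        for _, value in self.rows:
            if value is None:
                continue
            out.append(len(value) if isinstance(value, tuple) else int(value))
        return out

    def cell_sum(self) -> int:
        """Re-added total over all rows, with dashes contributing 0."""
        return sum(self.numeric_cells())

    def max_cell(self) -> int:
        """Maximum per-row value, ignoring dash rows."""
        return max(self.numeric_cells())

    def identifiers(self) -> list[str]:
        """All identifiers enumerated across rows (id-list tables only)."""
        out: list[str] = []
        for _, value in self.rows:
            if isinstance(value, tuple):
                out.extend(value)
        return out

    @property
    def tissue_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.rows)


# ---------------------------------------------------------------------------
# Expression input
# ---------------------------------------------------------------------------


def read_sample_map(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (sample_id, tissue) into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"sample map {path} needs 2 columns (sample_id, tissue)")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "tissue"]
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in sample map")
    return df.set_index("sample_id")["tissue"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a 3-column TSV (rna_id, biotype, is_pseudogene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 3:
        raise ParseError(
            f"annotation {path} needs 3 columns (rna_id, biotype, is_pseudogene)"
        )
    df = df.iloc[:, :3]
    df.columns = ["rna_id", "biotype", "is_pseudogene"]
    if df["rna_id"].duplicated().any():
        raise ValidationError("duplicate RNA ids in annotation")
    flag = df["is_pseudogene"].str.strip().str.lower()
    ok = flag.isin({"true", "false", "1", "0"})
    if not ok.all():
        bad = df.loc[~ok, "is_pseudogene"].unique().tolist()
        raise ParseError(f"is_pseudogene must be true/false/1/0, got {bad[:5]}")
    df["is_pseudogene"] = flag.isin({"true", "1"})
    return df.set_index("rna_id")


def _read_values_tsv(path: str | Path) -> pd.DataFrame:
    # round_trip: pandas' default float parser can be off by one ulp
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    df.index.name = "rna_id"
    return df


def _read_values_gct(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}: expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ParseError(f"{path}: malformed GCT dimension line")
        try:
            n_rows, n_cols = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise ParseError(f"{path}: malformed GCT dimension line") from exc
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if "Description" in df.columns:
        df = df.drop(columns=["Description"])
    if df.shape != (n_rows, n_cols):
        raise ParseError(
            f"{path}: declared dimensions {n_rows}x{n_cols} do not match "
            f"parsed {df.shape[0]}x{df.shape[1]}"
        )
    df.index.name = "rna_id"
    return df


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    *,
    sample_map: str | Path | pd.Series,
    annotation: str | Path | pd.DataFrame,
    unknown_biotype: str = "error",
    missing: str = "error",
) -> SampleExpressionMatrix:
    """Read a sample-level expression matrix and validate it.

    Parameters
    ----------
    path
        Expression table; header row gives sample ids.
    format
        ``"tsv"`` or ``"gct"`` (v1.2 dialect).
    sample_map, annotation
        Companion tables (paths or pre-loaded objects).
    unknown_biotype
        ``"error"`` rejects RNAs absent from the annotation or with an
        unrecognised biotype; ``"drop"`` removes them with a log message.
    missing
        ``"error"`` (default) rejects missing cells; ``"zero"`` fills them
        with 0 and logs a warning.
    """
    if format == "tsv":
        df = _read_values_tsv(path)
    elif format == "gct":
        df = _read_values_gct(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'gct')")

    if df.isna().any().any():
        if missing == "zero":
            n_missing = int(df.isna().sum().sum())
            log.warning("filling %d missing expression cells with 0", n_missing)
            df = df.fillna(0.0)
        else:
            col = df.columns[df.isna().any()][0]
            row = df.index[df[col].isna()][0]
            raise ValidationError(
                f"missing expression value at RNA {row!r}, sample {col!r} "
                "(set missing='zero' to coerce)"
            )
    df = df.astype(float)

    tissues = sample_map if isinstance(sample_map, pd.Series) else read_sample_map(sample_map)
    ann = annotation if isinstance(annotation, pd.DataFrame) else read_annotation(annotation)

    unmapped = [s for s in df.columns if s not in tissues.index]
    if unmapped:
        raise ValidationError(f"samples with no tissue mapping: {unmapped[:5]}")

    known = ann.index[ann["biotype"].isin(BIOTYPES)]
    bad = [r for r in df.index if r not in set(known)]
    if bad:
        if unknown_biotype == "drop":
            log.info("dropping %d RNAs with unknown/missing biotype", len(bad))
            df = df.drop(index=bad)
        else:
            raise ValidationError(
                f"RNAs with unknown or unannotated biotype: {bad[:5]} "
                "(set unknown_biotype='drop' to remove)"
            )
    if df.shape[0] == 0:
        raise ValidationError("no annotated RNAs left after biotype routing")

    return SampleExpressionMatrix(
        values=df,
        biotype=ann["biotype"].reindex(df.index),
        is_pseudogene=ann["is_pseudogene"].reindex(df.index).astype(bool),
        tissue_of_sample=tissues.reindex(df.columns),
    )


def filter_pseudogenes(
    matrix: SampleExpressionMatrix, *, only_mrna: bool = False
) -> SampleExpressionMatrix:
    """Remove pseudogene-flagged RNAs; the input is left unmodified.

    By default the flag is honoured for every biotype; ``only_mrna=True``
    restricts the filter to mRNAs.
    """
    flagged = matrix.is_pseudogene.astype(bool)
    if only_mrna:
        flagged = flagged & (matrix.biotype == "mRNA")
    n_removed = int(flagged.sum())
    log.info("filter_pseudogenes: removing %d of %d RNAs", n_removed, matrix.n_rnas)
    keep = list(matrix.values.index[~flagged])
    if not keep:
        log.warning("filter_pseudogenes: all RNAs were flagged; matrix is empty")
    return SampleExpressionMatrix(
        values=matrix.values.loc[keep],
        biotype=matrix.biotype.loc[keep],
        is_pseudogene=matrix.is_pseudogene.loc[keep],
        tissue_of_sample=matrix.tissue_of_sample,
    )


# ---------------------------------------------------------------------------
# Packaged reference-table fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "T1": "table1_sample_counts.tsv",
    "T2": "table2_ts_mirnas.tsv",
    "T3": "table3_ts_lncrna_counts.tsv",
    "T4": "table4_ts_mrna_counts.tsv",
    "T5": "table5_interaction_counts.tsv",
}

#: Tables whose cells are identifier lists rather than counts.
_ID_LIST_TABLES = frozenset({"T2"})


def _parse_fixture_cell(raw: str, table_id: str) -> object:
    raw = raw.strip()
    if raw in {EM_DASH, "-", ""}:
        return None
    if table_id in _ID_LIST_TABLES:
        return tuple(part.strip() for part in raw.split(",") if part.strip())
    return int(raw)


def load_paper_table(table_id: str) -> PaperTableFixture:
    """Load one of the packaged per-tissue reference tables (T1..T5)."""
    tid = table_id.upper()
    if tid not in _FIXTURE_FILES:
        raise KeyError(f"unknown table id {table_id!r}; expected one of {sorted(_FIXTURE_FILES)}")
    text = (
        resources.files("tscoex").joinpath("fixtures", _FIXTURE_FILES[tid]).read_text(
            encoding="utf-8"
        )
    )
    printed_total: int | None = None
    rows: list[tuple[str, object]] = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            if key.strip() == "printed_total":
                printed_total = int(value.strip())
            continue
        tissue, _, cell = line.partition("\t")
        if tissue == "tissue":  # header row
            continue
        rows.append((tissue, _parse_fixture_cell(cell, tid)))
    if printed_total is None:
        raise ParseError(f"fixture for {tid} lacks a printed_total header")
    return PaperTableFixture(table_id=tid, rows=tuple(rows), printed_total=printed_total)


def load_selection_counts() -> pd.DataFrame:
    """Per-biotype RNA tallies before and after the input pre-filters,
    as printed in the source tables (indexed by biotype)."""
    text = (
        resources.files("tscoex")
        .joinpath("fixtures", "selection_counts.tsv")
        .read_text(encoding="utf-8")
    )
    records = []
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("biotype\t"):
            continue
        bt, initial, retained = line.split("\t")
        records.append((bt, int(initial), int(retained)))
    return pd.DataFrame(records, columns=["biotype", "initial", "retained"]).set_index(
        "biotype"
    )


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------


def write_edge_list(
    networks: TissueNetwork | Iterable[TissueNetwork], path: str | Path
) -> None:
    """Write one or more tissue networks as a canonical edge-list TSV.

    Columns: tissue, rna_a, biotype_a, rna_b, biotype_b, pearson_r,
    n_samples. Endpoint order inside a row follows biotype precedence
    miRNA < lncRNA < mRNA then lexicographic id; rows are sorted by
    (tissue, endpoints) so output is diff-stable. Floats are written with
    ``repr`` so a read-back reproduces them bit-for-bit.
    """
    if isinstance(networks, TissueNetwork):
        networks = [networks]
    rows = []
    for net in networks:
        for e in net.edges:
            rows.append(e)
    rows.sort(key=lambda e: (e.tissue, BIOTYPE_RANK[e.biotype_a], e.rna_a,
                             BIOTYPE_RANK[e.biotype_b], e.rna_b))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for e in rows:
            fh.write(
                f"{e.tissue}\t{e.rna_a}\t{e.biotype_a}\t{e.rna_b}\t"
                f"{e.biotype_b}\t{e.pearson_r!r}\t{e.n_samples}\n"
            )


def read_edge_list(path: str | Path) -> list[CoexpressionEdge]:
    """Read an edge-list TSV written by :func:`write_edge_list`."""
    edges: list[CoexpressionEdge] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(_EDGE_COLUMNS):
            raise ParseError(f"{path}: unexpected edge-list header {header}")
        for line in fh:
            if not line.strip():
                continue
            tissue, a, bta, b, btb, r, n = line.rstrip("\n").split("\t")
            edges.append(
                CoexpressionEdge(
                    tissue=tissue,
                    rna_a=a,
                    biotype_a=bta,
                    rna_b=b,
                    biotype_b=btb,
                    pearson_r=float(r),
                    n_samples=int(n),
                )
            )
    return edges


def write_graphml(network: TissueNetwork, path: str | Path) -> None:
    """Export a tissue network as GraphML (nodes carry biotype)."""
    import networkx as nx

    g = nx.Graph(tissue=network.tissue)
    for e in network.edges:
        g.add_node(e.rna_a, biotype=e.biotype_a)
        g.add_node(e.rna_b, biotype=e.biotype_b)
        g.add_edge(e.rna_a, e.rna_b, pearson_r=float(e.pearson_r), n_samples=e.n_samples)
    nx.write_graphml(g, path)
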