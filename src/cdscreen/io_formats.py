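"""Readers, writers, and validated containers for every on-disk format.

All formats are plain UTF-8 tab-separated text with '.' decimal:

* expression matrices as TSV (first column = row id, header = sample ids)
  or GCT 1.2;
* sample group annotations as two-column TSV (sample_id, group);
* probe annotations and ortholog maps as two-column TSV;
* drug-signature libraries as TSV/GCT (drugs x genes);
* STRING-like scored edge lists (node_a, node_b, combined_score);
* gene-set collections as GMT;
* ranked drug lists as TSV (rank, drug_id, score).

Loading validates invariants (unique ids, numeric cells, consistent
dimensions) and raises :class:`FormatError` with coordinates on failure.
Write/read round-trips reproduce matrices within 1e-12 and ids exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CONTROL = "control"
CASE = "case"


class FormatError(ValueError):
    """A file violated its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """A genes/probes x samples log-scale expression matrix with group labels.

    ``values`` is indexed by row id (probe or gene symbol) with sample ids
    as columns.  ``groups`` maps each sample id to ``"control"`` or
    ``"case"``; it may be ``None`` for a matrix loaded before its sample
    annotation is attached.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate row id {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression matrix contains non-finite values")
        if self.groups is not None:
            self.groups = self.groups.reindex(cols)
            if self.groups.isna().any():
                missing = self.groups.index[self.groups.isna()][0]
                raise FormatError(f"sample {missing!r} has no group label")
            bad = set(self.groups) - {CONTROL, CASE}
            if bad:
                raise FormatError(f"unknown group labels {sorted(bad)}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if self.groups is None:
            raise ValueError("study has no group labels attached")
        return list(self.groups.index[self.groups == group])

    def require_two_groups(self, min_per_group: int = 2) -> None:
        for g in (CONTROL, CASE):
            n = len(self.samples_in_group(g))
            if n < min_per_group:
                raise ValueError(
                    f"group {g!r} has {n} samples; >= {min_per_group} required"
                )


@dataclass
class ProbeAnnotation:
    """probe_id -> gene symbol; probes without a symbol map to ``None``."""

    mapping: dict[str, str | None]

    def __post_init__(self) -> None:
        for probe, sym in self.mapping.items():
            if sym is not None and (not isinstance(sym, str) or not sym):
                raise FormatError(f"probe {probe!r}: empty gene symbol")

    def symbol(self, probe: str) -> str | None:
        return self.mapping.get(probe)


@dataclass
class OrthologMap:
    """source (mouse) symbol -> target (human) symbol; many-to-one allowed."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for src, tgt in self.mapping.items():
            if not tgt:
                raise FormatError(f"ortholog map: empty target for {src!r}")


@dataclass
class SignatureLibrary:
    """Drug-perturbation signatures: drugs x genes matrix.

    NaN entries mark genes not measured for a drug; a drug whose defined
    entries are all zero is rejected at load time.
    """

    values: pd.DataFrame  # drugs x genes
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate drug ids in signature library")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate gene ids in signature library")
        arr = self.values.to_numpy(dtype=float)
        defined = ~np.isnan(arr)
        zero_rows = ~((arr != 0) & defined).any(axis=1)
        if zero_rows.any():
            drug = self.values.index[np.flatnonzero(zero_rows)[0]]
            raise FormatError(f"drug {drug!r} has an all-zero signature")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class EdgeList:
    """Undirected scored edges with STRING-style combined scores in [0, 1000].

    After loading, self-loops are dropped and duplicate undirected pairs are
    collapsed keeping the maximum score.
    """

    edges: pd.DataFrame  # columns node_a, node_b, combined_score

    def __post_init__(self) -> None:
        df = self.edges
        required = ["node_a", "node_b", "combined_score"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(f"edge list missing column(s) {missing}")
        scores = df["combined_score"]
        if len(df) and ((scores < 0) | (scores > 1000)).any():
            bad = scores[(scores < 0) | (scores > 1000)].iloc[0]
            raise FormatError(f"combined_score {bad} outside [0, 1000]")
        if len(df) and (df["node_a"] == df["node_b"]).any():
            raise FormatError("edge list contains self-loops after load")

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set[str]:
        return set(self.edges["node_a"]) | set(self.edges["node_b"])


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, member symbols)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _parse_matrix(
    rows: list[list[str]], sample_ids: list[str], path: Path, first_data_line: int
) -> pd.DataFrame:
    row_ids: list[str] = []
    data = np.empty((len(rows), len(sample_ids)), dtype=float)
    for i, fields in enumerate(rows):
        row_ids.append(fields[0])
        for j, cell in enumerate(fields[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{fields[0]!r}, column {sample_ids[j]!r}"
                ) from None
            if not math.isfinite(v):
                raise FormatError(
                    f"{path}: non-finite value at row {fields[0]!r}, "
                    f"column {sample_ids[j]!r}"
                )
            data[i, j] = v
    seen: set[str] = set()
    for rid in row_ids:
        if rid in seen:
            raise FormatError(f"{path}: duplicate row id {rid!r}")
        seen.add(rid)
    return pd.DataFrame(data, index=row_ids, columns=sample_ids)


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionStudy:
    """Load an expression matrix from TSV or GCT 1.2 (no group labels)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if format == "tsv":
        if not lines:
            raise FormatError(f"{path}: empty file")
        header = lines[0].split("\t")
        sample_ids = header[1:]
        rows = [ln.split("\t") for ln in lines[1:] if ln]
        for fields in rows:
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}: row {fields[0]!r} has {len(fields) - 1} values, "
                    f"expected {len(sample_ids)}"
                )
        values = _parse_matrix(rows, sample_ids, path, 1)
    elif format == "gct":
        if len(lines) < 3 or lines[0].strip() != "#1.2":
            raise FormatError(f"{path}: missing GCT '#1.2' version line")
        try:
            n_rows, n_cols = (int(x) for x in lines[1].split("\t")[:2])
        except ValueError:
            raise FormatError(f"{path}: malformed GCT dimensions line") from None
        header = lines[2].split("\t")
        if header[:2] != ["Name", "Description"]:
            raise FormatError(f"{path}: GCT header must start Name<TAB>Description")
        sample_ids = header[2:]
        data_lines = [ln for ln in lines[3:] if ln]
        if len(data_lines) != n_rows or len(sample_ids) != n_cols:
            raise FormatError(
                f"{path}: GCT dims line says {n_rows} x {n_cols}, found "
                f"{len(data_lines)} rows x {len(sample_ids)} samples"
            )
        rows = []
        for ln in data_lines:
            fields = ln.split("\t")
            if len(fields) != n_cols + 2:
                raise FormatError(f"{path}: GCT row {fields[0]!r} has wrong width")
            rows.append([fields[0]] + fields[2:])
        values = _parse_matrix(rows, sample_ids, path, 3)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    return ExpressionStudy(values=values)


def write_expression(
    study: ExpressionStudy, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    df = study.values
    if format == "tsv":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("row_id\t" + "\t".join(map(str, df.columns)) + "\n")
            for rid, row in zip(df.index, df.to_numpy()):
                fh.write(str(rid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    elif format == "gct":
        with path.open("w", encoding="utf-8") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(map(str, df.columns)) + "\n")
            for rid, row in zip(df.index, df.to_numpy()):
                fh.write(
                    f"{rid}\t{rid}\t" + "\t".join(repr(float(v)) for v in row) + "\n"
                )
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_sample_groups(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, group) -> Series mapping sample to group."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (sample_id, group)")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dup = df[sample_col][df[sample_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    return pd.Series(df[group_col].values, index=df[sample_col].values, name="group")


def write_sample_groups(groups: pd.Series, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sid, g in groups.items():
            fh.write(f"{sid}\t{g}\n")


def attach_groups(study: ExpressionStudy, groups: pd.Series) -> ExpressionStudy:
    """Return a new study with group labels attached and validated."""
    return ExpressionStudy(values=study.values, groups=groups)


# ---------------------------------------------------------------------------
# two-column maps
# ---------------------------------------------------------------------------

#: marker written for probes without a gene symbol
MISSING_SYMBOL = "NA"


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Two-column TSV (probe_id, gene_symbol); symbol 'NA' or '' = unmapped."""
    path = Path(path)
    mapping: dict[str, str | None] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln:
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields")
        probe, sym = fields[0], fields[1]
        if probe in mapping:
            raise FormatError(f"{path}:{lineno}: duplicate probe id {probe!r}")
        mapping[probe] = None if sym in ("", MISSING_SYMBOL) else sym
    return ProbeAnnotation(mapping=mapping)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("probe_id\tgene_symbol\n")
        for probe, sym in ann.mapping.items():
            fh.write(f"{probe}\t{sym if sym is not None else MISSING_SYMBOL}\n")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    path = Path(path)
    mapping: dict[str, str] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln:
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields")
        src, tgt = fields[0], fields[1]
        if src in mapping:
            raise FormatError(f"{path}:{lineno}: duplicate source symbol {src!r}")
        mapping[src] = tgt
    return OrthologMap(mapping=mapping)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("source_symbol\ttarget_symbol\n")
        for src, tgt in omap.mapping.items():
            fh.write(f"{src}\t{tgt}\n")


# ---------------------------------------------------------------------------
# signature libraries
# ---------------------------------------------------------------------------


def read_signature_library(path: str | Path, format: str = "tsv") -> SignatureLibrary:
    """Drugs x genes matrix TSV; empty or 'NA' cells mark unmeasured genes."""
    if format != "tsv":
        raise ValueError("signature libraries are read as TSV")
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric cell in library: {exc}") from None
    return SignatureLibrary(values=values)


def write_signature_library(
    lib: SignatureLibrary, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    df = lib.values
    if format != "tsv":
        raise ValueError("signature libraries are written as TSV")
    with path.open("w", encoding="utf-8") as fh:
        fh.write("drug_id\t" + "\t".join(map(str, df.columns)) + "\n")
        for rid, row in zip(df.index, df.to_numpy()):
            fh.write(str(rid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: name, description, members — tab-separated, one per line.

    Duplicate members within a set are deduplicated (first occurrence kept).
    """
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    for lineno, ln in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has < 3 fields")
        name, desc = fields[0], fields[1]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = tuple(dict.fromkeys(m for m in fields[2:] if m))
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write(name + "\t" + desc + "\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# scored edge lists
# ---------------------------------------------------------------------------


def _canonicalize_edges(df: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops, orient pairs (min, max), keep max score per pair."""
    df = df[df["node_a"] != df["node_b"]].copy()
    a = df["node_a"].astype(str).to_numpy()
    b = df["node_b"].astype(str).to_numpy()
    df["node_a"] = np.minimum(a, b)
    df["node_b"] = np.maximum(a, b)
    df = (
        df.groupby(["node_a", "node_b"], as_index=False, sort=True)["combined_score"]
        .max()
    )
    return df.reset_index(drop=True)


def read_edges(path: str | Path, score_min: int = 800) -> EdgeList:
    """Load a STRING-like edge TSV, keeping combined_score >= score_min.

    The threshold is inclusive.  Self-loops are dropped; duplicate
    undirected pairs collapse to a single edge with the maximum score.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"combined_score": "Int64"})
    required = ["node_a", "node_b", "combined_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[required].copy()
    df["combined_score"] = df["combined_score"].astype(int)
    if len(df) and (
        (df["combined_score"] < 0) | (df["combined_score"] > 1000)
    ).any():
        bad = df["combined_score"][
            (df["combined_score"] < 0) | (df["combined_score"] > 1000)
        ].iloc[0]
        raise FormatError(f"{path}: combined_score {bad} outside [0, 1000]")
    df = df[df["combined_score"] >= score_min]
    df = _canonicalize_edges(df)
    return EdgeList(edges=df)


def edge_list_from_records(
    records: Iterable[tuple[str, str, int]], score_min: int = 0
) -> EdgeList:
    """Build a validated EdgeList from in-memory (a, b, score) records."""
    df = pd.DataFrame(records, columns=["node_a", "node_b", "combined_score"])
    if len(df) and ((df["combined_score"] < 0) | (df["combined_score"] > 1000)).any():
        raise FormatError("combined_score outside [0, 1000]")
    df = df[df["combined_score"] >= score_min]
    return EdgeList(edges=_canonicalize_edges(df))


def write_edges(edges: EdgeList, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tcombined_score\n")
        for a, b, s in edges.edges.itertuples(index=False):
            fh.write(f"{a}\t{b}\t{s}\n")


# ---------------------------------------------------------------------------
# ranked lists
# ---------------------------------------------------------------------------


def write_ranked_list(ranked: pd.DataFrame, path: str | Path) -> None:
    """Write a ranked drug list as TSV (rank, drug_id, score).

    Rows are sorted by score descending, ties broken by ascending drug_id;
    ranks are re-derived 1-based so the file is self-consistent.
    """
    df = ranked.copy()
    for col in ("drug_id", "score"):
        if col not in df.columns:
            raise ValueError(f"ranked list missing column {col!r}")
    df = df.sort_values(
        ["score", "drug_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("rank\tdrug_id\tscore\n")
        for rank, drug, score in zip(df["rank"], df["drug_id"], df["score"]):
            fh.write(f"{rank}\t{drug}\t{float(score)!r}\n")


def read_ranked_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype={"drug_id": str})
    for col in ("rank", "drug_id", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# misc tables
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Deterministic TSV dump used for DEG, centrality, enrichment tables."""
    df.to_csv(Path(path), sep="\t", index=index_label is not None,
              index_label=index_label)


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=index_col)
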