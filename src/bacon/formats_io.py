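"""Tabular I/O for time-course expression tables, gold standards and edge rankings.

The time-series dialect follows the DREAM4 10-gene time-series layout: a
header ``Time\\t<gene1>\\t...`` followed by one row per time point.  Several
series from the same network may live in one file as blocks separated by a
single blank line (the header may be repeated per block), or in one file per
series.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "SeriesTable",
    "TimeSeriesSet",
    "GoldStandard",
    "EdgeScoreTable",
    "read_timeseries",
    "read_timeseries_multi",
    "write_timeseries",
    "read_gold_standard",
    "write_gold_standard",
    "read_edge_ranking",
    "write_edge_ranking",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular dialect."""


@dataclasses.dataclass
class SeriesTable:
    """One time-course experiment: expression of every gene at every time point.

    ``values`` is (n_genes, n_times); ``replicate_values`` holds optional
    technical replicates of identical shape.
    """

    gene_names: list[str]
    time_points: np.ndarray
    values: np.ndarray
    replicate_values: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.time_points = np.asarray(self.time_points, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_points.ndim != 1 or self.time_points.size < 2:
            raise FormatError("a series needs at least 2 time points")
        if np.any(np.diff(self.time_points) <= 0):
            raise FormatError("time points must be strictly increasing")
        g, t = len(self.gene_names), self.time_points.size
        if self.values.shape != (g, t):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"({g} genes, {t} time points)"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("missing or non-finite expression values")
        if self.replicate_values is not None:
            self.replicate_values = [np.asarray(r, dtype=float) for r in self.replicate_values]
            for r in self.replicate_values:
                if r.shape != (g, t) or not np.all(np.isfinite(r)):
                    raise FormatError("replicate matrix shape/values invalid")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_times(self) -> int:
        return int(self.time_points.size)

    @property
    def n_replicates(self) -> int:
        return 1 + (len(self.replicate_values) if self.replicate_values else 0)

    def all_replicates(self) -> list[np.ndarray]:
        """All observation matrices, primary first."""
        return [self.values] + list(self.replicate_values or [])


@dataclasses.dataclass
class TimeSeriesSet:
    """All observed series for one network; every series shares the gene list."""

    series: list[SeriesTable]
    network_id: str = ""

    def __post_init__(self) -> None:
        if not self.series:
            raise FormatError("a TimeSeriesSet needs at least one series")
        names = self.series[0].gene_names
        for i, s in enumerate(self.series[1:], start=2):
            if s.gene_names != names:
                raise FormatError(
                    f"series {i} gene names differ from series 1 "
                    f"(gene identifiers are case-sensitive and order matters)"
                )

    @property
    def gene_names(self) -> list[str]:
        return self.series[0].gene_names

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)


@dataclasses.dataclass
class GoldStandard:
    """Known true directed edges over a gene universe; absent pairs are negatives."""

    edges: set[tuple[str, str]]
    universe: list[str]

    def __post_init__(self) -> None:
        known = set(self.universe)
        if len(known) != len(self.universe):
            raise FormatError("duplicate gene names in universe")
        for u, v in self.edges:
            if u == v:
                raise FormatError(f"self-edge {u}->{v} is not allowed")
            if u not in known or v not in known:
                raise FormatError(f"edge {u}->{v} names a gene outside the universe")

    def candidate_pairs(self) -> list[tuple[str, str]]:
        """All ordered gene pairs excluding self-pairs, in universe order."""
        return [(u, v) for u in self.universe for v in self.universe if u != v]

    @property
    def n_candidates(self) -> int:
        g = len(self.universe)
        return g * (g - 1)


@dataclasses.dataclass
class EdgeScoreTable:
    """Signed strength scores for every directed gene pair, ranked by |score|.

    ``derived_from`` records the winning cluster count and the K x K
    cluster-level score matrix the gene scores were copied from (None when the
    table was read back from disk).
    """

    entries: list[tuple[str, str, float]]
    derived_from: tuple[int, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for i in range(len(self.entries) - 1):
            if abs(self.entries[i][2]) < abs(self.entries[i + 1][2]):
                raise ValueError("entries must be sorted by descending |score|")

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, _ in self.entries]


# ---------------------------------------------------------------------------
# time-series tables


def _parse_header(fields: Sequence[str], path: str, lineno: int) -> list[str]:
    if not fields or fields[0] != "Time":
        raise FormatError(f"{path}:{lineno}: header must start with 'Time'")
    genes = list(fields[1:])
    if not genes:
        raise FormatError(f"{path}:{lineno}: header names no genes")
    if len(set(genes)) != len(genes):
        raise FormatError(f"{path}:{lineno}: duplicate gene names in header")
    return genes


def _parse_block(lines: list[tuple[int, str]], path: str,
                 genes: list[str] | None) -> tuple[list[str], SeriesTable]:
    """Parse one block of (lineno, text) rows into a SeriesTable."""
    first_no, first = lines[0]
    fields = first.split("\t")
    if fields and fields[0] == "Time":
        block_genes = _parse_header(fields, path, first_no)
        if genes is not None and block_genes != genes:
            raise FormatError(
                f"{path}:{first_no}: block header genes {block_genes} are "
                f"inconsistent with the first header {genes}"
            )
        genes = block_genes
        body = lines[1:]
    else:
        if genes is None:
            raise FormatError(f"{path}:{first_no}: first block must have a header")
        body = lines
    if not body:
        raise FormatError(f"{path}:{first_no}: block has a header but no rows")
    times: list[float] = []
    rows: list[list[float]] = []
    for lineno, text in body:
        cells = text.split("\t")
        if len(cells) != len(genes) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(genes) + 1} columns, got {len(cells)}"
            )
        try:
            numeric = [float(c) for c in cells]
        except ValueError:
            bad = next(c for c in cells if not _is_number(c))
            raise FormatError(f"{path}:{lineno}: non-numeric cell {bad!r}") from None
        times.append(numeric[0])
        rows.append(numeric[1:])
    values = np.asarray(rows, dtype=float).T  # genes x times
    return genes, SeriesTable(gene_names=list(genes),
                              time_points=np.asarray(times), values=values)


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def read_timeseries(path: str | Path, network_id: str | None = None) -> TimeSeriesSet:
    """Read a (possibly multi-block) time-series TSV into a TimeSeriesSet.

    Blocks are separated by blank lines; each block may repeat the header.
    Gene order is taken from the first header and enforced across blocks.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    blocks: list[list[tuple[int, str]]] = []
    current: list[tuple[int, str]] = []
    for lineno, text in enumerate(raw, start=1):
        if text.strip() == "":
            if current:
                blocks.append(current)
                current = []
        else:
            current.append((lineno, text))
    if current:
        blocks.append(current)
    if not blocks:
        raise FormatError(f"{path}: empty file")
    genes: list[str] | None = None
    series: list[SeriesTable] = []
    for block in blocks:
        genes, table = _parse_block(block, str(path), genes)
        series.append(table)
    return TimeSeriesSet(series=series, network_id=network_id or path.stem)


def read_timeseries_multi(paths: Iterable[str | Path],
                          network_id: str = "") -> TimeSeriesSet:
    """Read several files (each one or more series) into a single set."""
    series: list[SeriesTable] = []
    for p in paths:
        series.extend(read_timeseries(p).series)
    return TimeSeriesSet(series=series, network_id=network_id)


def write_timeseries(data: TimeSeriesSet, path: str | Path) -> None:
    """Write all series as blank-line-separated blocks with repeated headers."""
    path = Path(path)
    chunks = []
    header = "Time\t" + "\t".join(data.gene_names)
    for table in data.series:
        lines = [header]
        for t in range(table.n_times):
            cells = [_fmt(table.time_points[t])]
            cells += [_fmt(v) for v in table.values[:, t]]
            lines.append("\t".join(cells))
        chunks.append("\n".join(lines))
    path.write_text("\n\n".join(chunks) + "\n")


def _fmt(x: float) -> str:
    return format(float(x), ".6g")


# ---------------------------------------------------------------------------
# gold standards


def read_gold_standard(path: str | Path, gene_universe: Sequence[str]) -> GoldStandard:
    """Read a ``regulator<TAB>target<TAB>{0,1}`` edge list over a gene universe."""
    path = Path(path)
    known = set(gene_universe)
    seen: dict[tuple[str, str], int] = {}
    edges: set[tuple[str, str]] = set()
    for lineno, text in enumerate(path.read_text().splitlines(), start=1):
        if text.strip() == "":
            continue
        cells = text.split("\t")
        if len(cells) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
        u, v, lab = cells
        if lab not in ("0", "1"):
            raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
        for name in (u, v):
            if name not in known:
                raise FormatError(f"{path}:{lineno}: unknown gene {name!r}")
        if u == v and lab == "1":
            raise FormatError(f"{path}:{lineno}: self-edge {u}->{v} labeled true")
        label = int(lab)
        if (u, v) in seen and seen[(u, v)] != label:
            raise FormatError(f"{path}:{lineno}: contradictory duplicate line for {u}->{v}")
        seen[(u, v)] = label
        if label == 1:
            edges.add((u, v))
    return GoldStandard(edges=edges, universe=list(gene_universe))


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    """Write true edges (label 1) in universe order; negatives are implicit."""
    lines = [f"{u}\t{v}\t1" for u, v in gold.candidate_pairs() if (u, v) in gold.edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# edge rankings


def write_edge_ranking(table: EdgeScoreTable, path: str | Path) -> None:
    """Write ``regulator<TAB>target<TAB>score`` rows in descending |score| order."""
    if not table.entries:
        raise ValueError("refusing to write an empty edge ranking")
    lines = [f"{u}\t{v}\t{_fmt(s)}" for u, v, s in table.entries]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_ranking(path: str | Path) -> EdgeScoreTable:
    """Read a ranked edge list back, preserving order."""
    entries: list[tuple[str, str, float]] = []
    path = Path(path)
    for lineno, text in enumerate(path.read_text().splitlines(), start=1):
        if text.strip() == "":
            continue
        cells = text.split("\t")
        if len(cells) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(cells)}")
        u, v, s = cells
        if not _is_number(s):
            raise FormatError(f"{path}:{lineno}: non-numeric score {s!r}")
        entries.append((u, v, float(s)))
    if not entries:
        raise FormatError(f"{path}: empty edge ranking")
    return EdgeScoreTable(entries=entries)
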