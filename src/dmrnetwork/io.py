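"""Domain data model and readers/writers for methylation network analysis.

The pipeline operates on three tabular inputs — a probes x samples beta-value
matrix, a table of differentially methylated regions (DMRs) mapping probes to
genomic regions, and a sample metadata table — and emits edge lists, hub
tables, heatmap matrices and test results.  Everything here is plain TSV so
that outputs are diffable and byte-stable.

Beta values are methylation fractions in [0, 1] as reported by Illumina
arrays; missing measurements are carried as NaN throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKENS = frozenset({"", "na", "nan", "null"})


class ValidationError(ValueError):
    """An input file or in-memory object violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MethylationMatrix:
    """Probes x samples beta-value matrix; missing entries are NaN."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float64, shape (n_probes, n_samples)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError("beta values must lie in [0, 1]")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def subset_probes(self, probe_ids: list[str]) -> "MethylationMatrix":
        idx = [self.probe_ids.index(p) for p in probe_ids]
        return MethylationMatrix(list(probe_ids), list(self.sample_ids), self.values[idx])


@dataclass
class DMR:
    """One differentially methylated region and its member CpG probes."""

    dmr_id: str
    chrom: str
    start: int
    end: int
    gene_label: str  # "IGR" marks intergenic regions
    probe_ids: list[str]

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValidationError(f"DMR {self.dmr_id} has an empty probe list")
        if not self.start < self.end:
            raise ValidationError(
                f"DMR {self.dmr_id}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass
class DMRSet:
    """Ordered collection of DMRs with disjoint probe memberships."""

    dmrs: list[DMR]

    def __post_init__(self) -> None:
        _check_unique([d.dmr_id for d in self.dmrs], "DMR")
        seen: dict[str, str] = {}
        for d in self.dmrs:
            for p in d.probe_ids:
                if p in seen:
                    raise ValidationError(
                        f"probe {p} is listed in both DMR {seen[p]} and DMR {d.dmr_id}"
                    )
                seen[p] = d.dmr_id

    def __len__(self) -> int:
        return len(self.dmrs)

    def __iter__(self):
        return iter(self.dmrs)

    @property
    def dmr_ids(self) -> list[str]:
        return [d.dmr_id for d in self.dmrs]

    @property
    def all_probe_ids(self) -> list[str]:
        return [p for d in self.dmrs for p in d.probe_ids]

    @property
    def gene_labels(self) -> dict[str, str]:
        return {d.dmr_id: d.gene_label for d in self.dmrs}

    def probe_map(self) -> dict[str, list[str]]:
        return {d.dmr_id: list(d.probe_ids) for d in self.dmrs}

    def resolve_against(self, m: MethylationMatrix) -> None:
        """Raise if any member probe is absent from the matrix."""
        have = set(m.probe_ids)
        for d in self.dmrs:
            missing = [p for p in d.probe_ids if p not in have]
            if missing:
                raise ValidationError(
                    f"DMR {d.dmr_id}: probes not present in matrix: {', '.join(missing)}"
                )


@dataclass
class SampleTable:
    """Sample metadata: group label per sample, optional subject pairing."""

    sample_ids: list[str]
    group_labels: list[str]
    pair_ids: list[str | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pair_ids is None:
            self.pair_ids = [None] * len(self.sample_ids)
        if not (len(self.sample_ids) == len(self.group_labels) == len(self.pair_ids)):
            raise ValidationError("sample table columns have unequal lengths")
        _check_unique(self.sample_ids, "sample")
        by_pair: dict[str, list[str]] = {}
        for sid, grp, pid in zip(self.sample_ids, self.group_labels, self.pair_ids):
            if pid is not None:
                by_pair.setdefault(pid, []).append(grp)
        for pid, groups in by_pair.items():
            if len(groups) != 2:
                raise ValidationError(
                    f"pair_id {pid} occurs {len(groups)} times; pairs must occur exactly twice"
                )
            if groups[0] == groups[1]:
                raise ValidationError(
                    f"pair_id {pid}: both samples carry group label {groups[0]!r}"
                )

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.group_labels) if g == label]

    def group_of(self, sample_id: str) -> str:
        return self.group_labels[self.sample_ids.index(sample_id)]

    def pairs_between(self, label_a: str, label_b: str) -> list[tuple[str, str]]:
        """Complete (a, b) sample pairs spanning the two labels, sorted by pair id."""
        by_pair: dict[str, dict[str, str]] = {}
        for sid, grp, pid in zip(self.sample_ids, self.group_labels, self.pair_ids):
            if pid is not None and grp in (label_a, label_b):
                by_pair.setdefault(pid, {})[grp] = sid
        out = []
        for pid in sorted(by_pair):
            d = by_pair[pid]
            if label_a in d and label_b in d:
                out.append((d[label_a], d[label_b]))
        return out


@dataclass
class NetworkParams:
    """Knobs of the co-methylation network construction.

    beta        soft-threshold power applied to |PCC|; None selects the
                smallest qualifying power from ``beta_grid``
    r2_threshold  scale-free model-fitting index the log-log degree fit must
                exceed (default 0.70)
    beta_grid   ascending candidate powers scanned during auto-selection
    tom_cutoff  average-TOM threshold above which a DMR pair becomes an edge
    """

    beta: int | None = None
    r2_threshold: float = 0.70
    beta_grid: tuple[int, ...] = tuple(range(1, 21))
    tom_cutoff: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold < 1.0:
            raise ValidationError("r2_threshold must lie in (0, 1)")
        if not self.beta_grid or list(self.beta_grid) != sorted(self.beta_grid):
            raise ValidationError("beta_grid must be non-empty and ascending")
        if any(b <= 0 for b in self.beta_grid):
            raise ValidationError("beta_grid powers must be positive")
        if self.beta is not None and self.beta <= 0:
            raise ValidationError("beta must be positive")
        if not 0.0 <= self.tom_cutoff <= 1.0:
            raise ValidationError("tom_cutoff must lie in [0, 1]")


@dataclass
class DMRNetwork:
    """DMR-level weighted graph after average-TOM thresholding.

    Nodes are all DMRs (isolated ones included); an undirected edge carries
    the average TOM between the two regions and exists iff that average is
    >= ``cutoff``.  Edges are stored once in canonical (sorted endpoint)
    order.  ``components`` labels each node with its connected component,
    numbered 1, 2, ... by descending component size.
    """

    node_ids: list[str]
    gene_labels: dict[str, str]
    edges: list[tuple[str, str, float]]
    cutoff: float
    components: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodeset = set(self.node_ids)
        canon = []
        for u, v, w in self.edges:
            if u == v:
                raise ValidationError(f"self-loop on {u}")
            if u not in nodeset or v not in nodeset:
                raise ValidationError(f"edge ({u}, {v}) references unknown node")
            if w < self.cutoff:
                raise ValidationError(f"edge ({u}, {v}) weight {w} below cutoff {self.cutoff}")
            canon.append((min(u, v), max(u, v), float(w)))
        self.edges = sorted(canon)
        if not self.components:
            self.components = self._label_components()

    def _label_components(self) -> dict[str, int]:
        import networkx as nx

        g = self.to_networkx()
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        return {node: i + 1 for i, comp in enumerate(comps) for node in comp}

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for n in self.node_ids:
            g.add_node(n, gene_label=self.gene_labels.get(n, ""))
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=w)
        return g

    def degree(self, node: str) -> int:
        return sum(1 for u, v, _ in self.edges if node in (u, v))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.edges}

    def connected_node_set(self) -> set[str]:
        return {n for e in self.edges for n in e[:2]}

    def component_members(self, label: int) -> set[str]:
        return {n for n, c in self.components.items() if c == label}


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes: set[str] = set()
        for i in ids:
            if i in seen:
                dupes.add(i)
            seen.add(i)
        raise ValidationError(f"duplicate {what} ids: {', '.join(sorted(dupes))}")


def _parse_cell(token: str, probe: str, sample: str) -> float:
    t = token.strip().strip('"')
    if t.lower() in MISSING_TOKENS:
        return math.nan
    try:
        v = float(t)
    except ValueError:
        raise ValidationError(
            f"non-numeric value {token!r} at probe {probe}, sample {sample}"
        ) from None
    if math.isnan(v):
        return math.nan
    if not 0.0 <= v <= 1.0:
        raise ValidationError(
            f"beta value {v} outside [0, 1] at probe {probe}, sample {sample}"
        )
    return v


def read_beta_matrix(path, dialect: str = "plain_tsv") -> MethylationMatrix:
    """Read a probes x samples beta matrix from TSV.

    ``plain_tsv``: header row of sample ids (first column = probe id column),
    one row per probe.  ``geo_series_matrix``: same table embedded in a GEO
    series-matrix file — "!"-prefixed metadata lines and the
    series_matrix_table_begin/end delimiters are stripped, quotes removed.
    Empty cells and the tokens NA/NaN/null (case-insensitive) become missing.
    """
    if dialect not in ("plain_tsv", "geo_series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    if dialect == "geo_series_matrix":
        lines = [ln for ln in lines if not ln.startswith("!")]
    rows = [ln.split("\t") for ln in lines if ln.strip()]
    if not rows:
        raise ValidationError(f"{path}: empty table")
    header = [c.strip().strip('"') for c in rows[0]]
    sample_ids = header[1:]
    probe_ids: list[str] = []
    data = np.empty((len(rows) - 1, len(sample_ids)))
    for r, row in enumerate(rows[1:]):
        if len(row) != len(header):
            raise ValidationError(
                f"{path}: row {r + 2} has {len(row)} fields, expected {len(header)}"
            )
        probe = row[0].strip().strip('"')
        probe_ids.append(probe)
        for c, tok in enumerate(row[1:]):
            data[r, c] = _parse_cell(tok, probe, sample_ids[c])
    return MethylationMatrix(probe_ids, sample_ids, data)


def write_beta_matrix(m: MethylationMatrix, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(m.sample_ids) + "\n")
        for i, probe in enumerate(m.probe_ids):
            cells = [
                "NA" if math.isnan(v) else repr(float(v)) for v in m.values[i]
            ]
            fh.write(probe + "\t" + "\t".join(cells) + "\n")


DMR_COLUMNS = ["dmr_id", "chrom", "start", "end", "gene_label", "probe_ids"]


def read_dmr_set(path) -> DMRSet:
    """Read a DMR definition table (TSV; probe ids semicolon-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in DMR_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {', '.join(missing_cols)}")
    dmrs = []
    for _, row in df.iterrows():
        probes = [p for p in row["probe_ids"].split(";") if p]
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError:
            raise ValidationError(
                f"{path}: non-integer coordinates for DMR {row['dmr_id']}"
            ) from None
        dmrs.append(
            DMR(row["dmr_id"], row["chrom"], start, end, row["gene_label"], probes)
        )
    return DMRSet(dmrs)


def write_dmr_set(d: DMRSet, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(DMR_COLUMNS) + "\n")
        for dmr in d:
            fh.write(
                f"{dmr.dmr_id}\t{dmr.chrom}\t{dmr.start}\t{dmr.end}\t"
                f"{dmr.gene_label}\t{';'.join(dmr.probe_ids)}\n"
            )


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "group_label"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    pair_ids: list[str | None]
    if "pair_id" in df.columns:
        pair_ids = [p if p else None for p in df["pair_id"]]
    else:
        pair_ids = [None] * len(df)
    return SampleTable(list(df["sample_id"]), list(df["group_label"]), pair_ids)


def write_sample_table(s: SampleTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup_label\tpair_id\n")
        for sid, grp, pid in zip(s.sample_ids, s.group_labels, s.pair_ids):
            fh.write(f"{sid}\t{grp}\t{pid if pid is not None else ''}\n")


# ---------------------------------------------------------------------------
# Network writers (Cytoscape-readable)
# ---------------------------------------------------------------------------

def write_edge_list(network: DMRNetwork, path, format: str = "tsv") -> None:
    """Write the DMR network as SIF, GraphML or weighted TSV.

    SIF lines read ``dmrA<TAB>cometh<TAB>dmrB``; each undirected edge is
    emitted once with the lexicographically smaller id first.  The TSV adds
    the average-TOM weight; GraphML carries gene labels and edge weights.
    Emission order is sorted, so files are byte-stable across runs.
    """
    if format == "sif":
        with open(path, "wt", encoding="utf-8") as fh:
            for u, v, _ in network.edges:
                fh.write(f"{u}\tcometh\t{v}\n")
    elif format == "tsv":
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in network.edges:
                fh.write(f"{u}\t{v}\t{w!r}\n")
    elif format == "graphml":
        import networkx as nx

        nx.write_graphml(network.to_networkx(), path)
    else:
        raise ValueError(f"unknown edge-list format {format!r}")


def read_edge_list_tsv(path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(
        path, sep="\t", dtype={"source": str, "target": str},
        float_precision="round_trip",
    )
    return [
        (r.source, r.target, float(r.weight)) for r in df.itertuples(index=False)
    ]


def write_square_matrix(df: pd.DataFrame, path) -> None:
    """Write a square labelled matrix (e.g. DMR average-TOM) as TSV."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("dmr_id\t" + "\t".join(df.columns) + "\n")
        for idx, row in zip(df.index, df.to_numpy()):
            fh.write(str(idx) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_square_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
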