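"""Multi-dataset orchestration: per-dataset networks, shared-order heatmap
matrices, and cross-dataset network comparison.

Each dataset contributes one co-methylation network built from its own beta
matrix against the shared DMR set (its own soft-threshold power and
average-TOM cutoff).  The datasets are then compared: Jaccard overlap of
connected nodes and of edges, and — for each connected component of a
reference network — the fraction of that component's nodes that appear
connected in every other dataset, a quantitative surrogate for "this DMR
network is observed in that dataset".

All outputs are deterministic TSV/JSON; the manifest records parameters and
SHA-256 checksums of inputs and outputs so reruns can be diffed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from . import network as net
from .io import (
    DMRNetwork,
    DMRSet,
    NetworkParams,
    ValidationError,
    read_beta_matrix,
    read_dmr_set,
    write_edge_list,
    write_square_matrix,
)

logger = logging.getLogger(__name__)


@dataclass
class DatasetConfig:
    name: str
    beta_matrix: str
    dialect: str = "plain_tsv"
    sample_table: str | None = None
    beta: int | str = "auto"  # power, or "auto" for smallest qualifying
    tom_cutoff: float = 0.15
    r2_threshold: float = 0.70


@dataclass
class RunConfig:
    datasets: list[DatasetConfig]
    dmr_set: str
    reference_dataset: str
    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    presence_threshold: float = 0.5
    include_within_dmr: bool = False

    def __post_init__(self) -> None:
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValidationError("dataset names must be unique")
        if self.reference_dataset not in names:
            raise ValidationError(
                f"reference_dataset {self.reference_dataset!r} is not a dataset"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        datasets = [DatasetConfig(**d) for d in raw.pop("datasets")]
        return cls(datasets=datasets, **raw)


@dataclass
class NetworkComparison:
    """Pairwise overlap indices and per-component presence fractions."""

    node_jaccard: dict[tuple[str, str], float]
    edge_jaccard: dict[tuple[str, str], float]
    # (dataset, reference component id) -> fraction of component nodes connected there
    presence: dict[tuple[str, int], float]
    reference: str

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        pair_rows = [
            {
                "dataset_a": a,
                "dataset_b": b,
                "node_jaccard": self.node_jaccard[(a, b)],
                "edge_jaccard": self.edge_jaccard[(a, b)],
            }
            for a, b in sorted(self.node_jaccard)
        ]
        pres_rows = [
            {
                "dataset": ds,
                "reference_component": comp,
                "presence_fraction": frac,
            }
            for (ds, comp), frac in sorted(self.presence.items())
        ]
        return pd.DataFrame(pair_rows), pd.DataFrame(pres_rows)


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def compare_networks(
    nets: dict[str, DMRNetwork],
    reference: str,
    component_of_interest: int | None = None,
) -> NetworkComparison:
    """Node/edge Jaccard per dataset pair and reference-component presence.

    Node sets are restricted to connected nodes (degree >= 1) since every
    network carries the full DMR list as nodes.  Presence of a reference
    component in a dataset is the fraction of the component's nodes that
    are connected in that dataset's network.
    """
    if len(nets) < 2:
        raise ValidationError("need at least 2 networks to compare")
    if reference not in nets:
        raise ValidationError(f"reference {reference!r} not among networks")
    ref = nets[reference]
    comp_labels = sorted(
        {c for n, c in ref.components.items() if len(ref.component_members(c)) > 1}
    )
    if component_of_interest is not None:
        members = ref.component_members(component_of_interest)
        if not members:
            raise ValidationError(
                f"reference component {component_of_interest} is empty"
            )
        comp_labels = [component_of_interest]

    node_j, edge_j = {}, {}
    for a, b in itertools.combinations(sorted(nets), 2):
        node_j[(a, b)] = _jaccard(
            nets[a].connected_node_set(), nets[b].connected_node_set()
        )
        edge_j[(a, b)] = _jaccard(nets[a].edge_set(), nets[b].edge_set())

    presence = {}
    for ds, n in sorted(nets.items()):
        connected = n.connected_node_set()
        for comp in comp_labels:
            members = ref.component_members(comp)
            presence[(ds, comp)] = len(members & connected) / len(members)
    return NetworkComparison(node_j, edge_j, presence, reference)


def ordered_heatmap_matrix(
    matrices: dict[str, pd.DataFrame],
    reference: str,
    linkage_method: str = "average",
) -> dict[str, pd.DataFrame]:
    """Reindex every DMR average-TOM matrix by one shared clustering order.

    The order is the leaf order of hierarchical clustering (default average
    linkage) of the reference dataset's matrix under the dissimilarity
    1 - averageTOM; the same order is applied to all datasets so heatmaps
    are directly comparable row by row.
    """
    if reference not in matrices:
        raise ValidationError(f"reference {reference!r} not among matrices")
    ref = matrices[reference]
    ids = list(ref.index)
    for name, mat in matrices.items():
        if set(mat.index) != set(ids) or set(mat.columns) != set(ids):
            extra = sorted(set(mat.index) ^ set(ids))
            raise ValidationError(
                f"dataset {name!r} has a mismatched DMR set (difference: {extra[:10]})"
            )
    if len(ids) < 2:
        return {k: v.copy() for k, v in matrices.items()}
    dis = 1.0 - ref.to_numpy(dtype=float)
    dis = (dis + dis.T) / 2.0
    np.fill_diagonal(dis, 0.0)
    order = leaves_list(linkage(squareform(dis, checks=False), method=linkage_method))
    ordered_ids = [ids[i] for i in order]
    return {
        name: mat.loc[ordered_ids, ordered_ids] for name, mat in matrices.items()
    }


# ---------------------------------------------------------------------------
# run_all
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def analyze_dataset(
    matrix,
    dmrs: DMRSet,
    params: NetworkParams,
    include_within_dmr: bool = False,
) -> dict:
    """One dataset through the full network stage; returns all intermediates."""
    dmrs.resolve_against(matrix)
    corr = net.compute_correlation(matrix)
    if params.beta is None:
        beta, diagnostics = net.select_soft_threshold(corr, params)
    else:
        beta = int(params.beta)
        fits = []
        for b in params.beta_grid:
            try:
                fits.append(net.scale_free_fit(net.adjacency(corr, b)))
            except net.DegenerateDegreeError:
                fits.append(None)
        diagnostics = net.fit_table(fits, params.beta_grid)
    adj = net.adjacency(corr, beta)
    tom = net.compute_tom(adj)
    dmr_tom = net.dmr_average_tom(tom, dmrs, include_within_dmr)
    network = net.extract_network(dmr_tom, dmrs, params.tom_cutoff)
    hubs = net.hub_table(network)
    return {
        "beta": beta,
        "diagnostics": diagnostics,
        "correlation": corr,
        "tom": tom,
        "dmr_tom": dmr_tom,
        "network": network,
        "hubs": hubs,
    }


def run_all(config: RunConfig) -> dict:
    """Execute the full multi-dataset workflow and write every artifact.

    Per dataset: fit diagnostics, DMR average-TOM matrix (heatmap data),
    edge lists (TSV/SIF/GraphML) and hub table.  Shared: ordered heatmap
    matrices, the comparison report, and a manifest with parameters and
    checksums.  A dataset failing soft-threshold selection is recorded in
    the manifest and skipped; the run continues.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dmrs = read_dmr_set(config.dmr_set)

    manifest: dict = {
        "seed": config.seed,
        "tom_variant": "unsigned, denominator min(k_i,k_j)+1-a_ij",
        "include_within_dmr": config.include_within_dmr,
        "dmr_set": {"path": str(config.dmr_set), "sha256": _sha256(Path(config.dmr_set))},
        "datasets": {},
        "outputs": {},
        "warnings": [],
        "failures": {},
    }

    results: dict[str, dict] = {}
    written: list[Path] = []
    for ds in config.datasets:
        logger.info("dataset %s: reading %s", ds.name, ds.beta_matrix)
        matrix = read_beta_matrix(ds.beta_matrix, ds.dialect)
        params = NetworkParams(
            beta=None if ds.beta == "auto" else int(ds.beta),
            r2_threshold=ds.r2_threshold,
            tom_cutoff=ds.tom_cutoff,
        )
        entry = {
            "beta_matrix": {"path": str(ds.beta_matrix), "sha256": _sha256(Path(ds.beta_matrix))},
            "requested_beta": ds.beta,
            "tom_cutoff": ds.tom_cutoff,
            "r2_threshold": ds.r2_threshold,
            "n_probes": matrix.n_probes,
            "n_samples": matrix.n_samples,
        }
        try:
            res = analyze_dataset(matrix, dmrs, params, config.include_within_dmr)
        except net.SoftThresholdError as exc:
            logger.error("dataset %s: soft-threshold selection failed: %s", ds.name, exc)
            manifest["failures"][ds.name] = str(exc)
            diag_path = out / f"{ds.name}.fit_diagnostics.tsv"
            exc.diagnostics.to_csv(diag_path, sep="\t", index=False)
            written.append(diag_path)
            manifest["datasets"][ds.name] = entry
            continue
        entry["selected_beta"] = res["beta"]
        if res["correlation"].n_constant_pairs:
            manifest["warnings"].append(
                f"{ds.name}: {res['correlation'].n_constant_pairs} constant probe pairs"
            )
        manifest["datasets"][ds.name] = entry
        results[ds.name] = res

        res["diagnostics"].to_csv(out / f"{ds.name}.fit_diagnostics.tsv", sep="\t", index=False)
        write_square_matrix(res["dmr_tom"].to_frame(), out / f"{ds.name}.dmr_avg_tom.tsv")
        for fmt, suffix in (("tsv", "edges.tsv"), ("sif", "edges.sif"), ("graphml", "edges.graphml")):
            write_edge_list(res["network"], out / f"{ds.name}.{suffix}", fmt)
        res["hubs"].to_csv(out / f"{ds.name}.hubs.tsv", sep="\t", index=False)
        written.extend(
            out / f"{ds.name}.{sfx}"
            for sfx in ("fit_diagnostics.tsv", "dmr_avg_tom.tsv", "edges.tsv",
                        "edges.sif", "edges.graphml", "hubs.tsv")
        )

    if results:
        ref = config.reference_dataset
        if ref not in results:
            ref = sorted(results)[0]
            manifest["warnings"].append(
                f"reference dataset {config.reference_dataset!r} failed; using {ref!r}"
            )
        ordered = ordered_heatmap_matrix(
            {k: v["dmr_tom"].to_frame() for k, v in results.items()}, ref
        )
        for name, mat in ordered.items():
            p = out / f"{name}.heatmap_ordered.tsv"
            write_square_matrix(mat, p)
            written.append(p)

        if len(results) >= 2:
            comparison = compare_networks({k: v["network"] for k, v in results.items()}, ref)
            pair_df, pres_df = comparison.to_frames()
            pres_df["observed"] = pres_df["presence_fraction"] >= config.presence_threshold
            pair_df.to_csv(out / "comparison_pairs.tsv", sep="\t", index=False)
            pres_df.to_csv(out / "comparison_presence.tsv", sep="\t", index=False)
            written.extend([out / "comparison_pairs.tsv", out / "comparison_presence.tsv"])

    for p in sorted(set(written)):
        manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"results": results, "manifest": manifest, "out_dir": out}
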