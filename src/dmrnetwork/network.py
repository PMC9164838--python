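"""Co-methylation network construction on CpG probes and DMRs.

The method chain, run in order:

1. pairwise Pearson correlation (PCC) of probe methylation across samples;
2. unsigned soft-threshold adjacency  a_ij = |PCC_ij| ** beta;
3. scale-free fit of the connectivity distribution to select the smallest
   beta whose log-log degree fit reaches R^2 > 0.70 with negative slope;
4. topological overlap measure (TOM) between probes;
5. aggregation to the DMR level as the mean TOM over all cross-region
   probe pairs;
6. thresholding the DMR-level average TOM at a cutoff to extract the DMR
   network, and ranking its hub nodes by degree.

The TOM variant is the unsigned Zhang-Horvath form
``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
``L_ij = sum_u a_iu a_uj`` over u != i, j and connectivity
``k_i = sum_{u != i} a_iu``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DMRNetwork, DMRSet, MethylationMatrix, NetworkParams, ValidationError

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-9


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Pairwise-complete Pearson correlation between probes.

    ``n_obs[i, j]`` counts the samples where both probes were observed.
    ``n_constant_pairs`` counts pairs whose correlation was set to 0 because
    at least one probe had zero variance over the shared samples.
    """

    probe_ids: list[str]
    values: np.ndarray
    n_obs: np.ndarray
    n_constant_pairs: int = 0
    n_low_overlap_pairs: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.probe_ids):
            raise ValidationError("correlation matrix shape mismatch")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValidationError("correlation matrix not symmetric")
        if np.nanmax(np.abs(v)) > 1 + _SYM_TOL:
            raise ValidationError("correlation entries must lie in [-1, 1]")


def compute_correlation(
    m: MethylationMatrix,
    min_overlap: int = 10,
    on_low_overlap: str = "error",
) -> CorrelationMatrix:
    """Pairwise-complete-observation Pearson correlation between all probes.

    Probes constant over the shared samples contribute correlation 0 (not
    NaN) so downstream matrices stay finite; the number of such pairs is
    reported.  Pairs observed in fewer than ``min_overlap`` shared samples
    raise by default, or are zeroed and counted with
    ``on_low_overlap="flag"``.
    """
    if m.n_samples < 3:
        raise ValidationError("need at least 3 samples for correlation")
    if m.n_probes < 2:
        raise ValidationError("need at least 2 probes for correlation")
    if on_low_overlap not in ("error", "flag"):
        raise ValueError("on_low_overlap must be 'error' or 'flag'")

    x = m.values
    obs = ~np.isnan(x)
    all_missing = ~obs.any(axis=1)
    if all_missing.any():
        bad = [m.probe_ids[i] for i in np.flatnonzero(all_missing)]
        raise ValidationError(f"probes with all values missing: {', '.join(bad)}")

    n_obs = (obs.astype(np.int64) @ obs.T.astype(np.int64))
    if not np.isnan(x).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # constant probes
            r = np.corrcoef(x)
    else:
        r = pd.DataFrame(x.T).corr(min_periods=1).to_numpy()

    low = n_obs < min_overlap
    np.fill_diagonal(low, False)
    n_low = int(low.sum()) // 2
    if n_low and on_low_overlap == "error":
        i, j = np.argwhere(np.triu(low, 1))[0]
        raise ValidationError(
            f"{n_low} probe pairs share fewer than {min_overlap} observations "
            f"(e.g. {m.probe_ids[i]} vs {m.probe_ids[j]})"
        )

    constant = np.isnan(r)
    np.fill_diagonal(constant, False)
    n_constant = int(constant.sum()) // 2
    if n_constant:
        logger.warning("correlation: %d constant probe pairs set to 0", n_constant)
    r = np.where(constant, 0.0, r)
    if n_low:
        r = np.where(low, 0.0, r)
        logger.warning("correlation: %d low-overlap pairs set to 0", n_low)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(list(m.probe_ids), r, n_obs, n_constant, n_low)


# ---------------------------------------------------------------------------
# Adjacency and scale-free soft-threshold selection
# ---------------------------------------------------------------------------

@dataclass
class AdjacencyMatrix:
    """Unsigned weighted adjacency a_ij = |PCC_ij| ** beta, entries in [0, 1]."""

    probe_ids: list[str]
    values: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        v = self.values
        if v.min() < -_SYM_TOL or v.max() > 1 + _SYM_TOL:
            raise ValidationError("adjacency entries must lie in [0, 1]")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValidationError("adjacency matrix not symmetric")

    @property
    def connectivity(self) -> np.ndarray:
        """k_i = sum_{j != i} a_ij (diagonal excluded)."""
        return self.values.sum(axis=1) - np.diag(self.values)


def adjacency(c: CorrelationMatrix, beta: float) -> AdjacencyMatrix:
    if beta <= 0:
        raise ValueError("beta must be positive")
    a = np.abs(c.values) ** beta
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(list(c.probe_ids), a, beta)


@dataclass
class ScaleFreeFit:
    """Diagnostics of the log-log linear fit of the connectivity distribution."""

    beta: float
    r_squared: float
    slope: float
    mean_connectivity: float
    n_bins_used: int


class DegenerateDegreeError(ValidationError):
    """All connectivities identical: the degree distribution cannot be binned."""


def scale_free_fit(a: AdjacencyMatrix, n_bins: int = 10) -> ScaleFreeFit:
    """Fit log10 p(k) against log10 k over equal-width connectivity bins.

    Connectivities are binned into ``n_bins`` equal-width bins across their
    range; per non-empty bin, the mean connectivity and the fraction of
    nodes p(k) give one log-log point.  R^2 is the squared Pearson
    correlation of those points; a scale-free topology shows a negative
    slope.  Two non-empty bins always fit exactly (R^2 = 1), so n_bins must
    exceed 2 for the fit index to be meaningful.
    """
    k = a.connectivity
    if np.ptp(k) == 0:
        raise DegenerateDegreeError("degenerate degree distribution: all k identical")
    counts, edges = np.histogram(k, bins=n_bins, range=(k.min(), k.max()))
    sums, _ = np.histogram(k, bins=edges, weights=k)
    nonempty = counts > 0
    mean_k = sums[nonempty] / counts[nonempty]
    p_k = counts[nonempty] / k.size
    if nonempty.sum() < 2:
        raise DegenerateDegreeError("fewer than 2 non-empty connectivity bins")
    log_k = np.log10(mean_k)
    log_p = np.log10(p_k)
    if np.ptp(log_k) == 0:
        raise DegenerateDegreeError("degenerate binned connectivity")
    slope, _ = np.polyfit(log_k, log_p, 1)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(log_k, log_p)[0, 1]
    r2 = 0.0 if np.isnan(r) else float(r**2)
    return ScaleFreeFit(a.beta, r2, float(slope), float(k.mean()), int(nonempty.sum()))


class SoftThresholdError(ValidationError):
    """No candidate power reached the scale-free fit criterion."""

    def __init__(self, message: str, diagnostics: pd.DataFrame):
        super().__init__(message)
        self.diagnostics = diagnostics


def fit_table(fits: list[ScaleFreeFit | None], grid) -> pd.DataFrame:
    rows = []
    for b, f in zip(grid, fits):
        if f is None:
            rows.append((b, np.nan, np.nan, np.nan, 0))
        else:
            rows.append((b, f.r_squared, f.slope, f.mean_connectivity, f.n_bins_used))
    return pd.DataFrame(
        rows, columns=["beta", "r_squared", "slope", "mean_connectivity", "n_bins_used"]
    )


def select_soft_threshold(
    c: CorrelationMatrix, params: NetworkParams, n_bins: int = 10
) -> tuple[int, pd.DataFrame]:
    """Smallest power in the grid whose fit reaches R^2 > threshold, slope < 0.

    Returns the selected power and the full diagnostic table over the grid.
    Raises :class:`SoftThresholdError` (carrying the table) if no candidate
    qualifies.
    """
    fits: list[ScaleFreeFit | None] = []
    selected: int | None = None
    for b in params.beta_grid:
        try:
            f = scale_free_fit(adjacency(c, b), n_bins=n_bins)
        except DegenerateDegreeError:
            fits.append(None)
            continue
        fits.append(f)
        if selected is None and f.r_squared > params.r2_threshold and f.slope < 0:
            selected = int(b)
    table = fit_table(fits, params.beta_grid)
    if selected is None:
        raise SoftThresholdError(
            f"no power in {list(params.beta_grid)} reached "
            f"R^2 > {params.r2_threshold} with negative slope",
            table,
        )
    return selected, table


# ---------------------------------------------------------------------------
# Topological overlap
# ---------------------------------------------------------------------------

@dataclass
class TOMResult:
    """Topological overlap matrix with the adjacency it derives from."""

    probe_ids: list[str]
    values: np.ndarray
    adjacency: AdjacencyMatrix


def compute_tom(a: AdjacencyMatrix) -> TOMResult:
    """Unsigned topological overlap, computed with matrix products.

    For i != j: TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity; TOM_ii = 1.
    """
    v = a.values
    if v.min() < -_SYM_TOL or v.max() > 1 + _SYM_TOL:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    a0 = v.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMResult(list(a.probe_ids), tom, a)


# ---------------------------------------------------------------------------
# DMR-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class DMRTomMatrix:
    """Average topological overlap between DMR pairs.

    Off-diagonal entry (d1, d2) is the mean TOM over cross pairs of probes
    drawn one from each region; ``pair_counts`` records how many probe pairs
    each mean averages.  The diagonal is stored as 1 and never thresholded.
    """

    dmr_ids: list[str]
    values: np.ndarray
    pair_counts: np.ndarray
    include_within_dmr: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dmr_ids, columns=self.dmr_ids)


def dmr_average_tom(
    t: TOMResult, d: DMRSet, include_within_dmr: bool = False
) -> DMRTomMatrix:
    """Aggregate probe TOM to DMR level by averaging.

    Default (cross-block): entry (d1, d2) averages TOM_pq over p in d1, q in
    d2 only.  With ``include_within_dmr=True``, the mean runs over the whole
    union submatrix of the two regions' probes, within-region pairs
    included, diagonal excluded.
    """
    index = {p: i for i, p in enumerate(t.probe_ids)}
    for dmr in d:
        missing = [p for p in dmr.probe_ids if p not in index]
        if missing:
            raise ValidationError(
                f"DMR {dmr.dmr_id}: probes absent from TOM: {', '.join(missing)}"
            )
    n = len(d)
    sizes = np.array([len(dmr.probe_ids) for dmr in d], dtype=float)
    member = np.zeros((n, t.values.shape[0]))
    for i, dmr in enumerate(d):
        member[i, [index[p] for p in dmr.probe_ids]] = 1.0

    block_sum = member @ t.values @ member.T  # includes diagonal TOM entries
    cross_counts = np.outer(sizes, sizes)

    if not include_within_dmr:
        avg = block_sum / cross_counts
        counts = cross_counts.copy()
    else:
        # union-sum over probes(d1) U probes(d2), minus the n1+n2 diagonal ones
        union_sizes = sizes[:, None] + sizes[None, :]
        total = (
            np.diag(block_sum)[:, None]
            + np.diag(block_sum)[None, :]
            + 2.0 * block_sum
            - union_sizes
        )
        counts = union_sizes**2 - union_sizes
        avg = total / counts

    np.fill_diagonal(avg, 1.0)
    np.fill_diagonal(counts, 0.0)
    avg = np.clip((avg + avg.T) / 2.0, 0.0, 1.0)
    return DMRTomMatrix(d.dmr_ids, avg, counts, include_within_dmr)


# ---------------------------------------------------------------------------
# DMR network extraction, cutoff scan, hub ranking
# ---------------------------------------------------------------------------

def extract_network(dt: DMRTomMatrix, d: DMRSet, cutoff: float) -> DMRNetwork:
    """Threshold the DMR average-TOM matrix into an undirected network.

    An edge joins two DMRs iff their average TOM >= cutoff; every DMR stays
    a node, so isolated regions remain visible.  Connected components are
    labelled 1, 2, ... by descending size.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    ids = dt.dmr_ids
    v = dt.values
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = v[iu, ju] >= cutoff
    edges = [
        (ids[i], ids[j], float(v[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    ]
    return DMRNetwork(list(ids), d.gene_labels, edges, cutoff)


def scan_cutoffs(
    dt: DMRTomMatrix, d: DMRSet, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Edge counts, components and component-partition modularity per cutoff."""
    import networkx as nx

    if grid is None:
        grid = np.round(np.arange(0.01, 0.96, 0.01), 2)
    rows = []
    for cut in grid:
        net = extract_network(dt, d, float(cut))
        g = net.to_networkx()
        comps = list(nx.connected_components(g))
        if net.n_edges == 0:
            q = np.nan
        else:
            q = nx.algorithms.community.modularity(g, comps, weight=None)
        n_nontrivial = sum(1 for c in comps if len(c) > 1)
        rows.append((float(cut), net.n_edges, len(comps), n_nontrivial, q))
    return pd.DataFrame(
        rows, columns=["cutoff", "n_edges", "n_components", "n_nontrivial", "modularity"]
    )


def choose_cutoff(dt: DMRTomMatrix, d: DMRSet, grid: np.ndarray | None = None) -> float:
    """Pick the cutoff whose component partition maximises modularity.

    Scans a grid of cutoffs, treats each thresholded graph's connected
    components as a partition, and returns the smallest cutoff attaining the
    maximal (unweighted) modularity.  A convention for exploratory use; the
    per-dataset cutoffs of a real analysis are chosen by the analyst.
    """
    table = scan_cutoffs(dt, d, grid)
    valid = table.dropna(subset=["modularity"])
    if valid.empty:
        raise ValidationError("no cutoff in the grid yields any edge")
    best = valid["modularity"].max()
    return float(valid.loc[valid["modularity"] >= best - 1e-12, "cutoff"].iloc[0])


def hub_table(net: DMRNetwork, top_n: int = 10) -> pd.DataFrame:
    """Rank nodes by degree; percentages are relative to the whole network.

    Mirrors a "top N nodes connected with many other nodes" table: one row
    per hub with its degree and 100 * degree / total edge count (the column
    therefore does not sum to 100 over the top N), plus a totals row with
    the full network's edge count.
    """
    total = net.n_edges
    deg: dict[str, int] = {n: 0 for n in net.node_ids}
    for u, v, _ in net.edges:
        deg[u] += 1
        deg[v] += 1
    ranked = sorted(
        (n for n in net.node_ids if deg[n] > 0),
        key=lambda n: (-deg[n], net.gene_labels.get(n, ""), n),
    )[:top_n]
    rows = [
        {
            "dmr_id": n,
            "gene_label": net.gene_labels.get(n, ""),
            "edge_count": deg[n],
            "percent_of_total_edges": round(100.0 * deg[n] / total, 10) if total else 0.0,
        }
        for n in ranked
    ]
    rows.append(
        {
            "dmr_id": "Total",
            "gene_label": "",
            "edge_count": total,
            "percent_of_total_edges": 100.0 if total else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["dmr_id", "gene_label", "edge_count", "percent_of_total_edges"])
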