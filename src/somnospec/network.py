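"""Bootstrap partial-Spearman correlation networks.

Per severity group and per EEG measure (relative power or spectral entropy)
the analysis builds a 76-node network: 64 EEG nodes (8 channels x 8 bands)
plus 6 polysomnographic and 6 cognitive variables.  Edges are bootstrap
medians of Spearman partial correlations adjusted for sex and age: each of
``n_boot`` runs draws ``n_subsample`` subjects with replacement, computes all
pairwise partial correlations within the draw, and per entry the median and
2.5/97.5 percentiles over runs are retained.  The median matrix is
thresholded at ``|rho| >= 0.30`` (inclusive) into a signed weighted graph on
which layout (Fruchterman-Reingold), Newman modularity and strength /
closeness / betweenness centralities are computed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community
from scipy.stats import rankdata

from .recording import STANDARD_CHANNELS
from .spectral import (
    CANONICAL_BANDS,
    COGNITIVE_VARIABLES,
    PSG_VARIABLES,
    eeg_feature_names,
)

DEFAULT_THRESHOLD = 0.30
NON_EEG_NODES = PSG_VARIABLES + COGNITIVE_VARIABLES


def node_set(measure: str) -> list[str]:
    """The 76 node names of one network: 64 EEG nodes plus 12 variables."""
    if measure not in ("rp", "specen"):
        raise ValueError("measure must be 'rp' or 'specen'")
    return eeg_feature_names((measure,), CANONICAL_BANDS, STANDARD_CHANNELS) + list(
        NON_EEG_NODES
    )


def _residualize(ranked: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Least-squares removal of covariate effects from every column."""
    design = np.column_stack([np.ones(ranked.shape[0]), covariates])
    coeffs, *_ = np.linalg.lstsq(design, ranked, rcond=None)
    return ranked - design @ coeffs


def _corr_with_undefined(resid: np.ndarray) -> np.ndarray:
    """Correlation matrix of residual columns; NaN where a column is constant."""
    centered = resid - resid.mean(axis=0)
    std = centered.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        normed = centered / std
        corr = (normed.T @ normed) / resid.shape[0]
    corr[np.abs(std) < 1e-12, :] = np.nan
    corr[:, np.abs(std) < 1e-12] = np.nan
    return np.clip(corr, -1.0, 1.0, out=corr)


def partial_spearman(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Spearman partial correlation of ``x`` and ``y`` given covariates.

    All variables are rank-transformed with midranks; covariate effects are
    removed from both ranked ``x`` and ranked ``y`` by least squares and the
    Pearson correlation of the residuals is returned.  A variable that is
    constant after ranking yields NaN (undefined correlation, distinct from
    an error); fewer than 4 complete observations is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = np.empty((x.size, 0))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(covariates), axis=1)
    x, y, covariates = x[ok], y[ok], covariates[ok]
    if x.size < 4:
        raise ValueError(f"need >= 4 complete observations, got {x.size}")
    data = rankdata(np.column_stack([x, y]), axis=0, method="average")
    if np.ptp(data[:, 0]) == 0 or np.ptp(data[:, 1]) == 0:
        return float("nan")
    cov_ranked = rankdata(covariates, axis=0, method="average")
    cov_ranked = cov_ranked[:, np.ptp(cov_ranked, axis=0) > 0]
    resid = _residualize(data, cov_ranked)
    return float(_corr_with_undefined(resid)[0, 1])


@dataclasses.dataclass
class BootstrapCorrelationMatrix:
    """Bootstrap-median partial-correlation matrix with percentile companions.

    ``n_valid`` counts, per entry, the bootstrap runs in which the
    correlation was defined (a variable constant within a 20-subject draw
    yields an undefined value for its pairs; such runs are excluded from the
    median/percentile aggregation rather than imputed).
    """

    nodes: tuple[str, ...]
    median: np.ndarray
    p2_5: np.ndarray
    p97_5: np.ndarray
    n_valid: np.ndarray
    n_boot: int
    n_subsample: int
    seed: int

    @property
    def flagged(self) -> np.ndarray:
        """Entries undefined in more than half of the bootstrap runs."""
        return self.n_valid < (self.n_boot / 2.0)

    def frame(self, which: str = "median") -> pd.DataFrame:
        arr = getattr(self, which)
        return pd.DataFrame(arr, index=self.nodes, columns=self.nodes)

    def to_csv(self, directory: str | Path, stem: str) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for which in ("median", "p2_5", "p97_5"):
            p = directory / f"{stem}_{which}.csv"
            self.frame(which).to_csv(p)
            paths.append(p)
        return paths


def bootstrap_correlations(
    df: pd.DataFrame,
    columns: Sequence[str],
    covariates: Sequence[str] = ("age", "sex"),
    n_boot: int = 1000,
    n_subsample: int = 20,
    seed: int = 0,
) -> BootstrapCorrelationMatrix:
    """Bootstrap the partial-Spearman matrix over ``columns`` of ``df``.

    Subjects are put in a canonical order (sorted by ``id`` when present) so
    the seed-to-draw mapping is invariant to the input row order.  Sex is
    encoded 0/1 and, like age, rank-transformed alongside the data columns
    before per-run residualization.
    """
    if len(df) < 2:
        raise ValueError("bootstrap needs a group with >= 2 subjects")
    if "id" in df.columns:
        df = df.sort_values("id", kind="mergesort")
    data = df[list(columns)].to_numpy(dtype=float)
    cov = df[list(covariates)].copy()
    if "sex" in cov.columns and cov["sex"].dtype == object:
        cov["sex"] = (cov["sex"] == "M").astype(float)
    cov = cov.to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(df), size=(n_boot, n_subsample))
    k = len(columns)
    stack = np.empty((n_boot, k, k))
    for r in range(n_boot):
        idx = draws[r]
        ranked = rankdata(data[idx], axis=0, method="average")
        cov_ranked = rankdata(cov[idx], axis=0, method="average")
        cov_ranked = cov_ranked[:, np.ptp(cov_ranked, axis=0) > 0]
        resid = _residualize(ranked, cov_ranked)
        stack[r] = _corr_with_undefined(resid)

    n_valid = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(stack, axis=0)
        p2_5 = np.nanpercentile(stack, 2.5, axis=0)
        p97_5 = np.nanpercentile(stack, 97.5, axis=0)
    for arr in (median, p2_5, p97_5):
        np.fill_diagonal(arr, 1.0)
    return BootstrapCorrelationMatrix(
        nodes=tuple(columns),
        median=median,
        p2_5=p2_5,
        p97_5=p97_5,
        n_valid=n_valid,
        n_boot=n_boot,
        n_subsample=n_subsample,
        seed=seed,
    )


def bootstrap_matrix(
    table: pd.DataFrame,
    group: str,
    measure: str,
    n_boot: int = 1000,
    n_subsample: int = 20,
    seed: int = 0,
) -> BootstrapCorrelationMatrix:
    """Bootstrap matrix for one severity group and one EEG measure."""
    rows = table[table["group"] == group]
    if len(rows) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 subjects")
    return bootstrap_correlations(
        rows, node_set(measure), n_boot=n_boot, n_subsample=n_subsample, seed=seed
    )


@dataclasses.dataclass
class CorrelationNetwork:
    """Thresholded signed correlation graph with analysis annotations."""

    graph: nx.Graph
    threshold: float
    layout: dict[str, tuple[float, float]] | None = None
    modules: dict[str, int] | None = None
    modularity: float | None = None
    centrality: pd.DataFrame | None = None

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def threshold_network(
    mat: BootstrapCorrelationMatrix, threshold: float = DEFAULT_THRESHOLD
) -> CorrelationNetwork:
    """Retain edges with ``|median rho| >= threshold`` (inclusive).

    Signed weights are preserved; ``abs_weight`` and ``distance = 1/|rho|``
    edge attributes support modularity and centrality.  Isolated nodes stay
    in the node set; an empty edge set is allowed.
    """
    g = nx.Graph()
    g.add_nodes_from(mat.nodes)
    n = len(mat.nodes)
    for i in range(n):
        for j in range(i + 1, n):
            w = mat.median[i, j]
            if np.isfinite(w) and abs(w) >= threshold:
                g.add_edge(
                    mat.nodes[i],
                    mat.nodes[j],
                    weight=float(w),
                    abs_weight=float(abs(w)),
                    distance=float(1.0 / abs(w)),
                )
    return CorrelationNetwork(graph=g, threshold=threshold)


def layout_fruchterman_reingold(
    net: CorrelationNetwork, iterations: int = 500, seed: int = 0
) -> dict[str, tuple[float, float]]:
    """Force-directed layout; attraction scales with ``|rho|``."""
    if net.graph.number_of_nodes() == 1:
        node = next(iter(net.graph.nodes))
        net.layout = {node: (0.0, 0.0)}
        return net.layout
    pos = nx.spring_layout(
        net.graph, weight="abs_weight", iterations=iterations, seed=seed
    )
    net.layout = {n: (float(p[0]), float(p[1])) for n, p in pos.items()}
    return net.layout


def _partition_modularity(g: nx.Graph, communities: list[set]) -> float:
    return nx_community.modularity(g, communities, weight="abs_weight")


def _refine_partition(g: nx.Graph, communities: list[set]) -> list[set]:
    """Kernighan-Lin-style refinement: single-node moves (including splitting
    a node off into its own community) alternated with community merges,
    repeated until neither yields a modularity gain."""
    communities = [set(c) for c in communities]
    improved = True
    while improved:
        improved = False
        q = _partition_modularity(g, communities)
        for node in list(g.nodes):
            home = next(i for i, c in enumerate(communities) if node in c)
            best_gain, best_target = 0.0, None
            candidates = {
                i
                for i, c in enumerate(communities)
                for nbr in g.neighbors(node)
                if nbr in c
            }
            candidates.add(len(communities))  # allow splitting off
            for target in candidates:
                if target == home:
                    continue
                trial = [set(c) for c in communities] + [set()]
                trial[home].discard(node)
                trial[target].add(node)
                trial = [c for c in trial if c]
                gain = _partition_modularity(g, trial) - q
                if gain > best_gain + 1e-12:
                    best_gain, best_target = gain, trial
            if best_target is not None:
                communities = best_target
                q += best_gain
                improved = True
        # pair-swap pass (full Kernighan-Lin move set); quadratic in n, so
        # only attempted on small graphs where it is affordable
        if g.number_of_nodes() <= 30 and len(communities) > 1:
            swapped = True
            while swapped:
                swapped = False
                q = _partition_modularity(g, communities)
                best_gain, best_trial = 0.0, None
                for i in range(len(communities)):
                    for j in range(i + 1, len(communities)):
                        for u in communities[i]:
                            for v in communities[j]:
                                trial = [set(c) for c in communities]
                                trial[i].discard(u)
                                trial[i].add(v)
                                trial[j].discard(v)
                                trial[j].add(u)
                                gain = _partition_modularity(g, trial) - q
                                if gain > best_gain + 1e-12:
                                    best_gain, best_trial = gain, trial
                if best_trial is not None:
                    communities = best_trial
                    swapped = improved = True
        # merge pass: join any two communities if that raises Q
        merged = True
        while merged and len(communities) > 1:
            merged = False
            q = _partition_modularity(g, communities)
            best_gain, best_pair = 0.0, None
            for i in range(len(communities)):
                for j in range(i + 1, len(communities)):
                    trial = [
                        c for k, c in enumerate(communities) if k not in (i, j)
                    ] + [communities[i] | communities[j]]
                    gain = _partition_modularity(g, trial) - q
                    if gain > best_gain + 1e-12:
                        best_gain, best_pair = gain, trial
            if best_pair is not None:
                communities = best_pair
                merged = improved = True
    return communities


def modularity_partition(net: CorrelationNetwork) -> tuple[dict[str, int], float]:
    """Maximize weighted Newman modularity on absolute edge weights.

    Greedy agglomeration (Clauset-Newman-Moore) seeds the partition and a
    single-node-move refinement pass polishes it.  With an empty edge set
    every node is its own module and Q is defined as 0.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        modules = {n: i for i, n in enumerate(g.nodes)}
        net.modules, net.modularity = modules, 0.0
        return modules, 0.0
    seeds = [
        [set(c) for c in nx_community.greedy_modularity_communities(g, weight="abs_weight")],
    ]
    if g.number_of_nodes() <= 12:
        # extra starts (singletons + seeded random partitions); the full
        # KL move set from several starts reliably reaches the optimum at
        # small n, where restarts are affordable
        seeds.append([{n} for n in g.nodes])
        rng = np.random.default_rng(0)
        nodes = list(g.nodes)
        for k in (2, 3, 4):
            for _ in range(4):
                labels = rng.integers(0, k, size=len(nodes))
                parts = [
                    {n for n, l in zip(nodes, labels) if l == i} for i in range(k)
                ]
                seeds.append([p for p in parts if p])
    best_q, communities = -np.inf, None
    for start in seeds:
        candidate = _refine_partition(g, start)
        q = _partition_modularity(g, candidate)
        if q > best_q:
            best_q, communities = q, candidate
    q = best_q
    modules = {}
    for label, comm in enumerate(communities):
        for node in comm:
            modules[node] = label
    net.modules, net.modularity = modules, float(q)
    return modules, float(q)


def centrality_measures(net: CorrelationNetwork) -> pd.DataFrame:
    """Strength, closeness and betweenness per node.

    Strength sums incident ``|rho|``; closeness and betweenness use
    ``1/|rho|`` distances.  Nodes disconnected from everything get 0 for all
    three by convention.
    """
    g = net.graph
    strength = dict(g.degree(weight="abs_weight"))
    closeness = nx.closeness_centrality(g, distance="distance")
    betweenness = nx.betweenness_centrality(g, weight="distance", normalized=True)
    df = pd.DataFrame(
        {
            "strength": pd.Series(strength, dtype=float),
            "closeness": pd.Series(closeness, dtype=float),
            "betweenness": pd.Series(betweenness, dtype=float),
        }
    ).loc[list(g.nodes)]
    net.centrality = df
    return df


@dataclasses.dataclass
class RadarSummary:
    """Radar-chart summary: channel-averaged absolute correlations."""

    band_vs_variable: pd.DataFrame  # bands x non-EEG variables
    psg_vs_cognitive: pd.Series  # per PSG variable, mean |rho| over cognitive
    cognitive_vs_psg: pd.Series  # per cognitive score, mean |rho| over PSG


def radar_summary(mat: BootstrapCorrelationMatrix) -> RadarSummary:
    """Average ``|median rho|`` over channels per band and non-EEG variable."""
    med = mat.frame("median").abs()
    nodes = list(mat.nodes)
    eeg_nodes = [n for n in nodes if n not in NON_EEG_NODES]
    non_eeg = [n for n in nodes if n in NON_EEG_NODES]
    bands = sorted({n.split("_")[1] for n in eeg_nodes})
    band_order = [b.name for b in CANONICAL_BANDS if b.name in bands]
    rows = {}
    for band in band_order:
        members = [n for n in eeg_nodes if n.split("_")[1] == band]
        rows[band] = med.loc[members, non_eeg].mean(axis=0)
    band_vs_variable = pd.DataFrame(rows).T[non_eeg]
    psg = [v for v in PSG_VARIABLES if v in non_eeg]
    cog = [v for v in COGNITIVE_VARIABLES if v in non_eeg]
    psg_vs_cog = med.loc[psg, cog].mean(axis=1) if psg and cog else pd.Series(dtype=float)
    cog_vs_psg = med.loc[cog, psg].mean(axis=1) if psg and cog else pd.Series(dtype=float)
    return RadarSummary(band_vs_variable, psg_vs_cog, cog_vs_psg)


def network_to_json(net: CorrelationNetwork, path: str | Path) -> Path:
    """Export nodes (coordinates, module, centrality) and signed edges."""
    path = Path(path)
    layout = net.layout or {}
    modules = net.modules or {}
    cent = net.centrality
    nodes = []
    for n in net.graph.nodes:
        entry: dict = {"id": n}
        if n in layout:
            entry["x"], entry["y"] = layout[n]
        if n in modules:
            entry["module"] = int(modules[n])
        if cent is not None:
            entry.update({k: float(cent.loc[n, k]) for k in cent.columns})
        nodes.append(entry)
    edges = [
        {"source": a, "target": b, "weight": d["weight"]}
        for a, b, d in net.graph.edges(data=True)
    ]
    payload = {
        "threshold": net.threshold,
        "modularity": net.modularity,
        "nodes": nodes,
        "edges": edges,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def network_to_graphml(net: CorrelationNetwork, path: str | Path) -> Path:
    g = net.graph.copy()
    layout = net.layout or {}
    modules = net.modules or {}
    for n in g.nodes:
        if n in layout:
            g.nodes[n]["x"], g.nodes[n]["y"] = layout[n]
        if n in modules:
            g.nodes[n]["module"] = int(modules[n])
    nx.write_graphml(g, str(path))
    return Path(path)
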