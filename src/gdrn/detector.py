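"""Group-difference detection: ranked edges and regions.

Given per-group collections of (generated or observed) brain networks, the
detector compares two groups through the entrywise absolute difference of
their mean networks.  Every region pair (i, j), i < j, receives a score
|A_ij - B_ij|; region scores aggregate the incident edge scores.  Outputs
are deterministic ranked tables — by default the top 20 edges and top 15
regions per comparison — plus a thresholded edge set.

Group means are taken on the modelling scale (Fisher z by default) and
mapped back to correlations, which keeps averaging consistent with the
diffusion model's geometry.  A two-sample t-statistic per edge across the
individual matrices is available as an alternative difference statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import (
    AtlasLabels,
    ConnectivityMatrix,
    fisher_z,
    inverse_fisher_z,
    upper_indices,
)

__all__ = [
    "EdgeScoreTable",
    "RegionScoreTable",
    "group_mean_network",
    "edge_difference_scores",
    "edge_ttest_scores",
    "top_k_edges",
    "region_scores",
    "top_k_regions",
    "apply_threshold",
    "run_comparison",
]


def _sorted_edges(df: pd.DataFrame) -> pd.DataFrame:
    # descending score; deterministic (i, j) lexicographic order on ties
    df = df.sort_values(["score", "i", "j"], ascending=[False, True, True], kind="mergesort")
    return df.reset_index(drop=True)


@dataclass
class EdgeScoreTable:
    """Ranked group-difference scores per edge (upper triangle, i < j)."""

    df: pd.DataFrame  # columns: i, j, score
    comparison: str

    def __post_init__(self) -> None:
        df = self.df[["i", "j", "score"]].copy()
        if (df["i"] >= df["j"]).any():
            raise ValueError("edges must satisfy i < j")
        if df.duplicated(["i", "j"]).any():
            raise ValueError("duplicate edge pairs")
        if (df["score"] < 0).any():
            raise ValueError("edge scores must be non-negative")
        self.df = _sorted_edges(df)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class RegionScoreTable:
    """Ranked group-difference scores per region."""

    df: pd.DataFrame  # columns: index, abbreviation, name, score
    comparison: str

    def __post_init__(self) -> None:
        df = self.df[["index", "abbreviation", "name", "score"]].copy()
        if df["index"].duplicated().any():
            raise ValueError("duplicate region rows")
        if (df["score"] < 0).any():
            raise ValueError("region scores must be non-negative")
        df = df.sort_values(["score", "index"], ascending=[False, True], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


def group_mean_network(
    samples: Sequence[ConnectivityMatrix], transform: str = "fisher_z"
) -> ConnectivityMatrix:
    """Entrywise mean network of one group, averaged on the modelling scale.

    With ``transform='fisher_z'`` matrices are atanh-transformed, averaged and
    mapped back through tanh; ``'none'`` averages raw correlations.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    sizes = {fc.n_regions for fc in samples}
    if len(sizes) > 1:
        raise ValueError("matrices must share dimensions")
    if transform == "fisher_z":
        stack = np.stack([fisher_z(fc) for fc in samples])
        mean = inverse_fisher_z(stack.mean(axis=0))
    elif transform == "none":
        mean = np.stack([fc.values for fc in samples]).mean(axis=0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    mean = np.clip((mean + mean.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(
        mean, list(samples[0].region_indices), "group_mean", samples[0].group
    )


def _edge_table(scores: np.ndarray, region_indices: Sequence[int], comparison: str) -> EdgeScoreTable:
    iu, ju = upper_indices(scores.shape[0])
    idx = np.asarray(region_indices)
    df = pd.DataFrame({"i": idx[iu], "j": idx[ju], "score": scores[iu, ju]})
    return EdgeScoreTable(df, comparison)


def edge_difference_scores(
    A: ConnectivityMatrix, B: ConnectivityMatrix, comparison: str
) -> EdgeScoreTable:
    """Score every edge by the absolute group-mean difference |A_ij - B_ij|."""
    if A.n_regions != B.n_regions:
        raise ValueError("matrices must share dimensions")
    return _edge_table(np.abs(A.values - B.values), A.region_indices, comparison)


def edge_ttest_scores(
    samples_a: Sequence[ConnectivityMatrix],
    samples_b: Sequence[ConnectivityMatrix],
    comparison: str,
) -> EdgeScoreTable:
    """Alternative statistic: |two-sample Welch t| per edge on the Fisher-z
    scale across individual matrices."""
    from scipy import stats

    za = np.stack([fisher_z(fc) for fc in samples_a])
    zb = np.stack([fisher_z(fc) for fc in samples_b])
    t, _ = stats.ttest_ind(za, zb, axis=0, equal_var=False)
    t = np.nan_to_num(np.abs(t))
    return _edge_table(t, samples_a[0].region_indices, comparison)


def top_k_edges(table: EdgeScoreTable, k: int = 20) -> EdgeScoreTable:
    """First k rows of the ranked edge table (whole table if k exceeds it)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return EdgeScoreTable(table.df.head(k).copy(), table.comparison)


def region_scores(edges: EdgeScoreTable, atlas: AtlasLabels) -> RegionScoreTable:
    """Region score = sum of the scores of all edges incident to the region."""
    atlas_ix = set(atlas.indices)
    totals: dict[int, float] = {e.index: 0.0 for e in atlas.entries}
    for i, j, s in edges.df[["i", "j", "score"]].itertuples(index=False):
        if i not in atlas_ix or j not in atlas_ix:
            raise KeyError(f"edge ({i}, {j}) references a region missing from the atlas")
        totals[int(i)] += float(s)
        totals[int(j)] += float(s)
    rows = [
        {
            "index": e.index,
            "abbreviation": e.abbreviation,
            "name": e.full_name,
            "score": totals[e.index],
        }
        for e in atlas.entries
    ]
    return RegionScoreTable(pd.DataFrame(rows), edges.comparison)


def top_k_regions(table: RegionScoreTable, k: int = 15) -> RegionScoreTable:
    """First k rows of the ranked region table."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return RegionScoreTable(table.df.head(k).copy(), table.comparison)


def apply_threshold(table: EdgeScoreTable, tau: float) -> EdgeScoreTable:
    """Keep edges with score >= tau."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return EdgeScoreTable(table.df[table.df["score"] >= tau].copy(), table.comparison)


# ---------------------------------------------------------------------------
# File output (BrainNet-Viewer-compatible .edge / .node plus ranked CSVs)
# ---------------------------------------------------------------------------


def write_edge_file(
    table: EdgeScoreTable, atlas: AtlasLabels, path: str | Path
) -> None:
    """n x n weighted matrix, tab-separated, zeros off the surviving edge set."""
    order = {idx: pos for pos, idx in enumerate(atlas.indices)}
    n = len(order)
    mat = np.zeros((n, n))
    for i, j, s in table.df[["i", "j", "score"]].itertuples(index=False):
        mat[order[int(i)], order[int(j)]] = s
        mat[order[int(j)], order[int(i)]] = s
    np.savetxt(path, mat, fmt="%.12g", delimiter="\t")


def write_node_file(
    table: RegionScoreTable, path: str | Path, coords: dict[int, tuple] | None = None
) -> None:
    """x y z color size label rows; coordinates zero-filled unless supplied."""
    with open(path, "w") as fh:
        for row in table.df.itertuples(index=False):
            x, y, z = (coords or {}).get(int(row.index), (0.0, 0.0, 0.0))
            fh.write(
                f"{x:g}\t{y:g}\t{z:g}\t1\t{row.score:.12g}\t{row.abbreviation}\n"
            )


def write_edge_csv(table: EdgeScoreTable, atlas: AtlasLabels, path: str | Path) -> None:
    df = table.df.copy()
    df["abbrev_i"] = [atlas.entry(int(i)).abbreviation for i in df["i"]]
    df["abbrev_j"] = [atlas.entry(int(j)).abbreviation for j in df["j"]]
    df[["i", "j", "abbrev_i", "abbrev_j", "score"]].to_csv(
        path, index=False, float_format="%.12g"
    )


def write_region_csv(table: RegionScoreTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format="%.12g")


def run_comparison(
    samples_a: Sequence[ConnectivityMatrix],
    samples_b: Sequence[ConnectivityMatrix],
    atlas: AtlasLabels,
    k_edges: int = 20,
    k_regions: int = 15,
    tau: float | None = None,
    transform: str = "fisher_z",
    statistic: str = "mean_diff",
    out_dir: str | Path | None = None,
) -> tuple[EdgeScoreTable, RegionScoreTable]:
    """End-to-end comparison of two groups.

    Computes group means, edge difference scores, incident-region scores,
    the top-k tables and the tau-thresholded edge set; when ``out_dir`` is
    given, writes ranked CSVs plus .edge/.node exports there.  ``tau``
    defaults to the 99th percentile of the edge-score distribution.
    Returns the top-k edge and region tables.
    """
    ga, gb = samples_a[0].group, samples_b[0].group
    if ga == gb:
        raise ValueError(f"both sample sets belong to group {ga!r}")
    comparison = f"{ga}_vs_{gb}"
    if statistic == "mean_diff":
        mean_a = group_mean_network(samples_a, transform)
        mean_b = group_mean_network(samples_b, transform)
        edges = edge_difference_scores(mean_a, mean_b, comparison)
    elif statistic == "ttest":
        edges = edge_ttest_scores(samples_a, samples_b, comparison)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if tau is None:
        tau = float(np.percentile(edges.df["score"], 99))
    regions = region_scores(edges, atlas)
    top_e = top_k_edges(edges, k_edges)
    top_r = top_k_regions(regions, k_regions)
    surviving = apply_threshold(edges, tau)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_edge_csv(top_e, atlas, out / f"{comparison}_top_edges.csv")
        write_region_csv(top_r, out / f"{comparison}_top_regions.csv")
        write_edge_csv(surviving, atlas, out / f"{comparison}_thresholded_edges.csv")
        write_edge_file(surviving, atlas, out / f"{comparison}.edge")
        write_node_file(regions, out / f"{comparison}.node")
    return top_e, top_r
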