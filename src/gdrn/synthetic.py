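"""Synthetic three-group cohorts with planted differential edges.

Stands in for the (undeposited) rat fMRI cohort: three exposure groups —
saline control, low-nicotine and high-nicotine — whose subjects' region
time series are drawn from group-specific correlation structures.  The
saline group uses a block-structured base correlation matrix; the nicotine
groups additionally shift a known set of "planted" edges by a configurable
effect size delta-r.  Planted edges are the ground truth against which
detector recovery is scored.

Subject-to-subject variability has two controllable sources: a random
positive-definite-preserving jitter of the group correlation matrix (scale
``sigma_subj``) and finite-sample Pearson noise from a limited number of
timepoints.  Rows are i.i.d. multivariate normal draws — temporal
autocorrelation of real BOLD signals is deliberately not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .connectome import (
    AtlasLabels,
    ConnectivityMatrix,
    TimeSeriesMatrix,
    GROUPS,
    compute_fc,
    default_atlas,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "nearest_correlation",
    "build_group_correlation",
    "simulate_subject_timeseries",
    "generate_cohort",
    "recovery_score",
]

#: Eigenvalues are clipped at this floor when repairing indefinite matrices.
PD_EIG_FLOOR = 1e-6


@dataclass
class SyntheticSpec:
    """Configuration of a synthetic cohort.

    Defaults give the package's standard test fixture: 10 regions, 40
    subjects per group, 200 timepoints, 10 planted edges with delta-r 0.4 in
    the high group (0.2 in the low group), block-structured base correlation
    (blocks of 5 regions at r = 0.3) and mild subject jitter.
    """

    n_regions: int = 10
    n_subjects_per_group: int = 40
    n_timepoints: int = 200
    block_size: int = 5
    base_within: float = 0.3
    n_planted: int = 10
    delta_high: float = 0.4
    delta_low: float = 0.2
    sigma_subj: float = 0.05
    planted_edges: dict[str, list[tuple[int, int, float]]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        n_pairs = self.n_regions * (self.n_regions - 1) // 2
        if self.planted_edges is None and self.n_planted > n_pairs:
            raise ValueError("more planted edges than region pairs")
        for g, edges in (self.planted_edges or {}).items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            for i, j, dr in edges:
                if not (0 <= i < j < self.n_regions):
                    raise ValueError(f"planted edge ({i}, {j}) not in upper triangle")
                if abs(self.base_corr_entry(i, j) + dr) >= 1:
                    raise ValueError(f"planted edge ({i}, {j}) leaves (-1, 1)")

    def base_corr_entry(self, i: int, j: int) -> float:
        return self.base_within if i // self.block_size == j // self.block_size else 0.0

    def resolve_planted(self, rng: np.random.Generator) -> dict[str, list[tuple[int, int, float]]]:
        """Planted edges per group; drawn from the seed stream when not given."""
        if self.planted_edges is not None:
            return {g: [tuple(e) for e in v] for g, v in self.planted_edges.items()}
        iu, ju = np.triu_indices(self.n_regions, k=1)
        planted = {}
        for group, delta in (("low", self.delta_low), ("high", self.delta_high)):
            pick = rng.choice(len(iu), size=self.n_planted, replace=False)
            planted[group] = [(int(iu[p]), int(ju[p]), float(delta)) for p in pick]
        return planted


@dataclass
class GroundTruth:
    """Planted edges and the exact (post-projection) group correlations."""

    planted: dict[str, list[tuple[int, int, float]]]
    group_corr: dict[str, np.ndarray]

    def planted_for(self, comparison: str) -> set[tuple[int, int]]:
        """Ground-truth differential edges for a ``<a>_vs_<b>`` comparison:
        edges whose planted shift differs between the two groups."""
        a, b = comparison.split("_vs_")
        deltas: dict[tuple[int, int], list[float]] = {}
        for pos, g in enumerate((a, b)):
            for i, j, dr in self.planted.get(g, []):
                deltas.setdefault((i, j), [0.0, 0.0])[pos] = dr
        return {e for e, (da, db) in deltas.items() if da != db}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": {g: [list(e) for e in v] for g, v in self.planted.items()},
            "group_corr": {g: m.tolist() for g, m in self.group_corr.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted={g: [tuple(e) for e in v] for g, v in payload["planted"].items()},
            group_corr={g: np.asarray(m) for g, m in payload["group_corr"].items()},
        )


# ---------------------------------------------------------------------------
# Correlation-matrix construction
# ---------------------------------------------------------------------------


def nearest_correlation(mat: np.ndarray, max_iter: int = 100) -> np.ndarray:
    """Project a symmetric matrix to a nearby positive-definite correlation
    matrix by eigenvalue clipping followed by diagonal renormalization."""
    a = (np.asarray(mat, float) + np.asarray(mat, float).T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        if w.min() >= PD_EIG_FLOOR / 2 and np.allclose(np.diag(a), 1.0, atol=1e-12):
            return a
        w = np.clip(w, PD_EIG_FLOOR, None)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
    raise ValueError("positive-definite projection did not converge")


def build_group_correlation(
    spec: SyntheticSpec,
    group: str,
    planted: dict[str, list[tuple[int, int, float]]] | None = None,
) -> np.ndarray:
    """Group correlation matrix: block base plus the group's planted shifts,
    projected to the nearest positive-definite correlation matrix."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    n = spec.n_regions
    base = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            base[i, j] = base[j, i] = spec.base_corr_entry(i, j)
    for i, j, dr in (planted or {}).get(group, []):
        base[i, j] += dr
        base[j, i] += dr
    return nearest_correlation(base)


def simulate_subject_timeseries(
    corr: np.ndarray,
    n_timepoints: int,
    sigma_subj: float,
    seed: int,
    subject_id: str = "subject",
    group: str = "saline",
    region_indices: Sequence[int] | None = None,
) -> TimeSeriesMatrix:
    """Draw one subject's time series from a jittered group correlation.

    With ``sigma_subj > 0`` the group matrix is perturbed by a symmetric
    Gaussian jitter (re-projected to a valid correlation matrix); rows are
    then i.i.d. multivariate normal with that subject-level correlation.
    """
    corr = np.asarray(corr, float)
    n = corr.shape[0]
    w = np.linalg.eigvalsh(corr)
    if w.min() <= 0:
        raise ValueError("group correlation matrix is not positive definite")
    rng = np.random.default_rng(seed)
    subj_corr = corr
    if sigma_subj > 0:
        e = rng.standard_normal((n, n)) * sigma_subj
        pert = (e + e.T) / 2.0
        np.fill_diagonal(pert, 0.0)
        subj_corr = nearest_correlation(corr + pert)
    chol = np.linalg.cholesky(subj_corr)
    values = rng.standard_normal((n_timepoints, n)) @ chol.T
    indices = list(region_indices) if region_indices is not None else list(range(n))
    return TimeSeriesMatrix(values, indices, subject_id, group)


def generate_cohort(
    spec: SyntheticSpec, out_dir: str | Path | None = None
) -> tuple[dict[str, list[TimeSeriesMatrix]], dict[str, list[ConnectivityMatrix]], GroundTruth]:
    """Generate the full three-group cohort.

    Returns per-group time series, per-group FC matrices (via Pearson
    correlation) and the ground truth; optionally writes everything (plus a
    truncated atlas and ground_truth.json) under ``out_dir``.
    """
    rng = np.random.default_rng(spec.seed)
    planted = spec.resolve_planted(rng)
    group_corr = {g: build_group_correlation(spec, g, planted) for g in GROUPS}
    truth = GroundTruth(planted=planted, group_corr=group_corr)

    ts_by_group: dict[str, list[TimeSeriesMatrix]] = {g: [] for g in GROUPS}
    fc_by_group: dict[str, list[ConnectivityMatrix]] = {g: [] for g in GROUPS}
    for g in GROUPS:
        for s in range(spec.n_subjects_per_group):
            subj_seed = int(rng.integers(0, 2**31 - 1))
            ts = simulate_subject_timeseries(
                group_corr[g],
                spec.n_timepoints,
                spec.sigma_subj,
                subj_seed,
                subject_id=f"{g}_{s:03d}",
                group=g,
            )
            ts_by_group[g].append(ts)
            fc_by_group[g].append(compute_fc(ts))

    if out_dir is not None:
        from . import io_cli

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        atlas = default_atlas(spec.n_regions)
        atlas.to_file(out / "atlas.tsv")
        truth.to_json(out / "ground_truth.json")
        for g in GROUPS:
            gdir = out / g
            gdir.mkdir(exist_ok=True)
            for ts, fc in zip(ts_by_group[g], fc_by_group[g]):
                io_cli.write_timeseries(ts, gdir / f"{ts.subject_id}_ts.csv")
                io_cli.write_connectivity(fc, gdir / f"{fc.subject_id}_fc.tsv")
    return ts_by_group, fc_by_group, truth


def recovery_score(detected, truth: GroundTruth, k: int) -> float:
    """Fraction of planted edges found in the top-k of a detected edge table.

    The comparison label on the table selects the relevant planted set.
    """
    planted = truth.planted_for(detected.comparison)
    if not planted:
        raise ValueError(f"ground truth has no planted edges for {detected.comparison!r}")
    top = detected.df.head(k)
    found = {(int(i), int(j)) for i, j in top[["i", "j"]].itertuples(index=False)}
    return len(found & planted) / len(planted)
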