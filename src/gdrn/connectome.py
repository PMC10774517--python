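"""Functional connectivity construction and atlas handling.

A subject's brain activity arrives as a region-by-region time-series matrix
(rows = timepoints, columns = atlas regions).  The functional connectivity
(FC) matrix is the sample Pearson correlation between region time series: a
symmetric matrix with unit diagonal and entries in [-1, 1], viewed as a
weighted brain network whose nodes are atlas regions.

Because downstream generative modelling adds unbounded Gaussian noise, the
module also provides the Fisher z-transform (atanh), mapping correlations to
an unbounded scale, and strictly-upper-triangle vectorization, the flat
representation every model in this package operates on.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GROUPS",
    "AtlasEntry",
    "AtlasLabels",
    "TimeSeriesMatrix",
    "ConnectivityMatrix",
    "default_atlas",
    "load_timeseries",
    "compute_fc",
    "fisher_z",
    "inverse_fisher_z",
    "vectorize_upper",
    "devectorize_upper",
    "upper_indices",
]

#: Canonical exposure-group order (also the tie-break order for classification).
GROUPS = ("saline", "low", "high")

#: Columns with standard deviation below this are treated as degenerate.
VARIANCE_TOL = 1e-12

#: Correlations are clipped to +/-(1 - FISHER_CLIP) before atanh.
FISHER_CLIP = 1e-7


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------

# Named regions of the 150-region Wistar rat atlas used for reporting.
# (index, abbreviation, full name); hemisphere is parsed from the suffix.
_NAMED_REGIONS: tuple[tuple[int, str, str], ...] = (
    (14, "GD_R", "Granular and dysgranular insular cortex_R"),
    (18, "MEnt_R", "Medial entorhinal cortex_R"),
    (24, "RSD_R", "Retrosplenial dysgranular cortex_R"),
    (25, "RSGb_R", "Retrosplenial granular cortex, b region_R"),
    (26, "RSGc_R", "Retrosplenial granular cortex, c region_R"),
    (34, "S1Sh_R", "Primary somatosensory cortex, shoulder region_R"),
    (41, "V1M_R", "Primary visual cortex, monocular area_R"),
    (48, "AIV_L", "Agranular insular cortex, ventral part_L"),
    (56, "DLEnt_L", "Dorsolateral entorhinal cortex_L"),
    (57, "Ect_L", "Ectorhinal cortex_L"),
    (64, "MEnt_L", "Medial entorhinal cortex_L"),
    (67, "PtPC_L", "Parietal cortex, posterior area, caudal part_L"),
    (71, "RSGb_L", "Retrosplenial granular cortex, b region_L"),
    (72, "RSGc_L", "Retrosplenial granular cortex, c region_L"),
    (73, "S1_L", "Primary somatosensory cortex_L"),
    (80, "S1Sh_L", "Primary somatosensory cortex, shoulder region_L"),
    (87, "V1M_L", "Primary visual cortex, monocular area_L"),
    (103, "SN_L", "Substantia nigra_L"),
    (104, "AC_R", "Anterior commissure_R"),
    (105, "AC_L", "Anterior commissure_L"),
    (110, "DD_R", "Diagonal domain_R"),
    (111, "DD_L", "Diagonal domain_L"),
    (132, "PA_R", "Preoptic area_R"),
    (133, "PA_L", "Preoptic area_L"),
    (136, "Cer_R", "Cerebellum_R"),
    (137, "Cer_L", "Cerebellum_L"),
    (140, "BNST_R", "Bed nucleus of the stria terminalis_R"),
    (141, "BNST_L", "Bed nucleus of the stria terminalis_L"),
    (142, "Pit_R", "Pituitary_R"),
    (143, "Pit_L", "Pituitary_L"),
    (146, "OP_R", "Optic pathways_R"),
    (148, "PG_R", "Pineal gland_R"),
    (149, "PG_L", "Pineal gland_L"),
)


def _hemisphere_from_suffix(abbrev: str) -> str:
    if abbrev.endswith("_L"):
        return "L"
    if abbrev.endswith("_R"):
        return "R"
    return "midline"


@dataclass(frozen=True)
class AtlasEntry:
    index: int
    abbreviation: str
    full_name: str
    hemisphere: str  # "L", "R" or "midline"


@dataclass
class AtlasLabels:
    """Ordered atlas region labels.

    Indices must be unique and non-negative; abbreviation and name non-empty.
    """

    entries: list[AtlasEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for e in self.entries:
            if e.index < 0:
                raise ValueError(f"negative atlas index {e.index}")
            if e.index in seen:
                raise ValueError(f"duplicate atlas index {e.index}")
            seen.add(e.index)
            if not e.abbreviation or not e.full_name:
                raise ValueError(f"empty label for atlas index {e.index}")
            if e.hemisphere not in ("L", "R", "midline"):
                raise ValueError(f"bad hemisphere {e.hemisphere!r} for index {e.index}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def indices(self) -> list[int]:
        return [e.index for e in self.entries]

    def entry(self, index: int) -> AtlasEntry:
        for e in self.entries:
            if e.index == index:
                return e
        raise KeyError(f"atlas has no region with index {index}")

    def resolve(self, token: str) -> int:
        """Map a header token (numeric index or abbreviation) to a region index."""
        tok = token.strip()
        try:
            idx = int(tok)
        except ValueError:
            for e in self.entries:
                if e.abbreviation == tok:
                    return e.index
            raise KeyError(f"unknown region label {tok!r}") from None
        if idx not in set(self.indices):
            raise KeyError(f"unknown region index {idx}")
        return idx

    # -- text format: index<TAB>abbrev<TAB>name<TAB>hemisphere ---------------

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for e in self.entries:
                w.writerow([e.index, e.abbreviation, e.full_name, e.hemisphere])

    @classmethod
    def from_file(cls, path: str | Path) -> "AtlasLabels":
        entries = []
        with open(path) as fh:
            for ln, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) != 4:
                    raise ValueError(f"{path}: line {ln}: expected 4 tab-separated fields")
                entries.append(AtlasEntry(int(row[0]), row[1], row[2], row[3]))
        return cls(entries)


def default_atlas(n_regions: int = 150) -> AtlasLabels:
    """The shipped 150-region rat atlas.

    Regions that appear in the package's reporting tables carry their printed
    abbreviation and anatomical name; the remaining indices get placeholder
    ROI labels.  Smaller ``n_regions`` truncates (useful for synthetic tests).
    """
    named = {idx: (ab, name) for idx, ab, name in _NAMED_REGIONS}
    entries = []
    for i in range(n_regions):
        if i in named:
            ab, name = named[i]
            entries.append(AtlasEntry(i, ab, name, _hemisphere_from_suffix(ab)))
        else:
            entries.append(AtlasEntry(i, f"ROI{i:03d}", f"Region {i:03d}", "midline"))
    return AtlasLabels(entries)


# ---------------------------------------------------------------------------
# Subject-level containers
# ---------------------------------------------------------------------------


@dataclass
class TimeSeriesMatrix:
    """One subject's region time series (timepoints x regions)."""

    values: np.ndarray
    region_indices: list[int]
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D matrix")
        t, r = self.values.shape
        if r != len(self.region_indices):
            raise ValueError("column count does not match region_indices")
        if t < 3:
            raise ValueError("at least 3 timepoints are required for Pearson correlation")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains missing/non-finite values")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        sd = self.values.std(axis=0)
        bad = np.nonzero(sd < VARIANCE_TOL)[0]
        if bad.size:
            names = ", ".join(str(self.region_indices[i]) for i in bad)
            raise ValueError(f"zero-variance time series for region(s): {names}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """A symmetric Pearson FC matrix with unit diagonal (the brain network)."""

    values: np.ndarray
    region_indices: list[int]
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if v.shape[0] != len(self.region_indices):
            raise ValueError("matrix size does not match region_indices")
        if not np.array_equal(v, v.T):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("connectivity matrix diagonal must equal 1")
        if v.min() < -1.0 or v.max() > 1.0:
            raise ValueError("connectivity entries must lie in [-1, 1]")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def load_timeseries(
    path: str | Path, atlas: AtlasLabels, subject_id: str, group: str
) -> TimeSeriesMatrix:
    """Read a delimited time-series file and normalize columns to atlas order.

    The header row holds region identifiers (numeric atlas indices or
    abbreviations); each subsequent row is one timepoint.  Comma and tab
    delimiters are both accepted.
    """
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if not text:
        raise ValueError(f"{path}: empty file")
    delim = "\t" if "\t" in text[0] else ","
    header = [tok.strip() for tok in text[0].split(delim)]
    try:
        indices = [atlas.resolve(tok) for tok in header]
    except KeyError as exc:
        raise ValueError(f"{path}: header: {exc.args[0]}") from None
    rows = []
    for ln, line in enumerate(text[1:], start=2):
        fields = line.split(delim)
        if len(fields) != len(header):
            raise ValueError(f"{path}: line {ln}: expected {len(header)} fields")
        try:
            rows.append([float(x) for x in fields])
        except ValueError:
            raise ValueError(f"{path}: line {ln}: non-numeric value") from None
    values = np.asarray(rows, dtype=float)
    # normalize to atlas order
    order = np.argsort([atlas.indices.index(i) for i in indices], kind="stable")
    values = values[:, order]
    indices = [indices[i] for i in order]
    return TimeSeriesMatrix(values, indices, subject_id, group)


def compute_fc(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Pearson correlation between all pairs of region time series.

    Symmetry and the unit diagonal are enforced exactly; entries are clipped
    to [-1, 1] to absorb floating-point overshoot.
    """
    sd = ts.values.std(axis=0)
    bad = np.nonzero(sd < VARIANCE_TOL)[0]
    if bad.size:
        names = ", ".join(str(ts.region_indices[i]) for i in bad)
        raise ValueError(f"degenerate (constant) region(s): {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    # snap float-error residue on perfectly (anti)correlated pairs
    r[r > 1.0 - 1e-12] = 1.0
    r[r < -1.0 + 1e-12] = -1.0
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(r, list(ts.region_indices), ts.subject_id, ts.group)


def fisher_z(fc: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Fisher z-transform: atanh of off-diagonal correlations, 0 on the diagonal.

    Values are clipped to +/-(1 - 1e-7) first so the map is always finite.
    """
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    z = np.arctanh(np.clip(v, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP))
    np.fill_diagonal(z, 0.0)
    return z


def inverse_fisher_z(z: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fisher_z` (tanh); diagonal restored to 1."""
    r = np.tanh(np.asarray(z, dtype=float))
    np.fill_diagonal(r, 1.0)
    return r


def upper_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the strictly upper triangle, row-major order."""
    return np.triu_indices(n, k=1)


def vectorize_upper(fc: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Flatten the strictly upper triangle to a length n(n-1)/2 vector."""
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    iu, ju = upper_indices(v.shape[0])
    return v[iu, ju].copy()


def _square_from_upper(vec: np.ndarray, diagonal: float) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    m = vec.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number n(n-1)/2")
    out = np.full((n, n), diagonal, dtype=float)
    iu, ju = upper_indices(n)
    out[iu, ju] = vec
    out[ju, iu] = vec
    return out


def devectorize_upper(
    vec: np.ndarray,
    region_indices: Sequence[int],
    subject_id: str = "",
    group: str = "saline",
    clip: bool = True,
) -> ConnectivityMatrix:
    """Rebuild a ConnectivityMatrix from an upper-triangle vector.

    The diagonal is restored to 1; with ``clip`` (default) entries are clipped
    into [-1, 1] so arbitrary model output always yields a valid matrix.
    """
    mat = _square_from_upper(vec, diagonal=1.0)
    n = mat.shape[0]
    if len(region_indices) != n:
        raise ValueError(
            f"vector implies {n} regions but {len(region_indices)} region indices given"
        )
    if clip:
        mat = np.clip(mat, -1.0, 1.0)
        np.fill_diagonal(mat, 1.0)
    return ConnectivityMatrix(mat, list(region_indices), subject_id, group)


def square_from_upper(vec: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
    """Symmetric square matrix from an upper-triangle vector (plain array)."""
    return _square_from_upper(vec, diagonal)
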