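"""Trial-level power tables and negative-coupling distance networks.

This module holds the data model for per-subject, per-condition trial x ROI
power tables and the operations that turn them into distance networks:

* :func:`equalize_trials` -- subsample the larger of two trial tables so both
  conditions contribute the same number of observations to a correlation.
* :func:`pearson_matrix` -- across-trial product-moment correlation between
  every pair of ROI columns of two tables.
* :func:`negative_distance` -- keep only negative couplings and map them to
  distances in [0, 1]; non-negative (and undefined) entries become the
  non-edge sentinel 1.
* :func:`bipartite_network` / :func:`within_frequency_distance` -- convenience
  pipelines producing labeled distance-matrix objects.

Distances are asymmetric for the bipartite (cross-band) network because the
row and column nodes live in different measurement sets, even though they
share ROI labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

__all__ = [
    "CONDITIONS",
    "BAND_EPOCHS",
    "TrialPowerTable",
    "RoiNodeSet",
    "BipartiteDistanceMatrix",
    "SymmetricDistanceMatrix",
    "SubjectData",
    "equalize_trials",
    "pearson_matrix",
    "negative_distance",
    "bipartite_network",
    "within_frequency_distance",
]

CONDITIONS = ("R", "NR")
BAND_EPOCHS = ("cue_alpha", "item_gamma")

_NON_EDGE = 1.0  # sentinel distance for "no negative coupling"


@dataclass
class TrialPowerTable:
    """One subject/condition/band-epoch table of normalized source power.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    condition : {"R", "NR"}
        Task condition (Remember / No-Remember).
    band_epoch : {"cue_alpha", "item_gamma"}
        Which band-epoch the power values belong to.
    roi_labels : sequence of str
        Ordered ROI column labels; must be unique.
    values : ndarray, shape (n_trials, n_rois)
        Normalized source power, one row per trial.  At least three trials
        are required (a correlation over fewer is meaningless).
    """

    subject_id: str
    condition: str
    band_epoch: str
    roi_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.band_epoch not in BAND_EPOCHS:
            raise ValueError(f"band_epoch must be one of {BAND_EPOCHS}, got {self.band_epoch!r}")
        self.roi_labels = tuple(str(x) for x in self.roi_labels)
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (n_trials, n_rois) array")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but {len(self.roi_labels)} roi_labels"
            )
        if self.values.shape[0] < 3:
            raise ValueError("a trial table needs at least 3 trials")
        if not np.isfinite(self.values).all():
            raise ValueError("values contains non-finite entries")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def take_trials(self, indices: np.ndarray) -> "TrialPowerTable":
        """Return a copy restricted to the given trial rows (order preserved)."""
        return replace(self, values=self.values[np.asarray(indices)])


@dataclass(frozen=True)
class RoiNodeSet:
    """An ordered set of ROI node labels with a hemisphere tag per label.

    Labels follow the ``<name>.L`` / ``<name>.R`` suffix convention.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("ROI labels must be unique")
        for lab in self.labels:
            if not (lab.endswith(".L") or lab.endswith(".R")):
                raise ValueError(f"ROI label {lab!r} lacks a '.L'/'.R' hemisphere suffix")

    @property
    def hemispheres(self) -> tuple[str, ...]:
        return tuple(lab[-1] for lab in self.labels)

    def count(self, hemisphere: str) -> int:
        return sum(1 for h in self.hemispheres if h == hemisphere)

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_file(cls, path) -> "RoiNodeSet":
        labels = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    labels.append(line)
        return cls(tuple(labels))

    @classmethod
    def cortical_default(cls) -> "RoiNodeSet":
        """The packaged cerebral-cortex node list (38 labels per hemisphere)."""
        ref = resources.files("bgfilt.data").joinpath("aal_cortex_rois.txt")
        with resources.as_file(ref) as path:
            nodes = cls.from_file(path)
        if nodes.count("L") != 38 or nodes.count("R") != 38:
            raise RuntimeError("packaged ROI list is corrupt: expected 38 labels per hemisphere")
        return nodes


def _check_distance_range(values: np.ndarray) -> None:
    if values.size and (values.min() < 0.0 or values.max() > 1.0):
        raise ValueError("distances must lie in [0, 1]")


@dataclass
class BipartiteDistanceMatrix:
    """Asymmetric negative-coupling distances; rows and columns are disjoint
    node sets (row ROIs measured in one band-epoch, column ROIs in another).

    Diagonal entries are ordinary entries (intra-regional cross-band
    coupling) and are *not* forced to any value.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray
    n_trials_used: int = 0
    row_partition: str = "cue_alpha"
    col_partition: str = "item_gamma"

    def __post_init__(self) -> None:
        self.row_labels = tuple(self.row_labels)
        self.col_labels = tuple(self.col_labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match labels")
        _check_distance_range(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "BipartiteDistanceMatrix":
        return BipartiteDistanceMatrix(
            row_labels=self.col_labels,
            col_labels=self.row_labels,
            values=self.values.T.copy(),
            n_trials_used=self.n_trials_used,
            row_partition=self.col_partition,
            col_partition=self.row_partition,
        )


@dataclass
class SymmetricDistanceMatrix:
    """Within-band negative-coupling distances; self-distance fixed at 1
    (self-correlation is +1, hence a non-edge)."""

    labels: tuple[str, ...]
    values: np.ndarray
    n_trials_used: int = 0
    partition: str = "all"

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        p = len(self.labels)
        if self.values.shape != (p, p):
            raise ValueError("values shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.all(np.diag(self.values) == 1.0):
            raise ValueError("self-distances must equal 1")
        _check_distance_range(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SubjectData:
    """All four trial tables of one subject: {R, NR} x {cue_alpha, item_gamma}."""

    subject_id: str
    tables: dict

    def __post_init__(self) -> None:
        missing = [
            (c, b) for c in CONDITIONS for b in BAND_EPOCHS if (c, b) not in self.tables
        ]
        if missing:
            raise ValueError(f"subject {self.subject_id!r}: missing tables {missing}")
        labels = {t.roi_labels for t in self.tables.values()}
        if len(labels) != 1:
            raise ValueError(f"subject {self.subject_id!r}: roi_labels differ across tables")
        for c in CONDITIONS:
            if self.tables[(c, "cue_alpha")].n_trials != self.tables[(c, "item_gamma")].n_trials:
                raise ValueError(
                    f"subject {self.subject_id!r}: trial counts differ across band epochs of {c}"
                )

    def table(self, condition: str, band_epoch: str) -> TrialPowerTable:
        return self.tables[(condition, band_epoch)]

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return next(iter(self.tables.values())).roi_labels

    def n_trials(self, condition: str) -> int:
        return self.tables[(condition, "cue_alpha")].n_trials


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _equalize_indices(n_a: int, n_b: int, rng: np.random.Generator):
    """Kept-trial index arrays equalizing two tables to min(n_a, n_b) trials.

    The draw depends only on the generator state and the two sizes, so the
    same seed yields the same subsample for every band epoch of a condition
    pair.  Returns ``(idx_a, idx_b)``; the smaller side gets ``None``
    (kept verbatim).
    """
    n = min(n_a, n_b)
    if n_a > n:
        return np.sort(rng.choice(n_a, size=n, replace=False)), None
    if n_b > n:
        return None, np.sort(rng.choice(n_b, size=n, replace=False))
    return None, None


def equalize_trials(
    table_a: TrialPowerTable, table_b: TrialPowerTable, seed: int
) -> tuple[TrialPowerTable, TrialPowerTable]:
    """Equalize trial counts by randomly subsampling the larger table.

    The smaller table is returned unchanged; the larger is subsampled
    uniformly at random without replacement (trial order preserved within
    the kept subset).  The draw is reproducible under ``seed`` and depends
    only on the two trial counts, so calling once per band epoch with the
    same seed keeps the subsample consistent across epochs.
    """
    if table_a.roi_labels != table_b.roi_labels:
        raise ValueError("equalize_trials: roi_labels mismatch between tables")
    if table_a.band_epoch != table_b.band_epoch:
        raise ValueError("equalize_trials: band_epoch mismatch between tables")
    n = min(table_a.n_trials, table_b.n_trials)
    if n < 3:
        raise ValueError(f"equalize_trials: only {n} trials after equalization (need >= 3)")
    rng = np.random.default_rng(seed)
    idx_a, idx_b = _equalize_indices(table_a.n_trials, table_b.n_trials, rng)
    out_a = table_a if idx_a is None else table_a.take_trials(idx_a)
    out_b = table_b if idx_b is None else table_b.take_trials(idx_b)
    return out_a, out_b


def _pearson_raw(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-by-column Pearson correlation of two (n, p)/(n, q) arrays.

    Entries involving a zero-variance column come out as NaN (undefined);
    no silent substitution happens here.
    """
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    nx = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    ny = np.sqrt(np.einsum("ij,ij->j", yc, yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ yc) / np.outer(nx, ny)
    # guard against |r| drifting past 1 by floating-point error
    np.clip(r, -1.0, 1.0, out=r)
    return r


def pearson_matrix(x: TrialPowerTable, y: TrialPowerTable) -> np.ndarray:
    """Across-trial Pearson correlation between every (x column, y column).

    Returns an ``(x.n_rois, y.n_rois)`` array in [-1, 1].  Entries whose x
    or y column has zero variance are *undefined* and returned as NaN;
    downstream code must decide how to treat them (see
    :func:`negative_distance`).
    """
    if x.n_trials != y.n_trials:
        raise ValueError(
            "pearson_matrix: unequal trial counts "
            f"({x.n_trials} vs {y.n_trials}); run equalize_trials first"
        )
    if x.n_trials < 3:
        raise ValueError("pearson_matrix: need at least 3 trials")
    return _pearson_raw(x.values, y.values)


def _negative_distance_raw(r: np.ndarray) -> np.ndarray:
    """d = 1 - |r| on the negative branch, 1 elsewhere (NaN -> 1)."""
    d = np.where(r < 0, 1.0 + r, _NON_EDGE)  # 1 - |r| == 1 + r for r < 0
    return np.clip(d, 0.0, 1.0)


def negative_distance(r: np.ndarray, undefined_policy: str = "max_distance") -> np.ndarray:
    """Map a correlation matrix to negative-coupling distances in [0, 1].

    ``d = 1 - |r|`` where ``r < 0``; any non-negative relationship gets the
    maximum distance 1 (non-edge).  NaN entries (undefined correlations)
    map to 1 under ``undefined_policy="max_distance"`` (default) or raise
    under ``"strict"``.
    """
    r = np.asarray(r, dtype=float)
    undefined = np.isnan(r)
    if undefined.any():
        if undefined_policy == "strict":
            ii, jj = np.nonzero(undefined)
            raise ValueError(
                f"negative_distance: {undefined.sum()} undefined correlation entries, "
                f"first at ({ii[0]}, {jj[0]})"
            )
        if undefined_policy != "max_distance":
            raise ValueError(f"unknown undefined_policy {undefined_policy!r}")
    defined = ~undefined
    if defined.any() and (np.abs(r[defined]).max() > 1.0):
        raise ValueError("negative_distance: correlations must lie in [-1, 1]")
    return _negative_distance_raw(r)


def bipartite_network(
    x: TrialPowerTable,
    y: TrialPowerTable,
    undefined_policy: str = "max_distance",
) -> BipartiteDistanceMatrix:
    """Full cross-band pipeline: Pearson across trials, negative-only
    distance transform, labeled asymmetric matrix (rows = x ROIs,
    columns = y ROIs).  Diagonal (intra-regional) entries are retained."""
    r = pearson_matrix(x, y)
    d = negative_distance(r, undefined_policy)
    return BipartiteDistanceMatrix(
        row_labels=x.roi_labels,
        col_labels=y.roi_labels,
        values=d,
        n_trials_used=x.n_trials,
        row_partition=x.band_epoch,
        col_partition=y.band_epoch,
    )


def within_frequency_distance(
    x: TrialPowerTable, undefined_policy: str = "max_distance"
) -> SymmetricDistanceMatrix:
    """Within-band (non-time-delayed) comparison network.

    Same negative-only transform applied to the symmetric Pearson matrix of
    ``x`` against itself, with the diagonal forced to 1 (self-correlation
    is +1 by construction, hence a non-edge)."""
    r = pearson_matrix(x, x)
    d = negative_distance(r, undefined_policy)
    d = (d + d.T) / 2.0  # exact symmetry despite floating-point round-off
    np.fill_diagonal(d, 1.0)
    return SymmetricDistanceMatrix(
        labels=x.roi_labels,
        values=d,
        n_trials_used=x.n_trials,
        partition=x.band_epoch,
    )
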