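"""Epistemic network analysis of element co-occurrence, from scratch.

Each unit (a chimpanzee) is summarized by how its behavioral elements
co-occur in the recent temporal context of its coded lines.  A *moving
stanza window* of w lines slides over every conversation (one subject's
video): a pair of elements is connected on a line when one is present on
that line and the other anywhere in the window ending there, counted at
most once per line.  The per-unit pair counts are vectorized over the upper
triangle of the element x element matrix, normalized to the unit sphere
(so connection *pattern*, not volume, is compared), mean-centered, and
projected by SVD onto the two axes of greatest shared variance (SVD1,
SVD2).  Element (node) positions are then co-registered by least squares so
that each unit's edge-weighted network centroid lands near its projected
point; the Pearson/Spearman correlation between points and centroids is the
model's goodness of fit.  Group (community) means are compared per axis
with Mann-Whitney U tests and rank-biserial effect sizes r = 1 - 2U/(n1·n2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coding_io import PresenceMatrix
from .errors import DegenerateInputError, LookupError_, ParameterError

AXES = ("SVD1", "SVD2")


@dataclass(frozen=True)
class StanzaConfig:
    """Moving stanza window configuration.

    ``window`` counts lines including the current one; ``None`` means the
    whole conversation so far (an infinite stanza).  The window never
    crosses a conversation boundary.  ``binary`` counts each element pair at
    most once per line evaluation (presence/absence semantics); when False,
    the response element's occurrence count inside the window is summed.
    """

    window: Optional[int] = 4
    binary: bool = True

    def __post_init__(self):
        if self.window is not None and self.window < 1:
            raise ParameterError(f"window must be >= 1 or None, got {self.window}")


def pair_labels(elements: Sequence[str]) -> list[tuple[str, str]]:
    """Fixed upper-triangle ordering of unordered element pairs."""
    return list(combinations(elements, 2))


def accumulate_adjacency(matrix: PresenceMatrix, config: StanzaConfig = StanzaConfig()) -> pd.DataFrame:
    """Per-unit stanza-window co-occurrence counts over element pairs.

    For each line l of each conversation and each element pair (i, j), the
    unit's (i, j) weight grows by 1 if i is present on line l and j is
    present anywhere in the window {l-w+1 .. l} or vice versa — at most
    once per line in binary mode.  Conversations are independent: counts
    are summed per unit across its conversations, and windows truncate at
    conversation starts.

    Returns a units x pairs DataFrame (columns = upper-triangle pair
    labels); ``.attrs['community']`` maps units to groups.
    """
    if matrix.data.empty:
        raise DegenerateInputError("empty presence matrix")
    if matrix.has_na:
        raise ParameterError("presence matrix still has NA cells; run apply_na_policy first")
    elements = matrix.elements
    e = len(elements)
    iu = np.triu_indices(e, k=1)
    units = matrix.units
    acc = {u: np.zeros(len(iu[0])) for u in units}
    for (unit, _conv), grp in matrix.data.groupby(level=["unit", "conversation"], sort=False):
        b = grp.sort_index(level="line_index").to_numpy() > 0
        n_lines = b.shape[0]
        w = config.window
        for l in range(n_lines):
            lo = 0 if w is None else max(0, l - w + 1)
            cur = b[l]
            if config.binary:
                win = b[lo : l + 1].any(axis=0)
                co = np.outer(cur, win) | np.outer(win, cur)
                acc[unit] += co[iu].astype(float)
            else:
                wc = b[lo : l + 1].sum(axis=0).astype(float)
                co = np.outer(cur, wc) + np.outer(wc, cur) - np.outer(cur, cur)
                acc[unit] += np.where(
                    np.outer(cur, np.ones(e, bool)) | np.outer(np.ones(e, bool), cur), co, 0.0
                )[iu]
    out = pd.DataFrame(
        np.vstack([acc[u] for u in units]),
        index=pd.Index(units, name="unit"),
        columns=pd.MultiIndex.from_tuples(pair_labels(elements)),
    )
    out.attrs["community"] = dict(matrix.community)
    out.attrs["elements"] = list(elements)
    return out


def normalize_sphere(vectors: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Project each unit's adjacency vector onto the unit sphere.

    Division by the L2 norm removes total connection volume (units seen in
    more clips accumulate more counts) and keeps relative pattern.  Units
    with all-zero vectors cannot be normalized; they are dropped and
    returned in the exclusion list with a warning.
    """
    norms = np.linalg.norm(vectors.to_numpy(dtype=float), axis=1)
    zero = norms == 0
    excluded = list(vectors.index[zero])
    if excluded:
        warnings.warn(f"excluding {len(excluded)} unit(s) with empty networks: {excluded}")
    kept = vectors.loc[~zero]
    out = kept.div(norms[~zero], axis=0)
    out.attrs = dict(vectors.attrs)
    return out, excluded


@dataclass
class ENASpace:
    """A fitted projection space over normalized unit networks."""

    normalized: pd.DataFrame            # units x pairs, unit-sphere rows
    unit_points: pd.DataFrame           # units x (SVD1, SVD2), centered scores
    axes: np.ndarray                    # pairs x 2 orthonormal directions
    variance_explained: np.ndarray      # fraction per axis
    groups: pd.Series                   # unit -> group label
    elements: list[str]
    excluded_units: list[str] = field(default_factory=list)
    node_positions: Optional[pd.DataFrame] = None   # elements x (SVD1, SVD2)
    fit: Optional[dict] = None          # axis -> {'pearson': r, 'spearman': rho}

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.normalized.columns)


def _fix_signs(axes: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Reproducible orientation: the largest-|loading| coordinate of each axis
    # is made positive (figure sign is otherwise arbitrary under SVD).
    for j in range(axes.shape[1]):
        k = int(np.argmax(np.abs(axes[:, j])))
        if axes[k, j] < 0:
            axes[:, j] = -axes[:, j]
            scores[:, j] = -scores[:, j]
    return axes, scores


def ena_project(vectors: pd.DataFrame, groups: Optional[dict] = None, dims: int = 2) -> ENASpace:
    """Center the normalized vectors and project them by SVD.

    ``vectors`` are raw adjacency vectors (normalization is applied here).
    Unit points are the mean-centered scores on the first two right-singular
    directions; variance explained per axis is the squared-singular-value
    fraction.  Axis signs follow a fixed convention so repeated runs agree.
    """
    if dims != 2:
        raise ParameterError("only 2-D projection spaces are supported")
    normalized, excluded = normalize_sphere(vectors)
    if len(normalized) < 3:
        raise DegenerateInputError(f"need >= 3 units with nonempty networks, have {len(normalized)}")
    x = normalized.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if rank < dims:
        warnings.warn(f"projection rank {rank} < {dims}; trailing axis zeroed")
    axes = vt[:dims].T.copy()
    scores = centered @ axes
    if rank < dims:
        axes[:, rank:] = 0.0
        scores[:, rank:] = 0.0
    axes, scores = _fix_signs(axes, scores)
    total = float(np.sum(s**2))
    var = (s[:dims] ** 2 / total) if total > 0 else np.zeros(dims)
    group_src = groups if groups is not None else vectors.attrs.get("community", {})
    gseries = pd.Series({u_: group_src.get(u_, "all") for u_ in normalized.index}, name="group")
    elements = vectors.attrs.get(
        "elements", sorted({e for p in vectors.columns for e in p})
    )
    return ENASpace(
        normalized=normalized,
        unit_points=pd.DataFrame(scores, index=normalized.index, columns=list(AXES)),
        axes=axes,
        variance_explained=np.asarray(var),
        groups=gseries,
        elements=list(elements),
        excluded_units=excluded,
    )


def position_nodes(space: ENASpace) -> ENASpace:
    """Co-register element (node) positions with the projected unit points.

    Each unit's plotted network has a centroid: the average of its edge
    midpoints weighted by normalized edge weight.  Node coordinates are
    chosen by least squares so centroids approximate the units' projected
    points; the per-axis Pearson and Spearman correlations between points
    and centroids are the goodness of fit.  Fills ``node_positions`` and
    ``fit`` in place and returns the space.
    """
    w = space.normalized.to_numpy(dtype=float)
    elements = space.elements
    e_ix = {el: i for i, el in enumerate(elements)}
    # incidence: pair column -> half weight on each endpoint element
    inc = np.zeros((w.shape[1], len(elements)))
    for p, (a, b) in enumerate(space.pairs):
        inc[p, e_ix[a]] = 0.5
        inc[p, e_ix[b]] = 0.5
    totals = w.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    a = (w / totals) @ inc                      # units x elements, rows sum to 1
    y = space.unit_points.to_numpy(dtype=float)
    sol, _res, rank, _sv = np.linalg.lstsq(a, y, rcond=None)
    if rank < len(elements):
        warnings.warn(
            f"node placement under-determined (rank {rank} < {len(elements)} elements); "
            "minimum-norm solution used"
        )
    centroids = a @ sol
    fit = {}
    for j, axis in enumerate(AXES):
        if np.allclose(centroids[:, j], centroids[0, j]) or np.allclose(y[:, j], y[0, j]):
            fit[axis] = {"pearson": 1.0, "spearman": 1.0}  # exact/degenerate co-registration
        else:
            fit[axis] = {
                "pearson": float(stats.pearsonr(y[:, j], centroids[:, j])[0]),
                "spearman": float(stats.spearmanr(y[:, j], centroids[:, j])[0]),
            }
    space.node_positions = pd.DataFrame(sol, index=pd.Index(elements, name="element"), columns=list(AXES))
    space.fit = fit
    return space


def group_means_ci(space: ENASpace, level: float = 0.95) -> pd.DataFrame:
    """Per-group mean point with axis-aligned t confidence intervals.

    Returns a frame indexed by group with, per axis, the mean and the CI
    bounds; singleton groups get NaN bounds (flagged, no interval).
    """
    if not 0 < level < 1:
        raise ParameterError("level must lie in (0, 1)")
    rows = {}
    for g, members in space.groups.groupby(space.groups):
        pts = space.unit_points.loc[members.index]
        n = len(pts)
        row = {"n": n}
        for axis in AXES:
            v = pts[axis].to_numpy()
            m = float(v.mean())
            row[f"{axis}_mean"] = m
            if n >= 2:
                half = stats.t.ppf(0.5 + level / 2, n - 1) * v.std(ddof=1) / np.sqrt(n)
                row[f"{axis}_lo"], row[f"{axis}_hi"] = m - half, m + half
            else:
                row[f"{axis}_lo"] = row[f"{axis}_hi"] = np.nan
        rows[g] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "group"
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of two groups' coordinates along one axis."""

    group_a: str
    group_b: str
    axis: str
    u: float
    p_value: float
    effect_size: float  # rank-biserial r = 1 - 2U/(n1*n2); positive when group_a sits lower
    n1: int
    n2: int


def rank_compare(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Mann-Whitney U (of x), two-sided p, and rank-biserial effect size.

    U counts pairs where x exceeds y (ties half); r = 1 - 2U/(n1·n2), so
    complete separation (U = 0 or U = n1·n2) gives |r| = 1.  All-tied
    samples return U = n1·n2/2, p = 1, r = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("both groups need at least one unit")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        warnings.warn("all coordinates tied; comparison is uninformative")
        return n1 * n2 / 2, 1.0, 0.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    u = float(res.statistic)
    r = 1.0 - 2.0 * u / (n1 * n2)
    return u, float(res.pvalue), r


def compare_groups(space: ENASpace, group_a: str, group_b: str, axis: str = "SVD1") -> GroupComparison:
    """Mann-Whitney test of two communities' unit positions along one axis."""
    if axis not in AXES:
        raise ParameterError(f"axis must be one of {AXES}")
    for g in (group_a, group_b):
        if g not in set(space.groups):
            raise LookupError_(f"unknown group {g!r}")
    xa = space.unit_points.loc[space.groups[space.groups == group_a].index, axis]
    xb = space.unit_points.loc[space.groups[space.groups == group_b].index, axis]
    u, p, r = rank_compare(xa.to_numpy(), xb.to_numpy())
    return GroupComparison(group_a, group_b, axis, u, p, r, len(xa), len(xb))


def compare_all_groups(space: ENASpace) -> pd.DataFrame:
    """Every unordered group pair on both axes, as a tidy frame."""
    groups = sorted(space.groups.unique())
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            for axis in AXES:
                c = compare_groups(space, a, b, axis)
                rows.append((a, b, axis, c.u, c.p_value, c.effect_size, c.n1, c.n2))
    return pd.DataFrame(
        rows, columns=["group_a", "group_b", "axis", "U", "p_value", "effect_size", "n1", "n2"]
    )


def mean_network(
    normalized: pd.DataFrame, units: Sequence[str], threshold: float = 0.0
) -> pd.Series:
    """Average normalized edge weights over a set of units (one group's network).

    Pairs with mean weight <= ``threshold`` are dropped (display thinning).
    """
    units = list(units)
    if not units:
        raise DegenerateInputError("empty group")
    sub = normalized.loc[units]
    mean = sub.mean(axis=0)
    mean = mean[mean > threshold] if threshold > 0 else mean
    mean.name = "weight"
    return mean


def group_mean_network(space: ENASpace, group: str, threshold: float = 0.0) -> pd.Series:
    members = space.groups[space.groups == group].index
    if len(members) == 0:
        raise LookupError_(f"unknown or empty group {group!r}")
    return mean_network(space.normalized, list(members), threshold)
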