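"""Repertoire statistics: rarefaction, pairwise exact tests, clustering.

Camera-trap corpora are opportunistic: some subjects are seen in dozens of
clips, others in a handful.  Rarefaction asks whether more clips would keep
revealing new behavioral elements for a subject — if the accumulation curve
has plateaued, the observed inventory is close to complete and the subject
can be included in repertoire-level analyses.  Usage differences between
subjects are screened with Fisher's exact test (the usage matrix is sparse:
most techniques are unused by most subjects), and overall repertoire
similarity is visualized by hierarchical clustering of the globally
max-normalized frequency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .coding_io import EventTable
from .errors import DegenerateInputError, LookupError_, ParameterError

# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RarefactionCurve:
    """Bootstrap accumulation curve of distinct behavioral elements.

    ``x[i]`` observations (videos) sampled, ``mean[i]`` the expected number
    of distinct elements seen by then, averaged over ``n_boot`` random
    accumulation orders; ``sd`` the spread across replicates.
    """

    label: str
    x: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_boot: int
    seed: Optional[int]


def _video_item_sets(events: EventTable) -> list[set]:
    return [set(seq) for _s, _v, seq in events.sequences()]


def rarefaction_curve(
    events: EventTable,
    subject: Optional[str] = None,
    community: Optional[str] = None,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> RarefactionCurve:
    """Element accumulation curve for one subject or one pooled community.

    Each bootstrap replicate permutes the videos uniformly at random and
    accumulates the distinct elements seen; the observation unit is the
    video (the discrete camera-trap sampling event).  The terminal value is
    deterministic: it equals the subject's full observed inventory.
    """
    if (subject is None) == (community is None):
        raise ParameterError("give exactly one of subject= or community=")
    if subject is not None:
        if subject not in events.subjects:
            raise LookupError_(f"unknown subject {subject!r}")
        sub = events.restrict(subject=subject)
        label = subject
    else:
        if community not in events.communities:
            raise LookupError_(f"unknown community {community!r}")
        sub = events.restrict(community=community)
        label = community
    item_sets = _video_item_sets(sub)
    n = len(item_sets)
    rng = np.random.default_rng(seed)
    acc = np.zeros((n_boot, n))
    for r in range(n_boot):
        order = rng.permutation(n)
        seen: set = set()
        for j, vix in enumerate(order):
            seen |= item_sets[vix]
            acc[r, j] = len(seen)
    return RarefactionCurve(
        label, np.arange(1, n + 1), acc.mean(axis=0), acc.std(axis=0, ddof=0), n_boot, seed
    )


def is_saturated(
    curve: RarefactionCurve, eps: float = 0.05, tail: float = 0.2
) -> tuple[bool, dict]:
    """Plateau check: has the accumulation curve flattened?

    The mean slope (new elements per added observation) over the final
    ``tail`` fraction of the curve is compared against ``eps``.  Returns the
    verdict and a diagnostics dict with the measured tail slope.
    """
    if len(curve.x) < 5:
        raise DegenerateInputError(
            f"curve for {curve.label!r} has {len(curve.x)} points; need >= 5"
        )
    if not 0 < tail <= 1:
        raise ParameterError("tail must lie in (0, 1]")
    k = max(1, int(np.ceil(tail * len(curve.x))))
    xs, ys = curve.x[-(k + 1):], curve.mean[-(k + 1):]
    slope = (ys[-1] - ys[0]) / (xs[-1] - xs[0])
    return bool(slope < eps), {
        "tail_slope": float(slope),
        "tail_points": int(k),
        "terminal": float(curve.mean[-1]),
    }


# ---------------------------------------------------------------------------
# Pairwise exact tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseTestResult:
    """Fisher's exact comparison of one technique's usage between two subjects."""

    technique: int
    subject_a: str
    subject_b: str
    contingency: tuple  # ((uses_a, other_a), (uses_b, other_b))
    p_value: float
    p_adjusted: Optional[float] = None


def pairwise_fisher(
    freq: pd.DataFrame, technique, subject_a: str, subject_b: str
) -> PairwiseTestResult:
    """Two-sided Fisher's exact test of one technique's usage share.

    The 2x2 table contrasts uses of the technique against uses of all other
    techniques for each subject, so the margins are the subjects' usage
    totals.  Two-sided p sums hypergeometric probabilities of tables as or
    more extreme (probability ordering) than the observed one.
    """
    for s in (subject_a, subject_b):
        if s not in freq.index:
            raise LookupError_(f"unknown subject {s!r}")
        if freq.loc[s].sum() == 0:
            raise DegenerateInputError(f"subject {s!r} has zero usage total")
    if technique not in freq.columns:
        raise LookupError_(f"unknown technique {technique!r}")
    a_t = int(freq.loc[subject_a, technique])
    b_t = int(freq.loc[subject_b, technique])
    a_o = int(freq.loc[subject_a].sum()) - a_t
    b_o = int(freq.loc[subject_b].sum()) - b_t
    table = [[a_t, a_o], [b_t, b_o]]
    _, p = fisher_exact(table, alternative="two-sided")
    return PairwiseTestResult(technique, subject_a, subject_b, ((a_t, a_o), (b_t, b_o)), float(p))


def all_pairwise_fisher(freq: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher tests for every technique x subject-pair, with BH adjustment.

    Subjects with zero usage totals are excluded with a warning column in
    ``.attrs['excluded']``.  Raw two-sided p-values and Benjamini-Hochberg
    adjusted values are reported side by side across the whole family.
    """
    active = [s for s in freq.index if freq.loc[s].sum() > 0]
    excluded = [s for s in freq.index if s not in active]
    rows = []
    for t in freq.columns:
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                res = pairwise_fisher(freq, t, a, b)
                rows.append(
                    (t, a, b, res.contingency[0][0], res.contingency[1][0], res.p_value)
                )
    out = pd.DataFrame(
        rows, columns=["technique", "subject_a", "subject_b", "uses_a", "uses_b", "p_value"]
    )
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")[1]
    else:
        out["p_adjusted"] = []
    out.attrs["excluded"] = excluded
    return out


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Hierarchical clustering of subjects by normalized technique usage."""

    normalized: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster labels for the given number of clusters."""
        labels = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.normalized.index, labels.tolist()))


def cluster_repertoires(
    freq: pd.DataFrame,
    normalization: str = "global_max",
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of subjects on their usage profiles.

    ``global_max`` normalization divides the whole matrix by its single
    largest cell so all values lie in [0, 1] with the maximum exactly 1 —
    the convention used for repertoire heatmaps; ``row_total`` divides each
    subject's row by its usage total instead.
    """
    if len(freq.index) < 2:
        raise ParameterError("need at least 2 subjects to cluster")
    arr = freq.to_numpy(dtype=float)
    if normalization == "global_max":
        peak = arr.max()
        if peak <= 0:
            raise DegenerateInputError("all-zero frequency matrix")
        norm = arr / peak
    elif normalization == "row_total":
        totals = arr.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise DegenerateInputError("subject with zero usage total")
        norm = arr / totals
    elif normalization == "none":
        norm = arr
    else:
        raise ParameterError(f"unknown normalization {normalization!r}")
    normalized = pd.DataFrame(norm, index=freq.index, columns=freq.columns)
    link = sch.linkage(norm, method=method, metric=metric)
    order = [freq.index[i] for i in sch.leaves_list(link)]
    return ClusterResult(normalized, link, order)
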