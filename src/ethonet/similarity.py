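"""Sørensen similarity between behavioral repertoires, stratified by mound type.

Cross-community comparison works on presence/absence of behavioral
*elements* (not techniques): two communities are similar when the elements
they use to fish overlap.  The Sørensen index

    S(A, B) = 2·N_shared / (2·N_shared + N_only_A + N_only_B)

double-weights shared elements, runs from 0 (disjoint repertoires) to 1
(identical repertoires), and is only meaningful within a mound-type stratum
— fishing at an aerial mound and at an underground nest draw on different
inventories, so strata are never mixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .coding_io import EventTable, PresenceMatrix
from .errors import DegenerateInputError, StratificationError


@dataclass(frozen=True)
class Repertoire:
    """The set of behavioral elements an owner (subject or community) has shown."""

    owner: str
    mound_type: str
    elements: frozenset


def sorensen(rep_a: Repertoire, rep_b: Repertoire, check_stratum: bool = True) -> float:
    """Sørensen similarity S = 2·|A∩B| / (2·|A∩B| + |A\\B| + |B\\A|)."""
    if check_stratum and rep_a.mound_type != rep_b.mound_type:
        raise StratificationError(
            f"repertoires from different mound types "
            f"({rep_a.mound_type!r} vs {rep_b.mound_type!r})"
        )
    a, b = rep_a.elements, rep_b.elements
    if not a and not b:
        raise DegenerateInputError("Sørensen undefined: both repertoires empty")
    shared = len(a & b)
    return 2 * shared / (2 * shared + len(a - b) + len(b - a))


def _element_sets(
    data: Union[EventTable, PresenceMatrix], mound_type: str
) -> tuple[dict[str, set], dict[str, str]]:
    """Per-subject observed element sets and subject->community map at a stratum."""
    if isinstance(data, EventTable):
        sub = data.restrict(mound_type=mound_type)
        if len(sub) == 0:
            raise StratificationError(f"no events at mound type {mound_type!r}")
        sets = {s: set(g["element"]) for s, g in sub.df.groupby("subject")}
        return sets, sub.community_of()
    matrix = data.restrict_mound_type(mound_type)
    present = matrix.data.fillna(0.0) > 0
    sets = {
        unit: set(present.columns[grp.any(axis=0)])
        for unit, grp in present.groupby(level="unit")
    }
    return sets, dict(matrix.community)


def subject_repertoires(
    data: Union[EventTable, PresenceMatrix], mound_type: str
) -> dict[str, Repertoire]:
    """Observed element repertoire of every subject at one mound type."""
    sets, _ = _element_sets(data, mound_type)
    return {s: Repertoire(s, mound_type, frozenset(e)) for s, e in sets.items()}


def community_repertoire(
    data: Union[EventTable, PresenceMatrix], community: str, mound_type: str
) -> Repertoire:
    """Pooled element repertoire of a whole community at one mound type."""
    sets, comm = _element_sets(data, mound_type)
    pooled: set = set()
    for s, els in sets.items():
        if comm.get(s) == community:
            pooled |= els
    if not pooled:
        raise StratificationError(
            f"community {community!r} has no elements at mound type {mound_type!r}"
        )
    return Repertoire(community, mound_type, frozenset(pooled))


@dataclass
class SimilarityProfile:
    """Per-individual similarity of one community against a reference community.

    ``values[s]`` is subject s's mean Sørensen similarity against every
    reference-community subject (or against the pooled reference repertoire
    when built with ``pool_reference=True``); ``summary`` carries the box
    statistics (mean, median, quartiles, 2.5%/97.5% quantiles).
    """

    community: str
    reference: str
    mound_type: str
    values: pd.Series
    summary: dict


def community_similarity_profile(
    data: Union[EventTable, PresenceMatrix],
    community: str,
    reference_community: str,
    mound_type: str,
    pool_reference: bool = False,
) -> SimilarityProfile:
    """Individual-level similarity profile of ``community`` vs a reference.

    For each subject of ``community`` at the given mound type, Sørensen
    similarity is computed against every subject of the reference community
    and averaged (``pool_reference=True`` compares against the reference
    community's union repertoire instead).
    """
    sets, comm = _element_sets(data, mound_type)
    own = {s: e for s, e in sets.items() if comm.get(s) == community and e}
    ref = {s: e for s, e in sets.items() if comm.get(s) == reference_community and e}
    if not own or not ref:
        raise StratificationError(
            f"empty stratum: community={community!r} ({len(own)} subjects), "
            f"reference={reference_community!r} ({len(ref)} subjects) at {mound_type!r}"
        )
    if pool_reference:
        pooled = Repertoire(reference_community, mound_type,
                            frozenset(set().union(*ref.values())))
        vals = {
            s: sorensen(Repertoire(s, mound_type, frozenset(e)), pooled)
            for s, e in own.items()
        }
    else:
        vals = {
            s: float(
                np.mean(
                    [
                        sorensen(
                            Repertoire(s, mound_type, frozenset(e)),
                            Repertoire(r, mound_type, frozenset(re)),
                        )
                        for r, re in ref.items()
                    ]
                )
            )
            for s, e in own.items()
        }
    series = pd.Series(vals, name="sorensen").sort_index()
    q = series.quantile([0.025, 0.25, 0.5, 0.75, 0.975])
    summary = {
        "mean": float(series.mean()),
        "median": float(q[0.5]),
        "q1": float(q[0.25]),
        "q3": float(q[0.75]),
        "q2.5%": float(q[0.025]),
        "q97.5%": float(q[0.975]),
        "n": int(len(series)),
    }
    return SimilarityProfile(community, reference_community, mound_type, series, summary)


def pairwise_community_similarity(
    data: Union[EventTable, PresenceMatrix], mound_type: str
) -> pd.DataFrame:
    """Symmetric community x community Sørensen matrix of pooled repertoires."""
    sets, comm = _element_sets(data, mound_type)
    communities = sorted({comm[s] for s in sets})
    reps = {c: community_repertoire(data, c, mound_type) for c in communities}
    out = pd.DataFrame(1.0, index=communities, columns=communities)
    for i, a in enumerate(communities):
        for b in communities[i + 1 :]:
            s = sorensen(reps[a], reps[b])
            out.loc[a, b] = out.loc[b, a] = s
    return out
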