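"""Mining functional termite-fishing techniques from coded event sequences.

A *technique* is an ordered run of 2-7 consecutive behavioral elements that
contains a probing element followed (not necessarily immediately) by an
extraction element — the minimal structure that inserts a tool into a
termite nest and harvests it.  The miner enumerates every contiguous
n-gram of each (subject, video) sequence, keeps the functional ones, and
counts per-subject usage.  Camera-trap clips are the observation unit:
techniques never span two videos.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .coding_io import EventTable
from .errors import ParameterError
from .ethogram import Ethogram, Role


@dataclass(frozen=True)
class Technique:
    """One functional element combination (a catalogued n-gram)."""

    elements: tuple[str, ...]
    id: int

    @property
    def length(self) -> int:
        return len(self.elements)


@dataclass(frozen=True)
class TechniqueCatalog:
    """Deduplicated techniques with stable ids (ordered by length, then label)."""

    techniques: tuple[Technique, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.techniques)

    def by_id(self, tid: int) -> Technique:
        return self.techniques[tid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [t.id for t in self.techniques],
                "length": [t.length for t in self.techniques],
                "elements": [" > ".join(t.elements) for t in self.techniques],
            }
        )


def enumerate_ngrams(
    sequence: Sequence[str], k_min: int = 2, k_max: int = 7
) -> list[tuple[str, ...]]:
    """All contiguous subsequences of lengths k_min..k_max, in order of occurrence.

    Ordered first by starting position, then by length, so a caller reading
    the list left to right walks the sequence once.
    """
    if k_min < 2 or k_max < k_min:
        raise ParameterError(f"need 2 <= k_min <= k_max, got k_min={k_min}, k_max={k_max}")
    seq = tuple(sequence)
    n = len(seq)
    out = []
    for i in range(n):
        for k in range(k_min, min(k_max, n - i) + 1):
            out.append(seq[i : i + k])
    return out


def is_functional_technique(candidate: Sequence[str], ethogram: Ethogram) -> bool:
    """True iff some probe-role element precedes some extract-role element."""
    roles = [ethogram.role(lab) for lab in candidate]
    seen_probe = False
    for r in roles:
        if r is Role.PROBE:
            seen_probe = True
        elif r is Role.EXTRACT and seen_probe:
            return True
    return False


def build_technique_catalog(
    events: EventTable,
    ethogram: Ethogram,
    k_min: int = 2,
    k_max: int = 7,
    provenance: str = "",
) -> TechniqueCatalog:
    """The deduplicated set of functional n-grams over the whole corpus.

    Deterministic: ids are assigned in (length, lexicographic) order, so the
    same corpus always yields the same catalog regardless of video order.
    """
    ethogram.require_functional_roles()
    found: set[tuple[str, ...]] = set()
    for _, _, seq in events.sequences():
        for gram in enumerate_ngrams(seq, k_min, k_max):
            if gram not in found and is_functional_technique(gram, ethogram):
                found.add(gram)
    ordered = sorted(found, key=lambda g: (len(g), g))
    return TechniqueCatalog(
        tuple(Technique(g, i) for i, g in enumerate(ordered)), provenance=provenance
    )


def _count_occurrences(seq: tuple[str, ...], gram: tuple[str, ...]) -> list[int]:
    """Start positions of (possibly overlapping) occurrences of gram in seq."""
    k = len(gram)
    return [i for i in range(len(seq) - k + 1) if seq[i : i + k] == gram]


def technique_frequencies(
    catalog: TechniqueCatalog,
    events: EventTable,
    maximal_only: bool = False,
) -> pd.DataFrame:
    """Per-subject occurrence counts for every catalogued technique.

    Overlapping and nested occurrences are all counted: an occurrence of a
    long technique also contains occurrences of its shorter catalogued
    prefixes/infixes, so a probe-oscillate-extract bout increments both the
    three-element technique and the embedded probe-extract-style bigrams it
    contains.  With ``maximal_only=True`` an occurrence is skipped when it
    lies inside a longer catalogued occurrence (alternative convention).

    Returns a subjects x technique-id DataFrame of non-negative counts.
    """
    subjects = events.subjects
    subj_ix = {s: i for i, s in enumerate(subjects)}
    tid_by_gram = {t.elements: t.id for t in catalog.techniques}
    lengths = {gram: len(gram) for gram in tid_by_gram}
    k_min = min(lengths.values(), default=2)
    k_max = max(lengths.values(), default=2)
    arr = np.zeros((len(subjects), len(catalog.techniques)), dtype=int)
    for subj, _vid, seq_list in events.sequences():
        seq = tuple(seq_list)
        if maximal_only:
            occ = {
                tid_by_gram[gram]: _count_occurrences(seq, gram)
                for gram in tid_by_gram
            }
            spans = {
                (s, s + catalog.by_id(tid).length)
                for tid, starts in occ.items()
                for s in starts
            }
            for tid, starts in occ.items():
                k = catalog.by_id(tid).length
                kept = [
                    s
                    for s in starts
                    if not any(lo <= s and s + k <= hi and (hi - lo) > k for lo, hi in spans)
                ]
                arr[subj_ix[subj], tid] += len(kept)
        else:
            # every occurrence of a catalogued gram is, equivalently, one of
            # the sequence's n-grams — count them all in a single pass
            grams = Counter(
                seq[i : i + k]
                for i in range(len(seq))
                for k in range(k_min, min(k_max, len(seq) - i) + 1)
            )
            for gram, c in grams.items():
                tid = tid_by_gram.get(gram)
                if tid is not None:
                    arr[subj_ix[subj], tid] += c
    return pd.DataFrame(
        arr,
        index=pd.Index(subjects, name="subject"),
        columns=pd.Index([t.id for t in catalog.techniques], name="technique"),
    )


def repertoire_summary(
    freq: pd.DataFrame,
    catalog: TechniqueCatalog,
    age_class: Optional[dict] = None,
) -> pd.DataFrame:
    """Per-subject repertoire size and technique-length statistics.

    ``repertoire_size`` counts techniques with positive usage;
    ``mean_technique_length`` weights each technique's length by how often
    the subject used it.  The returned frame carries corpus-wide summaries
    in ``.attrs`` (overall mean/median repertoire size, usage-weighted mean
    length, and per-age-class mean lengths when ``age_class`` maps subjects
    to classes).
    """
    if freq.empty:
        raise ParameterError("empty frequency matrix")
    lengths = np.array([catalog.by_id(int(t)).length for t in freq.columns])
    used = freq > 0
    totals = freq.sum(axis=1)
    weighted_len = (freq * lengths).sum(axis=1) / totals.replace(0, np.nan)
    out = pd.DataFrame(
        {
            "repertoire_size": used.sum(axis=1),
            "total_uses": totals,
            "mean_technique_length": weighted_len,
        }
    )
    if age_class is not None:
        out["age_class"] = pd.Series(age_class).reindex(out.index)
    grand_total = float(freq.to_numpy().sum())
    out.attrs["overall"] = {
        "n_techniques": int((freq.sum(axis=0) > 0).sum()),
        "mean_repertoire_size": float(out["repertoire_size"].mean()),
        "median_repertoire_size": float(out["repertoire_size"].median()),
        "mean_technique_length": (
            float((freq * lengths).to_numpy().sum() / grand_total) if grand_total else np.nan
        ),
    }
    if age_class is not None:
        out.attrs["by_age_class"] = (
            out.groupby("age_class")["mean_technique_length"].mean().to_dict()
        )
    return out
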