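"""I/O and data model for coded behavioral event tables and wide matrices.

Coded video arrives as a long-format event table: one row per behavioral
element onset, with the subject, the video (camera-trap clip), the mound and
its type, and the onset time on a quarter-second grid.  Elements are
mutually exclusive in time — the onset of one element is the offset of the
previous — so a sequence of onsets fully describes a bout.

For network analysis the events are *widened* into a presence/absence
matrix: one line per time bin (or per event), one column per element, with
the line keyed by (unit = subject, conversation = subject's video).  Wide
matrices imported from other studies may carry not-applicable cells;
``apply_na_policy`` implements the standard cleanup: drop elements that are
NA in more than 90% of lines, then recode remaining NA as absent, because
the network accumulator cannot carry missing values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateInputError,
    FormatError,
    ParameterError,
    UndefinedStatisticError,
    ValidationError,
)
from .ethogram import OTHER_LABEL, Ethogram

EVENT_COLUMNS = [
    "community",
    "subject",
    "video_id",
    "mound_id",
    "mound_type",
    "start_time_s",
    "element",
    "body_position",
    "hand",
]

MOUND_TYPES = ("aerial", "underground")
TIME_GRID_S = 0.25
CONVERSATION_SEP = "|"


def conversation_key(subject: str, video_id: str) -> str:
    """Conversation identifier: one subject's appearance in one video."""
    return f"{subject}{CONVERSATION_SEP}{video_id}"


# ---------------------------------------------------------------------------
# EventTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventTable:
    """A validated long-format table of coded behavioral events.

    ``df`` holds the columns in :data:`EVENT_COLUMNS`; rows are strictly
    ordered by onset time within each (subject, video_id) group, onsets sit
    on the quarter-second grid, and mound types are ``aerial`` or
    ``underground``.
    """

    df: pd.DataFrame

    def __post_init__(self):
        object.__setattr__(self, "df", _validate_events(self.df))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject"].unique())

    @property
    def communities(self) -> list[str]:
        return sorted(self.df["community"].unique())

    def community_of(self) -> dict[str, str]:
        """Map subject -> community (first community seen per subject)."""
        return self.df.groupby("subject", sort=True)["community"].first().to_dict()

    def sequences(self) -> list[tuple[str, str, list[str]]]:
        """Per-(subject, video) ordered element sequences."""
        out = []
        for (subj, vid), grp in self.df.groupby(["subject", "video_id"], sort=True):
            out.append((subj, vid, grp["element"].tolist()))
        return out

    def restrict(self, *, community: Optional[str] = None, subject: Optional[str] = None,
                 mound_type: Optional[str] = None) -> "EventTable":
        m = pd.Series(True, index=self.df.index)
        if community is not None:
            m &= self.df["community"] == community
        if subject is not None:
            m &= self.df["subject"] == subject
        if mound_type is not None:
            m &= self.df["mound_type"] == mound_type
        return EventTable(self.df[m].reset_index(drop=True))


def _validate_events(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing required columns: {missing}")
    df = df[EVENT_COLUMNS].copy()
    for c in ("community", "subject", "video_id", "mound_id", "mound_type", "element"):
        df[c] = df[c].astype(str)
    df["start_time_s"] = pd.to_numeric(df["start_time_s"], errors="raise").astype(float)

    bad_type = set(df["mound_type"].unique()) - set(MOUND_TYPES)
    if bad_type:
        raise ValidationError(f"unknown mound types {sorted(bad_type)}; expected {MOUND_TYPES}")
    if (df["start_time_s"] < 0).any():
        raise ValidationError("negative start times")
    off_grid = ~np.isclose(df["start_time_s"] / TIME_GRID_S,
                           np.round(df["start_time_s"] / TIME_GRID_S), atol=1e-6)
    if off_grid.any():
        bad = df.loc[off_grid, "start_time_s"].iloc[0]
        raise ValidationError(f"start time {bad} not on the {TIME_GRID_S}s grid")

    for (subj, vid), grp in df.groupby(["subject", "video_id"], sort=False):
        t = grp["start_time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"start times not strictly increasing within video {vid!r} "
                f"(subject {subj!r}); elements are mutually exclusive in time"
            )
    return df.reset_index(drop=True)


def read_event_table(path: Union[str, Path], ethogram: Optional[Ethogram] = None) -> EventTable:
    """Read a long-format event CSV.

    Labels not present in ``ethogram`` are mapped to the catch-all
    ``Other`` code with a warning, mirroring standard coding practice.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if ethogram is not None:
        unknown = sorted(set(df["element"]) - set(ethogram._by_label))
        if unknown:
            warnings.warn(
                f"{len(unknown)} unknown element label(s) mapped to {OTHER_LABEL!r}: "
                f"{unknown[:5]}{'...' if len(unknown) > 5 else ''}"
            )
            df["element"] = df["element"].where(~df["element"].isin(unknown), OTHER_LABEL)
    df["body_position"] = df["body_position"].replace("", pd.NA)
    df["hand"] = df["hand"].replace("", pd.NA)
    return EventTable(df)


def write_event_table(events: EventTable, path: Union[str, Path]) -> None:
    df = events.df.copy()
    # quarter-second grid: write with enough precision for exact round-trip
    df["start_time_s"] = df["start_time_s"].map(lambda v: f"{v:.2f}")
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# PresenceMatrix
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Line x element presence/absence matrix ready for network accumulation.

    ``data`` carries a MultiIndex (unit, conversation, line_index) and one
    float column per element with values 1.0 (present), 0.0 (absent) or NaN
    (not applicable).  ``community`` maps units to their group label and
    ``mound_type`` maps conversations to their stratum.
    """

    data: pd.DataFrame
    community: dict = field(default_factory=dict)
    mound_type: dict = field(default_factory=dict)
    dropped_elements: tuple = ()

    def __post_init__(self):
        if not isinstance(self.data.index, pd.MultiIndex) or self.data.index.nlevels != 3:
            raise ValidationError("presence matrix needs a (unit, conversation, line_index) index")
        self.data.index = self.data.index.set_names(["unit", "conversation", "line_index"])
        for conv, grp in self.data.groupby(level="conversation", sort=False):
            idx = grp.index.get_level_values("line_index").to_numpy()
            if not np.array_equal(np.sort(idx), np.arange(len(idx))):
                raise ValidationError(f"line_index not contiguous from 0 in conversation {conv!r}")

    @property
    def elements(self) -> list[str]:
        return list(self.data.columns)

    @property
    def units(self) -> list[str]:
        return sorted(self.data.index.get_level_values("unit").unique())

    @property
    def has_na(self) -> bool:
        return bool(self.data.isna().any().any())

    def restrict_mound_type(self, mound_type: str) -> "PresenceMatrix":
        convs = [c for c, t in self.mound_type.items() if t == mound_type]
        mask = self.data.index.get_level_values("conversation").isin(convs)
        if not mask.any():
            raise DegenerateInputError(f"no conversations with mound type {mound_type!r}")
        data = self.data[mask]
        units = set(data.index.get_level_values("unit"))
        return PresenceMatrix(
            data.copy(),
            {u: c for u, c in self.community.items() if u in units},
            {c: t for c, t in self.mound_type.items() if c in convs},
            self.dropped_elements,
        )


def to_presence_matrix(
    events: EventTable,
    ethogram: Optional[Ethogram] = None,
    bin_s: Union[float, str] = 5.0,
) -> PresenceMatrix:
    """Widen an event table into a presence/absence matrix.

    With a numeric ``bin_s``, each conversation is cut into consecutive
    ``bin_s``-second time frames from t = 0 to the last occupied frame; an
    element is present in a frame iff one of its onsets falls inside it.
    With ``bin_s="per_event"`` each coded event becomes its own line.
    """
    if len(events) == 0:
        raise DegenerateInputError("empty event table")
    per_event = isinstance(bin_s, str)
    if per_event and bin_s != "per_event":
        raise ParameterError(f"bin_s must be a positive number or 'per_event', got {bin_s!r}")
    if not per_event and not bin_s > 0:
        raise ParameterError(f"bin_s must be positive, got {bin_s}")

    columns = ethogram.labels if ethogram is not None else sorted(events.df["element"].unique())
    col_ix = {c: i for i, c in enumerate(columns)}

    blocks, keys = [], []
    community, mound_type = {}, {}
    for (subj, vid), grp in events.df.groupby(["subject", "video_id"], sort=True):
        conv = conversation_key(subj, vid)
        community[subj] = grp["community"].iloc[0]
        mound_type[conv] = grp["mound_type"].iloc[0]
        t = grp["start_time_s"].to_numpy()
        labs = grp["element"].tolist()
        if per_event:
            block = np.zeros((len(labs), len(columns)))
            for i, lab in enumerate(labs):
                if lab in col_ix:
                    block[i, col_ix[lab]] = 1.0
        else:
            bins = np.floor(t / float(bin_s)).astype(int)
            block = np.zeros((bins.max() + 1, len(columns)))
            for b, lab in zip(bins, labs):
                if lab in col_ix:
                    block[b, col_ix[lab]] = 1.0
        blocks.append(block)
        keys.extend((subj, conv, i) for i in range(block.shape[0]))

    data = pd.DataFrame(
        np.vstack(blocks),
        index=pd.MultiIndex.from_tuples(keys, names=["unit", "conversation", "line_index"]),
        columns=columns,
    )
    return PresenceMatrix(data, community, mound_type)


def apply_na_policy(matrix: PresenceMatrix, na_threshold: float = 0.90) -> PresenceMatrix:
    """Drop mostly-not-applicable element columns; recode the rest as absent.

    Element columns whose NA proportion across all lines exceeds
    ``na_threshold`` (default 0.90) are removed and reported on the result's
    ``dropped_elements``; every remaining NA cell becomes an absence, since
    the network accumulator cannot carry missing values.  Idempotent.
    """
    if not 0 <= na_threshold <= 1:
        raise ParameterError("na_threshold must lie in [0, 1]")
    na_prop = matrix.data.isna().mean(axis=0)
    dropped = tuple(na_prop.index[na_prop > na_threshold])
    kept = [c for c in matrix.data.columns if c not in dropped]
    if not kept:
        raise DegenerateInputError("NA policy removed every element column")
    data = matrix.data[kept].fillna(0.0)
    return PresenceMatrix(
        data, dict(matrix.community), dict(matrix.mound_type),
        tuple(matrix.dropped_elements) + dropped,
    )


META_COLUMNS = ["community", "subject", "video_id", "line_index"]


def write_presence_matrix(matrix: PresenceMatrix, path: Union[str, Path]) -> None:
    """Write the wide CSV layout (community, subject, video_id, line_index, elements...)."""
    rows = matrix.data.reset_index()
    rows["video_id"] = [
        c.split(CONVERSATION_SEP, 1)[1] if CONVERSATION_SEP in c else c
        for c in rows["conversation"]
    ]
    rows["community"] = rows["unit"].map(matrix.community)
    rows["subject"] = rows["unit"]
    out = rows[META_COLUMNS + matrix.elements]
    out.to_csv(path, index=False, na_rep="NA")


def read_presence_matrix(
    path: Union[str, Path],
    mound_type: Optional[str] = None,
) -> PresenceMatrix:
    """Read a wide presence/absence CSV.

    Cells may be 1, 0, ``NA`` or blank; blank and NA both load as
    not-applicable and are resolved later by :func:`apply_na_policy`.
    ``mound_type``, when given, is recorded for every conversation in the
    file (wide exports are usually already stratified by it).
    """
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    elements = [c for c in df.columns if c not in META_COLUMNS]
    if not elements:
        raise FormatError(f"{path}: no element columns")
    conv = [conversation_key(s, v) for s, v in zip(df["subject"].astype(str), df["video_id"].astype(str))]
    data = df[elements].apply(pd.to_numeric, errors="coerce")
    data.index = pd.MultiIndex.from_arrays(
        [df["subject"].astype(str), conv, df["line_index"].astype(int)],
        names=["unit", "conversation", "line_index"],
    )
    community = dict(zip(df["subject"].astype(str), df["community"].astype(str)))
    mt = {c: mound_type for c in data.index.get_level_values("conversation")} if mound_type else {}
    return PresenceMatrix(data, community, mt)


# ---------------------------------------------------------------------------
# Interrater agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its observed/expected agreement components."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int


def cohens_kappa(coder_a: Sequence, coder_b: Sequence) -> KappaResult:
    """Cohen's kappa between two aligned label sequences.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the chance agreement implied by the two coders' marginal label
    frequencies.  Undefined (raises) when p_e = 1, i.e. both coders use a
    single identical label.
    """
    if len(coder_a) != len(coder_b):
        raise AlignmentError(
            f"coder sequences differ in length ({len(coder_a)} vs {len(coder_b)})"
        )
    n = len(coder_a)
    if n < 2:
        raise ParameterError("need at least 2 aligned items")
    a = pd.Categorical(list(coder_a))
    labels = sorted(set(a.categories) | set(pd.Categorical(list(coder_b)).categories))
    a = pd.Categorical(list(coder_a), categories=labels)
    b = pd.Categorical(list(coder_b), categories=labels)
    confusion = pd.crosstab(a, b, dropna=False).reindex(index=labels, columns=labels, fill_value=0)
    c = confusion.to_numpy(dtype=float)
    p_o = np.trace(c) / n
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / n**2)
    if p_e >= 1.0 - 1e-12:
        raise UndefinedStatisticError(
            "expected agreement is 1 (single shared label); kappa undefined"
        )
    return KappaResult((p_o - p_e) / (1 - p_e), p_o, p_e, n)
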