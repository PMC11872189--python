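"""Synthetic camera-trap corpora with known ground truth.

Real corpora of coded termite-fishing video cannot be redistributed, so
every pipeline stage is exercised against a generator whose structure
mirrors how such data arise: several communities of subjects, each subject
filmed in short motion-triggered clips (20 s in low light, 60 s in full
light), behavioral elements coded at quarter-second onsets, elements
mutually exclusive in time.

The generative model is a first-order Markov chain over the ethogram with a
probe-to-extract functional backbone: after a probing element the chain
moves to an extraction element with probability ``p_functional``, so
generated bouts contain catalogued techniques at a known rate.  Community
structure is planted three ways: (1) community-specific element propensity
profiles, (2) community-specific *pair affinities* that multiply the
transition probability between chosen element pairs (an excess
co-occurrence signature, like one community's habit of combining sitting
with oscillating the tool), and (3) mother-offspring propensity mixing
(offspring propensity = kappa * mother + (1 - kappa) * community exposure,
the latter either the community-average profile or a fresh individual
draw).  Clips truncate bouts mid-sequence, as cameras do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .coding_io import EventTable, PresenceMatrix, to_presence_matrix
from .errors import ConfigurationError, ParameterError
from .ethogram import Ethogram, Role, default_ethogram


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic corpus.

    Defaults emulate a modest two-community camera-trap study: 8 subjects
    per community (field communities run 5-31), 22 clips each (published
    corpora average ~22 usable clips per fishing subject), 20 s clips (the
    infrared low-light mode), ~1 element per 2.5 s, 2.5 s presence bins (about one coded action per line).
    ``profile_divergence`` scales how far community propensity profiles
    drift apart (0 = identical); ``affinity_strength`` multiplies the
    transition probability inside each community's planted element pair,
    and ``distinct_affinities`` decides whether communities get different
    planted pairs (True) or all share one (False, the null condition
    together with ``profile_divergence=0``).
    """

    n_communities: int = 2
    subjects_per_community: int = 8
    mound_type: str = "aerial"
    ethogram: Optional[Ethogram] = None
    videos_per_subject: int = 22
    clip_len_s: float = 20.0
    mean_gap_s: float = 2.5
    bin_s: float = 2.5
    p_functional: float = 0.9
    profile_divergence: float = 0.3
    affinity_strength: float = 6.0
    affinity_propensity_boost: float = 2.5
    base_skew: float = 0.6
    role_budgets: Optional[dict] = None
    distinct_affinities: bool = True
    subject_concentration: float = 0.6
    role_concentration: float = 25.0
    stereotypy: float = 1.0
    kinship_mix: float = 0.8
    # what the non-maternal share of an offspring's propensity is drawn from:
    # "profile" = the community-average profile (horizontal transmission pulls
    # toward the community norm), "draw" = a fresh individual-level draw
    kinship_fresh: str = "profile"
    mothers: Optional[dict] = None      # offspring subject -> mother subject
    na_rate: float = 0.0                # blanket NA injection for wide exports
    na_element_rates: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def resolved_ethogram(self) -> Ethogram:
        return self.ethogram if self.ethogram is not None else default_ethogram(self.mound_type)

    def validate(self) -> None:
        if self.clip_len_s not in (20.0, 60.0):
            raise ParameterError("clip_len_s must be 20 (low light) or 60 (full light)")
        if not 0 <= self.p_functional <= 1:
            raise ParameterError("p_functional must lie in [0, 1]")
        if not 0 <= self.kinship_mix <= 1:
            raise ParameterError("kinship_mix must lie in [0, 1]")
        eth = self.resolved_ethogram()
        if not eth.labels_with_role(Role.PROBE) or not eth.labels_with_role(Role.EXTRACT):
            raise ConfigurationError(
                "infeasible grammar: ethogram lacks probe or extract elements"
            )


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the planted structure."""

    elements: list[str]
    community_profiles: dict            # community -> np.ndarray over elements
    subject_propensities: dict          # subject -> realized (stationary) element propensities
    planted_pairs: dict                 # community -> (element_a, element_b)
    mothers: dict                       # offspring -> mother
    communities: dict                   # subject -> community
    config: SyntheticConfig
    subject_draws: dict = field(default_factory=dict)  # pre-grammar drawn vectors


def _community_names(n: int) -> list[str]:
    return [f"community_{i+1}" for i in range(n)]


def _subject_names(comm: str, n: int) -> list[str]:
    return [f"{comm}_S{j+1}" for j in range(n)]


# how often each functional role appears in a fishing clip: probing dominates
# (clips are motion-triggered at active mounds), extraction mostly arrives via
# the probe->extract backbone so its baseline share is small
DEFAULT_ROLE_BUDGETS = {
    Role.PROBE: 0.28,
    Role.EXTRACT: 0.08,
    Role.POSTURE: 0.18,
    Role.TOOL_MAKING: 0.14,
    Role.INGESTION: 0.07,
    Role.OTHER: 0.25,
}


def _base_weights(cfg: SyntheticConfig, eth: Ethogram, labels: list[str]) -> np.ndarray:
    """Role-budgeted base propensities with geometric skew within each role.

    A clip is mostly probe/extract cycling interleaved with posture, tool
    maintenance and tool-wiggling elements, and within a role one or two
    variants dominate (every community has its prototypical grip).
    """
    budgets = {Role(k): v for k, v in (cfg.role_budgets or DEFAULT_ROLE_BUDGETS).items()}
    w = np.zeros(len(labels))
    for role in Role:
        members = [i for i, lab in enumerate(labels) if eth.role(lab) is role]
        if not members:
            continue
        if role in (Role.PROBE, Role.EXTRACT):
            # which probe/extract variant a chimp favors is an individual
            # preference (left on the subject-level draw), so the community
            # base splits the functional budget evenly across variants
            decay = np.ones(len(members))
        else:
            decay = cfg.base_skew ** np.arange(len(members))
        w[members] = budgets.get(role, 0.05) * decay / decay.sum()
    return w / w.sum()


def _planted_pairs(cfg: SyntheticConfig, eth: Ethogram, base: np.ndarray, labels) -> dict:
    # plant affinities between non-functional elements (postures, tool making,
    # wiggle elements) so the probe->extract backbone grammar is untouched;
    # pairs are taken among the commonest such elements, since a community's
    # signature combination is a *habit*: frequent elements used together
    candidates = [
        (lab, base[i])
        for i, lab in enumerate(labels)
        if eth.role(lab) not in (Role.PROBE, Role.EXTRACT)
    ]
    if len(candidates) < 2:
        candidates = [(lab, base[i]) for i, lab in enumerate(labels)]
    candidates = [lab for lab, _w in sorted(candidates, key=lambda t: (-t[1], t[0]))]
    names = _community_names(cfg.n_communities)
    pairs = {}
    for i, c in enumerate(names):
        if cfg.distinct_affinities:
            a, b = (2 * i) % len(candidates), (2 * i + 1) % len(candidates)
        else:
            a, b = 0, 1
        pairs[c] = (candidates[a], candidates[b])
    return pairs


def _community_profiles(
    cfg: SyntheticConfig, labels: list[str], base: np.ndarray, planted: dict, rng
) -> dict:
    # community profiles drift from the base by a lognormal factor, and each
    # community's planted pair gets a modest propensity boost (its habit
    # elements are also among its frequent ones)
    ix = {lab: i for i, lab in enumerate(labels)}
    out = {}
    for c in _community_names(cfg.n_communities):
        z = rng.normal(size=len(labels))
        w = base * np.exp(cfg.profile_divergence * z)
        for lab in planted[c]:
            w[ix[lab]] *= cfg.affinity_propensity_boost
        out[c] = w / w.sum()
    return out


def _subject_propensity(
    profile: np.ndarray, cfg: SyntheticConfig, eth: Ethogram, labels: list[str], rng
) -> np.ndarray:
    """One subject's element propensities, drawn hierarchically.

    How much time a chimp spends in each functional role is fairly stable
    across individuals (everyone probes, extracts, postures), but *which
    variant* of a role it favors — one- or two-handed probing, which
    extraction aid — is strongly individual.  Role totals are therefore
    drawn with high concentration around the community profile and
    within-role variant shares with low concentration
    (``subject_concentration``), giving each subject a small set of favorite
    variants.  Mother-offspring mixing happens downstream on the final
    vector, so kin share favorites.
    """
    p = np.zeros_like(profile)
    role_of = [eth.role(lab) for lab in labels]
    role_totals = {}
    roles = [r for r in Role if any(ro is r for ro in role_of)]
    totals = np.array([profile[[i for i, ro in enumerate(role_of) if ro is r]].sum() for r in roles])
    drawn = rng.dirichlet(np.maximum(cfg.role_concentration * totals, 1e-3))
    role_totals = dict(zip(roles, drawn))
    for r in roles:
        members = [i for i, ro in enumerate(role_of) if ro is r]
        within = profile[members] / profile[members].sum()
        alpha = np.maximum(cfg.subject_concentration * len(members) * within, 1e-3)
        p[members] = role_totals[r] * rng.dirichlet(alpha)
    return p / p.sum()


def _transition_matrix(
    prop: np.ndarray, eth: Ethogram, labels: list[str], planted, cfg: SyntheticConfig
) -> np.ndarray:
    e = len(labels)
    # habits are repetitive: sharpening the propensity row (stereotypy > 1)
    # concentrates each subject's chain on its favorite elements, so clips
    # are personal loops rather than free wandering over the inventory
    row = prop ** cfg.stereotypy
    row /= row.sum()
    t = np.tile(row, (e, 1))
    ix = {lab: i for i, lab in enumerate(labels)}
    a, b = ix[planted[0]], ix[planted[1]]
    t[a, b] *= cfg.affinity_strength
    t[b, a] *= cfg.affinity_strength
    probes = [ix[l] for l in labels if eth.role(l) is Role.PROBE]
    extracts = [ix[l] for l in labels if eth.role(l) is Role.EXTRACT]
    ext_dist = np.zeros(e)
    ext_dist[extracts] = row[extracts]
    if ext_dist.sum() == 0:
        ext_dist[extracts] = 1.0
    ext_dist /= ext_dist.sum()
    t /= t.sum(axis=1, keepdims=True)
    for p in probes:
        t[p] = (1 - cfg.p_functional) * t[p] + cfg.p_functional * ext_dist
    return t


def _stationary(t: np.ndarray) -> np.ndarray:
    """Stationary distribution of the chain (realized element propensities)."""
    vals, vecs = np.linalg.eig(t.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _simulate_clip(start_dist, trans, labels, cfg: SyntheticConfig, rng) -> tuple[list, list]:
    """One clip: element labels and quarter-second onsets, truncated at clip end."""
    max_step = max(2, int(round(2 * cfg.mean_gap_s / 0.25)) - 1)
    times, els = [], []
    t = 0.25 * float(rng.integers(0, 4))
    state = int(rng.choice(len(labels), p=start_dist))
    while t < cfg.clip_len_s:
        times.append(t)
        els.append(labels[state])
        t += 0.25 * float(rng.integers(1, max_step + 1))
        state = int(rng.choice(len(labels), p=trans[state]))
    return els, times


def generate_corpus(config: SyntheticConfig) -> tuple[EventTable, PresenceMatrix, SyntheticTruth]:
    """Generate a seeded multi-community event corpus with ground truth.

    Returns the long-format event table, its presence/absence widening at
    ``config.bin_s``, and the :class:`SyntheticTruth` describing the planted
    structure.  Bit-reproducible for a fixed seed.
    """
    config.validate()
    eth = config.resolved_ethogram()
    labels = eth.labels
    rng = np.random.default_rng(config.seed)
    base = _base_weights(config, eth, labels)
    planted = _planted_pairs(config, eth, base, labels)
    profiles = _community_profiles(config, labels, base, planted, rng)
    mothers = dict(config.mothers or {})

    communities: dict = {}
    props: dict = {}
    realized: dict = {}
    rows = []
    for c in _community_names(config.n_communities):
        subjects = _subject_names(c, config.subjects_per_community)
        for s in subjects:
            communities[s] = c
        # mothers must be drawn before offspring mix with them
        for s in subjects:
            if s not in mothers:
                props[s] = _subject_propensity(profiles[c], config, eth, labels, rng)
        for s in subjects:
            if s in mothers:
                mom = mothers[s]
                if mom not in props:
                    props[mom] = _subject_propensity(
                        profiles[communities.get(mom, c)], config, eth, labels, rng
                    )
                if config.kinship_fresh == "profile":
                    fresh = profiles[c]
                else:
                    fresh = _subject_propensity(profiles[c], config, eth, labels, rng)
                p = config.kinship_mix * props[mom] + (1 - config.kinship_mix) * fresh
                props[s] = p / p.sum()
        for s in subjects:
            trans = _transition_matrix(props[s], eth, labels, planted[c], config)
            realized[s] = _stationary(trans)
            for v in range(config.videos_per_subject):
                vid = f"{s}_V{v+1}"
                mound = f"{c}_M{(v % 3) + 1}"
                els, times = _simulate_clip(realized[s], trans, labels, config, rng)
                for lab, t in zip(els, times):
                    rows.append((c, s, vid, mound, config.mound_type, t, lab, "", ""))

    events = EventTable(
        pd.DataFrame(
            rows,
            columns=[
                "community", "subject", "video_id", "mound_id", "mound_type",
                "start_time_s", "element", "body_position", "hand",
            ],
        )
    )
    matrix = to_presence_matrix(events, eth, bin_s=config.bin_s)
    truth = SyntheticTruth(
        elements=list(labels),
        community_profiles=profiles,
        subject_propensities=realized,
        subject_draws=props,
        planted_pairs=planted,
        mothers=mothers,
        communities=communities,
        config=config,
    )
    return events, matrix, truth


def generate_comparison_dataset(
    config: SyntheticConfig,
) -> tuple[dict, SyntheticTruth]:
    """Per-community wide presence matrices, with optional NA injection.

    Emulates published cross-community supplements: one wide matrix per
    community, cells in {1, 0, NA}, where NA marks context-dependent
    non-applicability.  ``config.na_rate`` injects NA uniformly;
    ``config.na_element_rates`` overrides the rate per element (set one
    element's rate above 0.9 to exercise the NA-column drop policy).
    """
    events, matrix, truth = generate_corpus(config)
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 1_000_003
    )
    out = {}
    for c in _community_names(config.n_communities):
        units = [u for u, cc in matrix.community.items() if cc == c]
        mask = matrix.data.index.get_level_values("unit").isin(units)
        data = matrix.data[mask].copy()
        for el in data.columns:
            rate = config.na_element_rates.get(el, config.na_rate)
            if rate > 0:
                hit = rng.random(len(data)) < rate
                data.loc[hit, el] = np.nan
        out[c] = PresenceMatrix(
            data,
            {u: c for u in units},
            {cv: t for cv, t in matrix.mound_type.items()
             if cv in set(data.index.get_level_values("conversation"))},
        )
    return out, truth


def default_family_config(seed: Optional[int] = None, **overrides) -> SyntheticConfig:
    """One community of three mother-offspring dyads (kinship recovery setup).

    Individual-repertoire analyses keep only well-observed subjects (those
    whose rarefaction curves plateau), so this configuration uses 60 clips
    per subject — the observation depth such subjects reach in published
    camera-trap corpora — against the corpus-wide default of 22.
    """
    overrides.setdefault("videos_per_subject", 60)
    overrides.setdefault("clip_len_s", 60.0)
    cfg = SyntheticConfig(
        n_communities=1,
        subjects_per_community=6,
        seed=seed,
        **overrides,
    )
    subs = _subject_names(_community_names(1)[0], 6)
    cfg.mothers = {subs[1]: subs[0], subs[3]: subs[2], subs[5]: subs[4]}
    return cfg
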