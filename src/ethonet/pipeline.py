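"""End-to-end analysis pipeline with a reproducible run manifest.

One config drives the full chain: load (or simulate) coded events,
validate, widen into presence matrices per mound-type stratum, mine
techniques, run rarefaction, pairwise Fisher screening, repertoire
clustering, cross-community Sørensen profiles, and the ENA models.  Every
stage writes plain CSV/JSON into the output directory and the manifest
records resolved parameters, seeds, package version, and sha256 hashes of
the inputs, so a rerun from the same manifest reproduces deterministic
outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .coding_io import (
    EventTable,
    apply_na_policy,
    read_event_table,
    to_presence_matrix,
    write_presence_matrix,
)
from .ena import (
    StanzaConfig,
    accumulate_adjacency,
    compare_all_groups,
    ena_project,
    group_means_ci,
    position_nodes,
)
from .errors import EthonetError, PipelineStageError
from .ethogram import Ethogram, default_ethogram
from .mining import build_technique_catalog, repertoire_summary, technique_frequencies
from .repertoire import all_pairwise_fisher, cluster_repertoires, is_saturated, rarefaction_curve
from .similarity import community_similarity_profile, pairwise_community_similarity
from .synthetic import SyntheticConfig, generate_corpus

log = logging.getLogger("ethonet")

MOUND_TYPES = ("aerial", "underground")


@dataclass
class RunConfig:
    """Resolved parameters for one full analysis run.

    Every stage parameter defaults to the documented package-wide default;
    a YAML config maps 1:1 onto these fields.  Either ``events_csv`` (with
    optional ``ethogram_csv``) or ``simulate`` must be given.
    """

    output_dir: str = "ethonet_run"
    events_csv: Optional[str] = None
    ethogram_csv: Optional[str] = None
    simulate: Optional[dict] = None      # SyntheticConfig overrides
    bin_s: float = 5.0
    na_threshold: float = 0.90
    k_min: int = 2
    k_max: int = 7
    n_boot: int = 1000
    rarefaction_seed: int = 17
    window: Optional[int] = 4
    ci_level: float = 0.95
    reference_community: Optional[str] = None
    seed: Optional[int] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineStageError("config", "unknown-keys", f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    """Context for one pipeline stage: logs timing, wraps errors."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            manifest.setdefault("stages", {})[name] = {"seconds": round(dt, 3)}
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
                return False
            log.error("stage %s: failed (%s)", name, exc)
            if isinstance(exc, PipelineStageError):
                return False
            code = type(exc).__name__ if isinstance(exc, EthonetError) else "unexpected"
            raise PipelineStageError(name, code, str(exc)) from exc

    return _Ctx()


def run_full_analysis(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Output files (all plain text) land in ``config.output_dir``:
    events.csv, wide_<stratum>.csv, catalog.csv, frequencies.csv,
    repertoire_summary.csv, rarefaction.csv, fisher.csv,
    cluster_matrix.csv, sorensen_<stratum>.csv, ena_points_<stratum>.csv,
    ena_nodes_<stratum>.csv, ena_edges_<stratum>.csv,
    ena_comparisons_<stratum>.csv, and manifest.json.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "ethonet",
        "version": __version__,
        "parameters": config.resolved(),
        "inputs": {},
        "outputs": [],
        "notices": [],
    }

    def emit(name: str, df: pd.DataFrame, **kw):
        path = out / name
        df.to_csv(path, **kw)
        manifest["outputs"].append(name)

    # ---- load or simulate ------------------------------------------------
    with _stage(manifest, "load"):
        if (config.events_csv is None) == (config.simulate is None):
            raise PipelineStageError(
                "load", "config", "give exactly one of events_csv or simulate"
            )
        if config.events_csv is not None:
            ethogram = (
                Ethogram.from_csv(config.ethogram_csv)
                if config.ethogram_csv
                else None
            )
            events = read_event_table(config.events_csv, ethogram)
            manifest["inputs"]["events_csv"] = _sha256(Path(config.events_csv))
            if config.ethogram_csv:
                manifest["inputs"]["ethogram_csv"] = _sha256(Path(config.ethogram_csv))
        else:
            sim = SyntheticConfig(**{"seed": config.seed, **config.simulate})
            events, _, truth = generate_corpus(sim)
            ethogram = sim.resolved_ethogram()
            manifest["inputs"]["simulate"] = {
                "seed": sim.seed,
                "planted_pairs": {c: list(p) for c, p in truth.planted_pairs.items()},
            }
        events.df.pipe(lambda d: d.assign(start_time_s=d.start_time_s.map("{:.2f}".format))) \
            .to_csv(out / "events.csv", index=False)
        manifest["outputs"].append("events.csv")

    # ---- widen per stratum ----------------------------------------------
    strata: dict = {}
    with _stage(manifest, "widen"):
        for mt in MOUND_TYPES:
            sub = events.restrict(mound_type=mt)
            if len(sub) == 0:
                manifest["notices"].append(f"stratum {mt!r} empty: model skipped")
                continue
            eth = ethogram if ethogram is not None else default_ethogram(mt)
            mat = to_presence_matrix(sub, eth, bin_s=config.bin_s)
            mat = apply_na_policy(mat, config.na_threshold)
            strata[mt] = (sub, eth, mat)
            write_presence_matrix(mat, out / f"wide_{mt}.csv")
            manifest["outputs"].append(f"wide_{mt}.csv")
        if not strata:
            raise PipelineStageError("widen", "no-data", "no nonempty stratum")

    # ---- technique mining (per stratum ethogram; catalog pooled) ---------
    with _stage(manifest, "mine"):
        freqs, summaries = {}, {}
        for mt, (sub, eth, _m) in strata.items():
            catalog = build_technique_catalog(sub, eth, config.k_min, config.k_max,
                                              provenance=f"stratum={mt}")
            freq = technique_frequencies(catalog, sub)
            freqs[mt] = (catalog, freq)
            summaries[mt] = repertoire_summary(freq, catalog)
            emit(f"catalog_{mt}.csv", catalog.to_frame(), index=False)
            emit(f"frequencies_{mt}.csv", freq)
            emit(f"repertoire_summary_{mt}.csv", summaries[mt])

    # ---- rarefaction -----------------------------------------------------
    with _stage(manifest, "rarefy"):
        rows = []
        for mt, (sub, _eth, _m) in strata.items():
            for s in sub.subjects:
                curve = rarefaction_curve(
                    sub, subject=s, n_boot=config.n_boot, seed=config.rarefaction_seed
                )
                sat = (
                    is_saturated(curve)[0] if len(curve.x) >= 5 else None
                )
                for x, m_, sd in zip(curve.x, curve.mean, curve.sd):
                    rows.append((mt, s, int(x), m_, sd, sat))
        emit(
            "rarefaction.csv",
            pd.DataFrame(rows, columns=["stratum", "subject", "x", "mean", "sd", "saturated"]),
            index=False,
        )

    # ---- pairwise Fisher screening --------------------------------------
    with _stage(manifest, "fisher"):
        parts = []
        for mt, (_c, freq) in freqs.items():
            res = all_pairwise_fisher(freq)
            res.insert(0, "stratum", mt)
            parts.append(res)
        emit("fisher.csv", pd.concat(parts, ignore_index=True), index=False)

    # ---- clustering ------------------------------------------------------
    with _stage(manifest, "cluster"):
        for mt, (_c, freq) in freqs.items():
            if len(freq.index) >= 2 and freq.to_numpy().sum() > 0:
                cl = cluster_repertoires(freq)
                emit(f"cluster_matrix_{mt}.csv", cl.normalized.loc[cl.leaf_order])
            else:
                manifest["notices"].append(f"stratum {mt!r}: clustering skipped (too few subjects)")

    # ---- Sørensen --------------------------------------------------------
    with _stage(manifest, "sorensen"):
        for mt, (sub, _eth, _m) in strata.items():
            if len(sub.communities) < 2:
                manifest["notices"].append(
                    f"stratum {mt!r}: single community, Sørensen profiles skipped"
                )
                continue
            emit(f"sorensen_{mt}.csv", pairwise_community_similarity(sub, mt))
            ref = config.reference_community or sub.communities[0]
            prof_rows = []
            for c in sub.communities:
                if c == ref:
                    continue
                p = community_similarity_profile(sub, c, ref, mt)
                for s, v in p.values.items():
                    prof_rows.append((c, ref, s, v))
            if prof_rows:
                emit(
                    f"sorensen_profiles_{mt}.csv",
                    pd.DataFrame(prof_rows, columns=["community", "reference", "subject", "mean_sorensen"]),
                    index=False,
                )

    # ---- ENA -------------------------------------------------------------
    with _stage(manifest, "ena"):
        for mt, (_sub, _eth, mat) in strata.items():
            vectors = accumulate_adjacency(mat, StanzaConfig(window=config.window))
            space = position_nodes(ena_project(vectors))
            emit(f"ena_points_{mt}.csv", space.unit_points.join(space.groups))
            emit(f"ena_nodes_{mt}.csv", space.node_positions)
            edges = space.normalized.mean(axis=0).rename("mean_weight").rename_axis(["element_a", "element_b"])
            emit(f"ena_edges_{mt}.csv", edges.reset_index(), index=False)
            emit(f"ena_group_means_{mt}.csv", group_means_ci(space, config.ci_level))
            if space.groups.nunique() >= 2:
                emit(f"ena_comparisons_{mt}.csv", compare_all_groups(space), index=False)
            manifest.setdefault("ena", {})[mt] = {
                "variance_explained": [float(v) for v in space.variance_explained],
                "fit": space.fit,
                "excluded_units": space.excluded_units,
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
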