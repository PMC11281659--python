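"""End-to-end orchestration: census -> coding -> parsimony -> rooting ->
chronology -> Venn timeline -> f-values -> split network (-> prototypes).

``analyze`` is the in-memory pipeline; ``run_pipeline`` adds file I/O, a JSON
manifest with seeds and artifact checksums, and stage-labeled failure
reporting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import sha256_file
from . import __version__
from .census import CensusMatrix, read_census, to_occurrence
from .coding import encode_states, informative_filter, write_nexus
from .loops import (
    non_modular_filter,
    prototype_chronology,
    prototype_venn,
    read_prototype_map,
    write_prototype_chronology,
)
from .network import neighbor_net, split_bootstrap, uncorrected_p, venn_incidence
from .occupancy import compare_categories, f_values
from .parsimony import mp_search
from .rooting import ClockCalibration, build_chronology
from .venn import (
    category_of,
    delimit_phases,
    first_appearances,
    phase_count_table,
    presence_grid,
    venn_groups,
)

log = logging.getLogger("foldchron")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    census_path: str | Path
    labels_path: str | Path
    out_dir: str | Path
    prototype_map_path: str | Path | None = None
    n_states: int = 24
    search_replicates: int = 3
    moves: str = "NNI"
    seed: int = 0
    rooting_mode: str = "max"
    clock_anchors: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 3.6), (1.0, 0.0)]
    )
    marker_map: dict | None = None
    bootstrap_replicates: int = 100


@dataclass
class AnalysisResult:
    character_matrix: object
    informative_report: object
    search: object
    chronology: object
    venn: dict
    timeline: object
    timeline_method: str
    phase_table: object
    fvalues: object
    comparisons: list
    split_system: object
    prototype_nd: dict | None = None
    prototype_venn: dict | None = None


def analyze(
    census: CensusMatrix,
    n_states: int = 24,
    search_replicates: int = 3,
    moves: str = "NNI",
    seed: int = 0,
    rooting_mode: str = "max",
    clock_anchors=None,
    marker_map=None,
    bootstrap_replicates: int = 100,
    prototype_map=None,
) -> AnalysisResult:
    """Run every stage on an in-memory census."""

    def stage(name, fn):
        try:
            out = fn()
            log.info("stage %s done", name)
            return out
        except Exception as exc:  # noqa: BLE001 - relabeled with stage name
            raise PipelineError(name, exc) from exc

    occ = stage("occurrence", lambda: to_occurrence(census))
    cm_full = stage("encode", lambda: encode_states(census, n_states))
    cm, report = stage("informative-filter", lambda: informative_filter(cm_full))
    log.info("characters kept=%d dropped=%d", len(report.kept), len(report.dropped))
    search = stage(
        "mp-search",
        lambda: mp_search(cm, n_replicates=search_replicates, seed=seed, moves=moves),
    )
    cal = ClockCalibration(clock_anchors) if clock_anchors else ClockCalibration()
    chron = stage(
        "rooting-chronology",
        lambda: build_chronology(search.best_trees[0], cm, rooting_mode, cal),
    )
    vg = stage("venn-groups", lambda: venn_groups(occ))

    def _timeline():
        from .venn import VennError, quantile_timeline

        try:
            return delimit_phases(first_appearances(chron.nd, vg), marker_map), "markers"
        except VennError as exc:
            # recovered group minima can be non-monotone on small/noisy data;
            # fall back to nd sextiles and record it in the manifest
            log.warning("marker-based phase delimitation failed (%s); "
                        "using quantile boundaries", exc)
            return quantile_timeline(chron.nd.values()), "quantile-fallback"

    timeline, timeline_method = stage("phase-timeline", _timeline)
    table = stage(
        "phase-table",
        lambda: phase_count_table(chron.nd, vg, "domains", timeline),
    )
    fv = stage("f-values", lambda: f_values(occ))
    category = {fid: category_of(g) for fid, g in vg.items()}
    comparisons = []
    for code in ("A", "B", "E"):
        try:
            comparisons.append(compare_categories(fv, category, code))
        except Exception:  # a category may be empty on tiny fixtures
            pass
    inc = stage("venn-incidence", lambda: venn_incidence(vg))
    if bootstrap_replicates > 0:
        splits = stage(
            "split-network",
            lambda: split_bootstrap(inc, n_replicates=bootstrap_replicates, seed=seed),
        )
    else:
        splits = stage("split-network", lambda: neighbor_net(uncorrected_p(inc)))
    proto_nd = proto_vg = None
    if prototype_map is not None:
        nonmod = stage(
            "loop-filter", lambda: non_modular_filter(prototype_map, chron.nd)
        )
        proto_nd = stage(
            "loop-chronology",
            lambda: prototype_chronology(prototype_map, chron.nd, nonmod),
        )
        proto_vg = stage(
            "loop-venn", lambda: prototype_venn(prototype_map, vg, nonmod)
        )
    return AnalysisResult(
        character_matrix=cm,
        informative_report=report,
        search=search,
        chronology=chron,
        venn=vg,
        timeline=timeline,
        timeline_method=timeline_method,
        phase_table=table,
        fvalues=fv,
        comparisons=comparisons,
        split_system=splits,
        prototype_nd=proto_nd,
        prototype_venn=proto_vg,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """File-based pipeline run; returns (and writes) the JSON manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    census = read_census(cfg.census_path, cfg.labels_path)
    pm = (
        read_prototype_map(cfg.prototype_map_path)
        if cfg.prototype_map_path
        else None
    )
    res = analyze(
        census,
        n_states=cfg.n_states,
        search_replicates=cfg.search_replicates,
        moves=cfg.moves,
        seed=cfg.seed,
        rooting_mode=cfg.rooting_mode,
        clock_anchors=cfg.clock_anchors,
        marker_map=cfg.marker_map,
        bootstrap_replicates=cfg.bootstrap_replicates,
        prototype_map=pm,
    )
    artifacts: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts[name] = sha256_file(path)

    emit("characters.nex", lambda p: write_nexus(res.character_matrix, p))
    emit(
        "tree.nwk",
        lambda p: Path(p).write_text(res.search.best_trees[0].to_newick() + "\n"),
    )
    emit(
        "rooted_tree.nwk",
        lambda p: Path(p).write_text(res.chronology.tree.to_newick() + "\n"),
    )
    emit("chronology.tsv", lambda p: res.chronology.write_tsv(p))

    def write_features(p):
        rows = [
            {
                "id": fid,
                "nd": res.chronology.nd[fid],
                "venn": g.name,
                "category": category_of(g),
                "phase": res.timeline.phase_name(res.chronology.nd[fid]),
            }
            for fid, g in sorted(res.venn.items())
        ]
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)

    emit("features.tsv", write_features)
    emit("phase_table.tsv", lambda p: res.phase_table.write_tsv(p))
    emit(
        "presence_grid.tsv",
        lambda p: presence_grid(res.chronology.nd, res.venn, res.timeline).to_csv(
            p, sep="\t"
        ),
    )
    emit(
        "fvalues.tsv",
        lambda p: res.fvalues.rename_axis("family").to_csv(p, sep="\t"),
    )
    emit("splits.nex", lambda p: res.split_system.to_nexus(p))
    if res.prototype_nd is not None:
        emit(
            "prototype_chronology.tsv",
            lambda p: write_prototype_chronology(
                res.prototype_nd, res.prototype_venn, p
            ),
        )
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "n_states": cfg.n_states,
        "search_replicates": cfg.search_replicates,
        "moves": cfg.moves,
        "rooting_mode": cfg.rooting_mode,
        "bootstrap_replicates": cfg.bootstrap_replicates,
        "tree_length": res.search.length,
        "retention_index": res.search.retention_index,
        "g1": res.search.g1,
        "characters_kept": len(res.informative_report.kept),
        "characters_dropped": len(res.informative_report.dropped),
        "phase_boundaries": res.timeline.boundaries,
        "phase_boundary_method": res.timeline_method,
        "prototype_stages_run": res.prototype_nd is not None,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    marker.unlink()
    return manifest
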