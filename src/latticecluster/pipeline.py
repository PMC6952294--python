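"""Two-stage clustering workflow.

Stage 0: discard bad images (few spots or not indexed).
Stage 1: hierarchical clustering on the CS6Dist lattice metric, grown
bottom-up along the dendrogram until each cluster's merged data reach a
minimally acceptable completeness ("just enough lattice clustering").
Stage 2: within each lattice cluster, clustering on sqrt(1 - CC) of the
merged-image reflection intensities, sliced at the largest-gap level.

No space-group prefilter is applied anywhere: all cells are compared as
primitive triclinic lattices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .cells import UnitCell, niggli_reduce
from .cluster import LINKAGES, ClusterAssignment, Dendrogram, hierarchical, slice_dendrogram
from .metrics import METRICS, DistanceMatrix, distance_matrix
from .reflections import (
    ImageRecord,
    MIN_COMMON_DEFAULT,
    ReflectionSet,
    cc_distance_matrix,
    completeness,
    merge,
    spot_filter,
)

__all__ = ["PipelineConfig", "PurityReport", "run_two_stage", "purity", "TwoStageResult"]


@dataclass
class PipelineConfig:
    """Configuration for the two-stage run; every field has a documented
    default and the rng_seed is echoed in all outputs."""

    min_spots: int = 10
    metric: str = "cs6dist"
    linkage: str = "average"
    slice_level: float | None = None   # None = auto (completeness-driven growth)
    completeness_target: float = 0.7
    d_min: float = 2.5
    min_common: int = MIN_COMMON_DEFAULT
    stage2_min_gap: float = 0.15       # minimum CC-distance gap to split on
    rng_seed: int = 0
    out_dir: str | None = None
    two_stage: bool = True             # False = lattice-only clustering

    def __post_init__(self):
        if not 0 <= self.completeness_target <= 1:
            raise ValueError("completeness_target must be in [0, 1]")
        if self.d_min <= 0:
            raise ValueError("d_min must be > 0")
        if self.min_spots < 0:
            raise ValueError("min_spots must be >= 0")
        if self.linkage not in LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}; choose from {LINKAGES}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; choose from {sorted(METRICS)}")
        if self.min_common < 2:
            raise ValueError("min_common must be >= 2")
        if self.stage2_min_gap < 0:
            raise ValueError("stage2_min_gap must be >= 0")


@dataclass
class ClusterPurity:
    cluster: str
    size: int
    majority_species: str
    majority_fraction: float
    medoid_id: str


@dataclass
class PurityReport:
    clusters: list[ClusterPurity]
    overall: float

    def __post_init__(self):
        if not 0 <= self.overall <= 1 + 1e-12:
            raise ValueError("purity must be in [0, 1]")


@dataclass
class TwoStageResult:
    """Everything produced by a pipeline run."""

    labels: dict[str, str]             # image id -> composite cluster label
    medoids: dict[str, str]            # cluster label -> medoid image id
    discarded: list[str]               # image ids routed to the discard cluster
    stage1: ClusterAssignment | None
    dendrogram: Dendrogram | None
    purity_report: "PurityReport | None"
    log: list[str] = field(default_factory=list)

    def log_text(self) -> str:
        return "\n".join(self.log) + "\n"

    def assignment_tsv(self) -> str:
        lines = ["id\tcluster\tis_medoid"]
        medoid_ids = set(self.medoids.values())
        for ident in sorted(self.labels):
            lines.append(
                f"{ident}\t{self.labels[ident]}\t{1 if ident in medoid_ids else 0}"
            )
        for ident in sorted(self.discarded):
            lines.append(f"{ident}\tdiscard\t0")
        return "\n".join(lines) + "\n"


def _merged_completeness(
    sets: list[ReflectionSet], d_min: float
) -> float:
    if not sets:
        return 0.0
    merged = merge(sets, compatibility=None)
    return completeness(merged, d_min)


def _grow_to_completeness(
    dg: Dendrogram,
    start_labels: np.ndarray,
    image_sets: list[ReflectionSet | None],
    cfg: PipelineConfig,
    log: list[str],
) -> np.ndarray:
    """Grow clusters bottom-up along the dendrogram merge order until each
    reaches the completeness target; clusters already at target stop
    merging unless an unsatisfied neighbour absorbs them."""
    n = dg.n_leaves
    comp_cache: dict[frozenset, float] = {}

    def comp_of(members: frozenset) -> float:
        if members not in comp_cache:
            sets = [image_sets[i] for i in members if image_sets[i] is not None]
            comp_cache[members] = _merged_completeness(sets, cfg.d_min)
        return comp_cache[members]

    # current partition as an id -> member-set map aligned with dendrogram nodes
    groups: dict[int, frozenset] = {}
    start_groups: dict[int, set] = {}
    for i, lab in enumerate(start_labels):
        start_groups.setdefault(int(lab), set()).add(i)
    # map each leaf to its starting group representative
    leaf_group = {i: frozenset(start_groups[int(start_labels[i])]) for i in range(n)}
    node_members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    active: dict[frozenset, bool] = {}
    for g in {leaf_group[i] for i in range(n)}:
        active[g] = True
    current_of_leaf = dict(leaf_group)

    for k, (i, j, h, _) in enumerate(dg.merges):
        node_members[n + k] = node_members[i] | node_members[j]
        # the current clusters containing the two children
        rep_i = current_of_leaf[min(node_members[i])]
        rep_j = current_of_leaf[min(node_members[j])]
        if rep_i == rep_j:
            continue
        sat_i = comp_of(rep_i) >= cfg.completeness_target
        sat_j = comp_of(rep_j) >= cfg.completeness_target
        if sat_i and sat_j:
            continue
        merged = rep_i | rep_j
        for leaf in merged:
            current_of_leaf[leaf] = merged
    clusters = {}
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        g = current_of_leaf[i]
        if g not in clusters:
            clusters[g] = len(clusters)
        labels[i] = clusters[g]
    unmet = [
        g for g in clusters
        if comp_of(g) < cfg.completeness_target
    ]
    if unmet:
        log.append(
            f"notice: completeness target {cfg.completeness_target:.2f} "
            f"unreachable for {len(unmet)} cluster(s); emitting them as-is"
        )
    return labels


def _largest_gap_assignment(
    dm: DistanceMatrix, linkage: str, min_gap: float = 0.0
) -> np.ndarray:
    if dm.n < 2:
        return np.zeros(dm.n, dtype=int)
    dg = hierarchical(dm, linkage)
    level = dg.largest_gap_level(min_gap)
    return slice_dendrogram(dg, level, dm).labels


def run_two_stage(
    images: Sequence[ImageRecord], cfg: PipelineConfig,
    truth: dict[str, str] | None = None,
) -> TwoStageResult:
    """Run the full filter / lattice-cluster / CC-cluster workflow.

    Deterministic given the config: rerunning with identical inputs and
    config produces byte-identical outputs.
    """
    log = [
        "latticecluster two-stage run",
        "config: " + " ".join(
            f"{k}={v}" for k, v in sorted(asdict(cfg).items())
        ),
    ]
    kept, discarded = spot_filter(images, cfg.min_spots)
    log.append(f"stage 0: kept {len(kept)} image(s), discarded {len(discarded)}")
    if not kept:
        raise ValueError("no images survive spot filtering")

    ids = [img.id for img in kept]
    cells = [niggli_reduce(img.cell).cell for img in kept]
    sets = [img.reflections for img in kept]

    if len(kept) == 1:
        labels = {ids[0]: "0"}
        medoids = {"0": ids[0]}
        report = purity_from_labels(labels, truth) if truth else None
        log.append("single kept image: trivial assignment")
        result = TwoStageResult(labels, medoids, [im.id for im in discarded],
                                None, None, report, log)
        _write_outputs(result, cfg)
        return result

    dm = distance_matrix(cells, cfg.metric, ids)
    dg = hierarchical(dm, cfg.linkage)

    have_reflections = any(s is not None for s in sets)
    if cfg.slice_level is not None:
        start_labels = slice_dendrogram(dg, cfg.slice_level, dm).labels
        log.append(f"stage 1: fixed slice level {cfg.slice_level}")
    else:
        start_labels = np.arange(len(kept))
    if have_reflections and cfg.completeness_target > 0:
        stage1_labels = _grow_to_completeness(dg, start_labels, sets, cfg, log)
        log.append(
            "stage 1: grew clusters to completeness target "
            f"{cfg.completeness_target:.2f} at d_min {cfg.d_min:.2f}"
        )
    elif cfg.slice_level is not None:
        stage1_labels = start_labels
    else:
        level = dg.largest_gap_level()
        stage1_labels = slice_dendrogram(dg, level, dm).labels
        log.append(
            f"stage 1: no reflections available; largest-gap slice at {level:.4f}"
        )
    stage1 = _relabel(dm, stage1_labels)
    log.append(f"stage 1: {stage1.k} lattice cluster(s)")

    labels: dict[str, str] = {}
    medoids: dict[str, str] = {}
    if cfg.two_stage and have_reflections:
        for ci in range(stage1.k):
            members = stage1.members(ci)
            member_sets = [sets[i] for i in members]
            usable = [i for i, s in zip(members, member_sets) if s is not None]
            if len(usable) < 2:
                for i in members:
                    labels[ids[i]] = f"{ci}.0"
                medoids[f"{ci}.0"] = ids[stage1.medoids[ci]]
                continue
            sub_sets = [sets[i] for i in usable]
            cc_dm, undefined = cc_distance_matrix(
                sub_sets, cfg.min_common, [ids[i] for i in usable]
            )
            if undefined:
                log.append(
                    f"stage 2: cluster {ci}: {len(undefined)} pair(s) with "
                    "undefined CC set to matrix maximum"
                )
            sub_labels = _largest_gap_assignment(cc_dm, cfg.linkage, cfg.stage2_min_gap)
            sub = _relabel(cc_dm, sub_labels)
            pos_of = {item: p for p, item in enumerate(usable)}
            for p, i in enumerate(usable):
                labels[ids[i]] = f"{ci}.{sub.labels[p]}"
            for sj, m in enumerate(sub.medoids):
                medoids[f"{ci}.{sj}"] = ids[usable[m]]
            # members without reflections stay with the lattice cluster medoid
            for i in members:
                if i not in pos_of:
                    labels[ids[i]] = f"{ci}.0"
        log.append(f"stage 2: {len(set(labels.values()))} final cluster(s)")
    else:
        if cfg.two_stage and not have_reflections:
            log.append("stage 2 skipped: no reflection data supplied")
        for ci in range(stage1.k):
            for i in stage1.members(ci):
                labels[ids[i]] = str(ci)
            medoids[str(ci)] = ids[stage1.medoids[ci]]

    report = purity_from_labels(labels, truth) if truth else None
    result = TwoStageResult(
        labels, medoids, sorted(im.id for im in discarded), stage1, dg, report, log
    )
    _write_outputs(result, cfg)
    return result


def _relabel(dm: DistanceMatrix, labels: np.ndarray) -> ClusterAssignment:
    order: dict[int, int] = {}
    for lab in labels:
        if int(lab) not in order:
            order[int(lab)] = len(order)
    new = np.array([order[int(lab)] for lab in labels])
    medoids = []
    for ci in range(len(order)):
        members = np.nonzero(new == ci)[0]
        sub = dm.d[np.ix_(members, members)]
        medoids.append(int(members[int(np.argmin(sub.sum(axis=1)))]))
    objective = float(sum(dm.d[i, medoids[new[i]]] for i in range(dm.n)))
    return ClusterAssignment(new, medoids, objective, list(dm.labels))


def purity_from_labels(
    labels: dict[str, str], truth: dict[str, str]
) -> PurityReport:
    """Size-weighted majority-species purity of a composite labelling."""
    missing = [ident for ident in labels if ident not in truth]
    if missing:
        raise ValueError(f"truth labels missing for items: {missing[:5]}")
    by_cluster: dict[str, list[str]] = {}
    for ident, cl in labels.items():
        by_cluster.setdefault(cl, []).append(ident)
    clusters = []
    weighted = 0.0
    total = 0
    for cl in sorted(by_cluster):
        members = by_cluster[cl]
        counts: dict[str, int] = {}
        for ident in members:
            counts[truth[ident]] = counts.get(truth[ident], 0) + 1
        species, cnt = max(sorted(counts.items()), key=lambda kv: kv[1])
        frac = cnt / len(members)
        clusters.append(ClusterPurity(cl, len(members), species, frac, members[0]))
        weighted += frac * len(members)
        total += len(members)
    return PurityReport(clusters, weighted / total if total else 1.0)


def purity(assignment: ClusterAssignment, truth: Sequence[str]) -> PurityReport:
    """Purity of a flat ClusterAssignment against per-item species labels."""
    if len(truth) != len(assignment.labels):
        raise ValueError("truth labels must cover all assigned items")
    labels = {
        assignment.item_labels[i]: str(assignment.labels[i])
        for i in range(len(assignment.labels))
    }
    truth_map = {assignment.item_labels[i]: truth[i] for i in range(len(truth))}
    report = purity_from_labels(labels, truth_map)
    # medoid ids from the assignment, not first members
    medoid_of = {
        str(ci): assignment.item_labels[m] for ci, m in enumerate(assignment.medoids)
    }
    clusters = [
        ClusterPurity(c.cluster, c.size, c.majority_species, c.majority_fraction,
                      medoid_of.get(c.cluster, c.medoid_id))
        for c in report.clusters
    ]
    return PurityReport(clusters, report.overall)


def _write_outputs(result: TwoStageResult, cfg: PipelineConfig) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "assignments.tsv").write_text(result.assignment_tsv(), encoding="utf-8")
    (out / "run.log").write_text(result.log_text(), encoding="utf-8")
    if result.purity_report is not None:
        lines = ["cluster\tsize\tmajority_species\tmajority_fraction\tmedoid_id"]
        for c in result.purity_report.clusters:
            lines.append(
                f"{c.cluster}\t{c.size}\t{c.majority_species}"
                f"\t{c.majority_fraction:.6f}\t{c.medoid_id}"
            )
        lines.append(f"overall\t\t\t{result.purity_report.overall:.6f}\t")
        (out / "purity.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")
    if result.dendrogram is not None:
        (out / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n",
                                            encoding="utf-8")
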