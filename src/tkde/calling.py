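"""Pipeline orchestration and the binding-site / constitutive-site rules.

Per chromosome: gather peak centers, partition them with the binary range
tree (or treat the chromosome as one node when the tree is disabled), run the
KDE mode finder on each terminal node, and turn each modal region into a
binding-site call when at least one cell line supports it with the required
number of distinct replicate datasets. A call is constitutive when its
supported cell-line fraction strictly exceeds the constitutive cutoff
("more than 90%" of available cell lines by default).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .kde_modes import DensityModel, ModalRegion, delineate_regions, find_modes
from .peaks_io import BindingSiteCall, DatasetManifest, PeakCenter, load_centers
from .range_tree import TerminalNode, build_terminal_nodes

logger = logging.getLogger("tkde")


@dataclass
class CallingConfig:
    """Tuning parameters of the full pipeline.

    bandwidth: Gaussian kernel standard deviation in bp (100-400 bp suits
    transcription factors with narrow peaks; 100 is the default operating
    point). coverage_cutoff governs the range-tree stopping rule,
    constitutive_cutoff the strict "more than" fraction test at calling;
    both default to 0.90 but are independent knobs. min_replicates is the
    number of distinct datasets of one cell line a modal region must contain
    (capped at the cell line's dataset count; 1 disables the filter).
    disable_tree skips the range tree and hands each whole chromosome to the
    mode finder — slow, but the oracle the tree is checked against.
    """

    bandwidth: float = 100.0
    coverage_cutoff: float = 0.90
    constitutive_cutoff: float = 0.90
    min_replicates: int = 2
    strict_parsing: bool = False
    disable_tree: bool = False

    def __post_init__(self) -> None:
        if not (self.bandwidth > 0):
            raise ParameterError(f"bandwidth must be positive: {self.bandwidth}")
        for name in ("coverage_cutoff", "constitutive_cutoff"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ParameterError(f"{name} must be in (0, 1]: {v}")
        if self.min_replicates < 1:
            raise ParameterError(f"min_replicates must be >= 1: {self.min_replicates}")


@dataclass
class RunLog:
    """Per-chromosome tallies reported after a run."""

    centers: dict[str, int] = field(default_factory=dict)
    nodes: dict[str, int] = field(default_factory=dict)
    regions: dict[str, int] = field(default_factory=dict)
    sites: dict[str, int] = field(default_factory=dict)
    constitutive: dict[str, int] = field(default_factory=dict)

    @property
    def total_regions(self) -> int:
        return sum(self.regions.values())


def support_by_cell_line(
    member_dataset_ids,
    manifest: DatasetManifest,
    min_replicates: int,
) -> dict[str, bool]:
    """Which cell lines support a modal region.

    Cell line L is supported iff the region holds centers from at least
    min(min_replicates, number of datasets of L) *distinct* datasets of L;
    several centers from one dataset count once.
    """
    distinct: dict[str, set] = defaultdict(set)
    for ds in member_dataset_ids:
        try:
            cl = manifest.cell_line_of[ds]
        except KeyError as exc:
            raise ValidationError(f"dataset_id not in manifest: {ds!r}") from exc
        distinct[cl].add(ds)
    return {
        cl: len(distinct.get(cl, ())) >= min(min_replicates, manifest.datasets_per_cell_line[cl])
        for cl in manifest.cell_lines
    }


def call_sites(
    regions: list[tuple[ModalRegion, np.ndarray]],
    chrom: str,
    manifest: DatasetManifest,
    config: CallingConfig,
) -> list[BindingSiteCall]:
    """Apply the binding-site and constitutive rules to modal regions.

    Each element of ``regions`` pairs a ModalRegion with the dataset ids of
    its member centers. A region is emitted iff at least one cell line
    supports it; constitutive iff the supported fraction strictly exceeds
    config.constitutive_cutoff.
    """
    calls: list[BindingSiteCall] = []
    for region, dataset_ids in regions:
        support = support_by_cell_line(dataset_ids, manifest, config.min_replicates)
        n_supported = sum(support.values())
        if n_supported == 0:
            continue
        fraction = n_supported / manifest.n_cell_lines
        calls.append(
            BindingSiteCall(
                chrom=chrom,
                summit=region.summit,
                region_start=region.left,
                region_end=region.right,
                n_supporting_cell_lines=n_supported,
                cell_line_fraction=fraction,
                n_peak_centers=len(region.member_indices),
                constitutive=fraction > config.constitutive_cutoff,
            )
        )
    calls.sort(key=lambda c: c.summit)
    return calls


def _node_regions(node: TerminalNode, config: CallingConfig) -> list[tuple[ModalRegion, np.ndarray]]:
    model = DensityModel(positions=node.positions, bandwidth=config.bandwidth)
    modes = find_modes(model)
    # DensityModel sorts its input; node positions are already sorted, so the
    # parallel dataset_ids stay aligned
    regions = delineate_regions(model, modes)
    return [(r, node.dataset_ids[r.member_indices]) for r in regions]


def run_tkde_centers(
    centers: list[PeakCenter],
    manifest: DatasetManifest,
    config: CallingConfig,
) -> tuple[list[BindingSiteCall], RunLog]:
    """Run the pipeline on already-loaded peak centers (all chromosomes)."""
    by_chrom: dict[str, list[PeakCenter]] = defaultdict(list)
    for c in centers:
        by_chrom[c.chrom].append(c)
    if not by_chrom:
        logger.warning("no peak centers in input; emitting no calls")

    all_calls: list[BindingSiteCall] = []
    runlog = RunLog()
    for chrom in sorted(by_chrom):
        chrom_centers = by_chrom[chrom]
        if config.disable_tree:
            pos = np.sort(np.array([c.position for c in chrom_centers]))
            order = np.argsort([c.position for c in chrom_centers], kind="stable")
            ids = np.array([c.dataset_id for c in chrom_centers], dtype=object)[order]
            nodes = [TerminalNode(chrom, pos, ids, cell_line_coverage=1.0)]
        else:
            nodes = build_terminal_nodes(chrom_centers, manifest, config.coverage_cutoff)
        regions: list[tuple[ModalRegion, np.ndarray]] = []
        for node in nodes:
            regions.extend(_node_regions(node, config))
        calls = call_sites(regions, chrom, manifest, config)
        runlog.centers[chrom] = len(chrom_centers)
        runlog.nodes[chrom] = len(nodes)
        runlog.regions[chrom] = len(regions)
        runlog.sites[chrom] = len(calls)
        runlog.constitutive[chrom] = sum(c.constitutive for c in calls)
        logger.info(
            "%s: %d centers -> %d nodes -> %d sites (%d constitutive)",
            chrom, len(chrom_centers), len(nodes), len(calls), runlog.constitutive[chrom],
        )
        all_calls.extend(calls)
    all_calls.sort(key=lambda c: (c.chrom, c.summit))
    return all_calls, runlog


def run_tkde(manifest: DatasetManifest, config: CallingConfig) -> tuple[list[BindingSiteCall], RunLog]:
    """Read every dataset in the manifest and run the full pipeline."""
    centers = load_centers(manifest, strict=config.strict_parsing)
    return run_tkde_centers(centers, manifest, config)


def count_modal_regions(
    centers: list[PeakCenter],
    manifest: DatasetManifest,
    config: CallingConfig,
) -> int:
    """Total modal regions over all chromosomes, before any calling filter."""
    by_chrom: dict[str, list[PeakCenter]] = defaultdict(list)
    for c in centers:
        by_chrom[c.chrom].append(c)
    total = 0
    for chrom, chrom_centers in by_chrom.items():
        nodes = build_terminal_nodes(chrom_centers, manifest, config.coverage_cutoff)
        for node in nodes:
            total += len(_node_regions(node, config))
    return total
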