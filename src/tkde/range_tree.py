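"""Binary range tree over 1-D peak centers.

One tree per chromosome. The sorted centers start in the root; each node is
split at its midrange m = (min + max)/2 with left = {x < m} and
right = {x >= m}. A node becomes terminal when splitting it would leave either
prospective child with peak centers from too few of the manifest's cell
lines: a child is acceptable only when its covered fraction strictly exceeds
``coverage_cutoff`` (or the child covers every cell line). With 55 cell lines
and cutoff 0.9 the boundary 49.5 is unattainable, so this is simply "a child
covering 49 < 49.5 lines refuses the split"; when cutoff * n_cell_lines is an
integer, a child sitting exactly on the boundary also refuses it — landing on
the boundary means the split is already eroding cell-line coverage, the
signature of a split running through a binding-site cluster rather than
between clusters. Additional forced stops: a node with at most one distinct
position, or a split that would leave a child empty (all positions tied).

"Available cell lines" means all cell lines in the manifest, genome-wide, and
a cell line counts as present in a node as soon as one of its datasets
contributes a single center; the stricter replicate rule belongs to the
calling stage, not to the partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .peaks_io import DatasetManifest, PeakCenter


@dataclass
class TerminalNode:
    """A contiguous run of sorted peak centers; the unit of KDE work."""

    chrom: str
    positions: np.ndarray  # sorted ascending, float64
    dataset_ids: np.ndarray  # parallel to positions, dtype=object
    cell_line_coverage: float

    def __len__(self) -> int:
        return len(self.positions)


def build_terminal_nodes(
    centers: Sequence[PeakCenter],
    manifest: DatasetManifest,
    coverage_cutoff: float = 0.90,
) -> list[TerminalNode]:
    """Partition one chromosome's centers into terminal nodes.

    Every input center lands in exactly one node; concatenating the returned
    nodes in genomic order reproduces the sorted input. The root itself may
    fall below the coverage cutoff, in which case it is the single terminal
    node (its children would only be worse).
    """
    if not (0.0 < coverage_cutoff <= 1.0):
        raise ParameterError(f"coverage_cutoff must be in (0, 1]: {coverage_cutoff}")
    if len(centers) == 0:
        return []
    chroms = {c.chrom for c in centers}
    if len(chroms) != 1:
        raise ParameterError(f"centers span multiple chromosomes: {sorted(chroms)}")
    chrom = chroms.pop()

    pos = np.array([c.position for c in centers], dtype=float)
    ids = np.array([c.dataset_id for c in centers], dtype=object)
    order = np.argsort(pos, kind="stable")
    pos, ids = pos[order], ids[order]

    # integer cell-line codes for fast distinct-coverage counts
    cl_index = {cl: i for i, cl in enumerate(manifest.cell_lines)}
    try:
        codes = np.array([cl_index[manifest.cell_line_of[d]] for d in ids], dtype=np.int64)
    except KeyError as exc:
        raise ParameterError(f"dataset_id not in manifest: {exc.args[0]}") from exc

    n_lines = manifest.n_cell_lines
    threshold = coverage_cutoff * n_lines

    def child_ok(lo: int, hi: int) -> bool:
        n_cov = len(np.unique(codes[lo:hi]))
        return n_cov > threshold or n_cov == n_lines

    nodes: list[TerminalNode] = []
    stack: list[tuple[int, int]] = [(0, len(pos))]
    while stack:
        lo, hi = stack.pop()
        lo_pos, hi_pos = pos[lo], pos[hi - 1]
        if lo_pos == hi_pos:  # <=1 distinct position: midrange split makes no progress
            nodes.append(_make_node(chrom, pos, ids, codes, lo, hi, n_lines))
            continue
        mid = (lo_pos + hi_pos) / 2.0
        cut = lo + int(np.searchsorted(pos[lo:hi], mid, side="left"))
        if cut == lo or cut == hi:  # a child would be empty
            nodes.append(_make_node(chrom, pos, ids, codes, lo, hi, n_lines))
            continue
        if not (child_ok(lo, cut) and child_ok(cut, hi)):
            nodes.append(_make_node(chrom, pos, ids, codes, lo, hi, n_lines))
            continue
        # push right first so nodes pop out in genomic order
        stack.append((cut, hi))
        stack.append((lo, cut))
    nodes.sort(key=lambda n: n.positions[0])
    return nodes


def _make_node(
    chrom: str,
    pos: np.ndarray,
    ids: np.ndarray,
    codes: np.ndarray,
    lo: int,
    hi: int,
    n_lines: int,
) -> TerminalNode:
    coverage = len(np.unique(codes[lo:hi])) / n_lines
    return TerminalNode(
        chrom=chrom,
        positions=pos[lo:hi].copy(),
        dataset_ids=ids[lo:hi].copy(),
        cell_line_coverage=coverage,
    )
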