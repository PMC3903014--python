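"""Shared test utilities, including the independent dense-grid mode oracle."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.stats import norm

from tkde.peaks_io import DatasetManifest, ManifestEntry, PeakCenter


def grid_density(positions: np.ndarray, h: float, grid: np.ndarray) -> np.ndarray:
    """KDE evaluated via scipy's normal pdf — independent of the package's path."""
    out = np.zeros_like(grid)
    for i0 in range(0, grid.size, 8192):
        blk = grid[i0 : i0 + 8192]
        out[i0 : i0 + 8192] = norm.pdf((blk[:, None] - positions[None, :]) / h).sum(axis=1)
    return out / (positions.size * h)


def grid_mode_positions(
    positions: np.ndarray,
    h: float,
    step_frac: float = 1e-3,
    pad: float = 4.0,
    rel_dip: float = 1e-10,
) -> np.ndarray:
    """Brute-force local maxima of the KDE on a dense grid.

    Interior grid points that beat their left neighbour strictly and their
    right neighbour at least weakly are candidate maxima; candidates without
    an intervening relative dip of at least rel_dip are merged (the pair is a
    single mode blurred by grid/float resolution).
    """
    positions = np.asarray(positions, dtype=float)
    grid = np.arange(positions.min() - pad * h, positions.max() + pad * h, step_frac * h)
    d = grid_density(positions, h, grid)
    cand = np.flatnonzero((d[1:-1] > d[:-2]) & (d[1:-1] >= d[2:])) + 1
    keep: list[int] = []
    for i in cand:
        if not keep:
            keep.append(int(i))
            continue
        j = keep[-1]
        dip = d[j : i + 1].min()
        if dip < (1.0 - rel_dip) * min(d[i], d[j]):
            keep.append(int(i))
        elif d[i] > d[j]:
            keep[-1] = int(i)
    return grid[keep]


def toy_manifest(n_cell_lines: int, replicates: int = 2) -> DatasetManifest:
    """An in-memory manifest (file paths are placeholders, never opened)."""
    entries = [
        ManifestEntry(f"CL{c:02d}_rep{r}", Path(f"CL{c:02d}_rep{r}.bed"), f"CL{c:02d}", f"rep{r}")
        for c in range(n_cell_lines)
        for r in range(1, replicates + 1)
    ]
    return DatasetManifest(entries=entries)


def centers_at(spec: list[tuple[float, str]], chrom: str = "chr1") -> list[PeakCenter]:
    return [PeakCenter(chrom, pos, ds) for pos, ds in spec]
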