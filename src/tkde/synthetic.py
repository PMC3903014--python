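"""Synthetic multi-cell-line peak catalogs with known ground truth.

The generator emulates the situation the method targets: a panel of cell
lines, each assayed in replicate, where some loci are bound in every cell
line (constitutive), some in a random subset (cell-line specific), and each
dataset also carries unstructured background peaks. Observed peak centers
scatter around their true locus with Gaussian jitter (clipped at +/-5 sigma so
well-spaced loci stay separable), modelling the peak-caller's localization
noise. Everything is deterministic given the seed.

A "specific" locus draws its presence set once, Bernoulli per cell line; a
draw equal to the full cell-line universe is redrawn, because a locus present
everywhere is constitutive by definition and would contradict its planted
kind (with an all-ones draw, presence of one arbitrary cell line is dropped
instead after 100 failed redraws, which can only happen when the presence
probability is ~1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .peaks_io import BindingSiteCall, DatasetManifest, ManifestEntry, PeakCenter

TRUTH_COLUMNS = ("position", "kind", "presence")


@dataclass
class SimulationConfig:
    n_cell_lines: int = 10
    replicates_per_cell_line: int = 2
    n_constitutive_loci: int = 20
    n_specific_loci: int = 0
    specific_presence_prob: float = 0.5
    noise_peaks_per_dataset: int = 0
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    min_locus_spacing: int = 2_000
    center_jitter_sd: float = 20.0
    peak_width_min: int = 150
    peak_width_max: int = 350
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cell_lines, self.replicates_per_cell_line, self.n_constitutive_loci,
            self.n_specific_loci, self.noise_peaks_per_dataset,
        )
        if any(c < 0 for c in counts) or self.n_cell_lines == 0 or self.replicates_per_cell_line == 0:
            raise ConfigurationError("counts must be non-negative (cell lines and replicates positive)")
        if self.center_jitter_sd < 0:
            raise ConfigurationError("center_jitter_sd must be >= 0")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ConfigurationError("dropout_prob must be in [0, 1]")
        if self.peak_width_min < 1 or self.peak_width_max < self.peak_width_min:
            raise ConfigurationError("peak width range invalid")
        expected_width = (self.peak_width_min + self.peak_width_max) / 2.0
        if self.min_locus_spacing <= 2 * expected_width:
            raise ConfigurationError(
                f"min_locus_spacing {self.min_locus_spacing} must exceed twice the "
                f"expected peak width ({expected_width})"
            )


@dataclass(frozen=True)
class Locus:
    position: float
    kind: str  # constitutive | specific | noise
    presence: frozenset[str]


@dataclass
class SyntheticTruth:
    loci: list[Locus]
    chrom: str

    def constitutive_positions(self) -> np.ndarray:
        return np.array(sorted(l.position for l in self.loci if l.kind == "constitutive"))


@dataclass
class RecoveryReport:
    recall: float
    precision: float
    n_matched: int
    n_truth: int
    n_calls: int
    distances: np.ndarray  # |summit - locus| for matched pairs, sorted

    @property
    def median_distance(self) -> float:
        return float(np.median(self.distances)) if self.distances.size else math.nan


def _place_loci(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    """Uniform placement subject to the pairwise spacing constraint."""
    margin = 5.0 * cfg.center_jitter_sd + cfg.peak_width_max
    lo, hi = margin, cfg.chrom_length - margin
    if hi <= lo or n * cfg.min_locus_spacing > (hi - lo):
        raise ConfigurationError(
            f"cannot place {n} loci with spacing {cfg.min_locus_spacing} on a "
            f"{cfg.chrom_length} bp chromosome"
        )
    placed: list[float] = []
    attempts = 0
    while len(placed) < n:
        cand = float(rng.uniform(lo, hi))
        if all(abs(cand - p) >= cfg.min_locus_spacing for p in placed):
            placed.append(cand)
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise ConfigurationError("locus placement did not converge; reduce count or spacing")
    return np.array(placed)


def _cell_lines(cfg: SimulationConfig) -> list[str]:
    return [f"CL{i:02d}" for i in range(cfg.n_cell_lines)]


def simulate(cfg: SimulationConfig, out_dir: str | Path) -> tuple[SyntheticTruth, DatasetManifest]:
    """Generate peak BED files, a manifest, and a truth table under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    cell_lines = _cell_lines(cfg)
    universe = frozenset(cell_lines)

    positions = _place_loci(rng, cfg, cfg.n_constitutive_loci + cfg.n_specific_loci)
    loci: list[Locus] = []
    for i, p in enumerate(positions):
        if i < cfg.n_constitutive_loci:
            loci.append(Locus(p, "constitutive", universe))
        else:
            presence = universe
            for _ in range(100):
                draw = frozenset(
                    cl for cl in cell_lines if rng.random() < cfg.specific_presence_prob
                )
                if draw != universe:
                    presence = draw
                    break
            else:
                presence = frozenset(sorted(universe)[1:])
            loci.append(Locus(p, "specific", presence))
    loci.sort(key=lambda l: l.position)

    entries: list[ManifestEntry] = []
    for cl in cell_lines:
        for r in range(1, cfg.replicates_per_cell_line + 1):
            ds = f"{cl}_rep{r}"
            fp = out_dir / f"{ds}.bed"
            lines: list[str] = []
            for locus in loci:
                if cl not in locus.presence:
                    continue
                if rng.random() < cfg.dropout_prob:
                    continue
                jitter = float(np.clip(rng.normal(0.0, cfg.center_jitter_sd),
                                       -5 * cfg.center_jitter_sd, 5 * cfg.center_jitter_sd)) \
                    if cfg.center_jitter_sd > 0 else 0.0
                lines.append(_peak_line(cfg, rng, locus.position + jitter))
            for _ in range(cfg.noise_peaks_per_dataset):
                noise_pos = float(rng.uniform(cfg.peak_width_max, cfg.chrom_length - cfg.peak_width_max))
                lines.append(_peak_line(cfg, rng, noise_pos))
            with open(fp, "w") as fh:
                fh.write("".join(lines))
            entries.append(ManifestEntry(ds, fp, cl, f"rep{r}"))

    manifest = DatasetManifest(entries=entries)
    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("dataset_id\tfile_path\tcell_line\treplicate\n")
        for e in entries:
            fh.write(f"{e.dataset_id}\t{e.file_path.name}\t{e.cell_line}\t{e.replicate}\n")
    manifest.source = manifest_path

    truth = SyntheticTruth(loci=loci, chrom=cfg.chrom)
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for l in loci:
            fh.write(f"{float(l.position)!r}\t{l.kind}\t{','.join(sorted(l.presence))}\n")
    return truth, manifest


def _peak_line(cfg: SimulationConfig, rng: np.random.Generator, center: float) -> str:
    width = int(rng.integers(cfg.peak_width_min, cfg.peak_width_max + 1))
    start = max(0, int(round(center)) - width // 2)
    return f"{cfg.chrom}\t{start}\t{start + width}\n"


def read_truth(path: str | Path, chrom: str = "chr1") -> SyntheticTruth:
    loci: list[Locus] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in TRUTH_COLUMNS}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            presence = frozenset(f[idx["presence"]].split(",")) if f[idx["presence"]] else frozenset()
            loci.append(Locus(float(f[idx["position"]]), f[idx["kind"]], presence))
    return SyntheticTruth(loci=loci, chrom=chrom)


def score_recovery(
    truth: SyntheticTruth,
    calls: list[BindingSiteCall],
    match_radius: float = 50.0,
) -> RecoveryReport:
    """Greedy one-to-one matching of constitutive calls to constitutive loci.

    Candidate (call, locus) pairs within match_radius are matched nearest
    first; recall is over planted constitutive loci, precision over
    constitutive calls.
    """
    truth_pos = truth.constitutive_positions()
    summits = np.array([c.summit for c in calls if c.constitutive])
    pairs = [
        (abs(s - t), i, j)
        for i, s in enumerate(summits)
        for j, t in enumerate(truth_pos)
        if abs(s - t) <= match_radius
    ]
    pairs.sort()
    used_call: set[int] = set()
    used_truth: set[int] = set()
    dists: list[float] = []
    for d, i, j in pairs:
        if i in used_call or j in used_truth:
            continue
        used_call.add(i)
        used_truth.add(j)
        dists.append(d)
    n_matched = len(dists)
    return RecoveryReport(
        recall=n_matched / truth_pos.size if truth_pos.size else math.nan,
        precision=n_matched / summits.size if summits.size else math.nan,
        n_matched=n_matched,
        n_truth=int(truth_pos.size),
        n_calls=int(summits.size),
        distances=np.sort(np.array(dists)),
    )


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    """A copy of cfg with a different seed (convenience for seed ladders)."""
    return replace(cfg, seed=seed)
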