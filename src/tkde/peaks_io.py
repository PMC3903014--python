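"""Peak-file and manifest I/O.

ChIP-seq peak calls arrive as BED3+/narrowPeak intervals, one file per dataset.
The only datum the downstream method uses is the peak *center*, defined as half
the sum of the start and end coordinates; centers are kept at half-integer
resolution because the density estimation that consumes them is continuous.
Coordinates are BED-standard 0-based half-open throughout and strand is ignored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, ValidationError

logger = logging.getLogger("tkde")

MANIFEST_COLUMNS = ("dataset_id", "file_path", "cell_line", "replicate")


@dataclass(frozen=True)
class PeakRecord:
    """One called peak: a half-open genomic interval tagged by its dataset."""

    chrom: str
    start: int
    end: int
    dataset_id: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start coordinate: {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )


@dataclass(frozen=True)
class PeakCenter:
    """The 1-D datum the method clusters: half the sum of start and end."""

    chrom: str
    position: float
    dataset_id: str


@dataclass(frozen=True)
class ManifestEntry:
    dataset_id: str
    file_path: Path
    cell_line: str
    replicate: str


@dataclass
class DatasetManifest:
    """Maps each dataset to its cell line and replicate label.

    The manifest defines the cell-line universe: the denominator of every
    "fraction of cell lines" computed downstream is the number of distinct
    cell lines listed here, whether or not each contributed peaks to a given
    chromosome.
    """

    entries: list[ManifestEntry]
    source: Path | None = None

    cell_lines: list[str] = field(init=False)
    datasets_per_cell_line: dict[str, int] = field(init=False)
    cell_line_of: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        ids = [e.dataset_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate dataset_id in manifest: {dupes}")
        if not self.entries:
            raise ValidationError("manifest contains no datasets")
        self.cell_line_of = {e.dataset_id: e.cell_line for e in self.entries}
        self.cell_lines = sorted({e.cell_line for e in self.entries})
        self.datasets_per_cell_line = {
            cl: sum(1 for e in self.entries if e.cell_line == cl)
            for cl in self.cell_lines
        }

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_lines)


@dataclass(frozen=True)
class BindingSiteCall:
    """One declared binding site: a density mode with its modal-region extent.

    ``constitutive`` is True when the supported cell-line fraction strictly
    exceeds the configured cutoff ("more than 90%" by default).
    """

    chrom: str
    summit: float
    region_start: float
    region_end: float
    n_supporting_cell_lines: int
    cell_line_fraction: float
    n_peak_centers: int
    constitutive: bool

    def __post_init__(self) -> None:
        if not (self.region_start <= self.summit <= self.region_end):
            raise ValidationError(
                f"summit {self.summit} outside region "
                f"[{self.region_start}, {self.region_end}]"
            )
        if not (0.0 <= self.cell_line_fraction <= 1.0):
            raise ValidationError(f"fraction out of range: {self.cell_line_fraction}")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Parse a tab-delimited manifest with header columns
    dataset_id, file_path, cell_line, replicate.

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"empty manifest: {path}")
    header = lines[0].split("\t")
    try:
        idx = {col: header.index(col) for col in MANIFEST_COLUMNS}
    except ValueError as exc:
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        raise FormatError(f"manifest {path} missing columns {missing}") from exc
    if len(lines) == 1:
        raise ValidationError(f"manifest {path} has a header but no datasets")
    entries = []
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) < len(header):
            raise FormatError(f"manifest row has {len(fields)} fields, expected {len(header)}: {ln!r}")
        fp = Path(fields[idx["file_path"]])
        if not fp.is_absolute():
            fp = path.parent / fp
        entries.append(
            ManifestEntry(
                dataset_id=fields[idx["dataset_id"]],
                file_path=fp,
                cell_line=fields[idx["cell_line"]],
                replicate=fields[idx["replicate"]],
            )
        )
    return DatasetManifest(entries=entries, source=path)


_SKIP_PREFIXES = ("#", "track", "browser")


def read_peaks(path: str | Path, dataset_id: str, strict: bool = False) -> list[PeakRecord]:
    """Read a BED3+/narrowPeak file into PeakRecords.

    Only the first three columns are used; narrowPeak's extra columns are
    ignored. Header/track/comment lines are skipped. A record with
    ``end <= start`` is skipped with a warning (lenient, the default) or
    raises (``strict=True``). Non-numeric coordinates always raise.
    """
    path = Path(path)
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates {fields[1]!r}, {fields[2]!r}"
                ) from exc
            if end <= start or start < 0:
                msg = f"{path}:{lineno}: invalid interval [{start}, {end})"
                if strict:
                    raise ValidationError(msg)
                logger.warning("%s — line skipped", msg)
                continue
            records.append(PeakRecord(fields[0], start, end, dataset_id))
    return records


def compute_center(record: PeakRecord) -> PeakCenter:
    """Peak center = (start + end) / 2, kept at half-integer resolution."""
    return PeakCenter(record.chrom, (record.start + record.end) / 2.0, record.dataset_id)


def load_centers(manifest: DatasetManifest, strict: bool = False) -> list[PeakCenter]:
    """Read every dataset in the manifest and return all peak centers."""
    centers: list[PeakCenter] = []
    for entry in manifest.entries:
        records = read_peaks(entry.file_path, entry.dataset_id, strict=strict)
        centers.extend(compute_center(r) for r in records)
        logger.info("dataset %s: %d peaks", entry.dataset_id, len(records))
    return centers


def write_sites(
    calls: Sequence[BindingSiteCall],
    path: str | Path,
    provenance: Iterable[str] = (),
    summary_path: str | Path | None = None,
) -> None:
    """Write site calls as BED6+4 plus a per-chromosome summary table.

    Columns: chrom, region_start, region_end (half-open; zero-width regions
    become [floor(summit), floor(summit)+1)), name site_<k>,
    score = round(1000*cell_line_fraction), strand ".", then summit,
    n_supporting_cell_lines, n_peak_centers, constitutive (0/1).
    """
    path = Path(path)
    if summary_path is None:
        summary_path = Path(str(path) + ".summary.tsv")
    with open(path, "w") as out:
        for line in provenance:
            out.write(f"# {line}\n")
        for k, c in enumerate(calls, start=1):
            lo = math.floor(c.region_start)
            hi = math.floor(c.region_end)
            if hi <= lo:  # zero-width modal region (single peak center)
                lo = math.floor(c.summit)
                hi = lo + 1
            out.write(
                "\t".join(
                    [
                        c.chrom,
                        str(lo),
                        str(hi),
                        f"site_{k}",
                        str(round(1000 * c.cell_line_fraction)),
                        ".",
                        repr(c.summit),
                        str(c.n_supporting_cell_lines),
                        str(c.n_peak_centers),
                        "1" if c.constitutive else "0",
                    ]
                )
                + "\n"
            )
    per_chrom: dict[str, list[int]] = {}
    for c in calls:
        tot = per_chrom.setdefault(c.chrom, [0, 0])
        tot[0] += 1
        tot[1] += int(c.constitutive)
    with open(summary_path, "w") as out:
        out.write("chrom\tn_sites\tn_constitutive\n")
        for chrom in sorted(per_chrom):
            out.write(f"{chrom}\t{per_chrom[chrom][0]}\t{per_chrom[chrom][1]}\n")


def read_sites(path: str | Path) -> list[BindingSiteCall]:
    """Re-parse a BED6+4 file produced by :func:`write_sites`."""
    calls: list[BindingSiteCall] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            f = line.rstrip("\n").split("\t")
            summit = float(f[6])
            lo, hi = float(f[1]), float(f[2])
            calls.append(
                BindingSiteCall(
                    chrom=f[0],
                    summit=summit,
                    region_start=min(lo, summit),
                    region_end=max(hi, summit),
                    n_supporting_cell_lines=int(f[7]),
                    cell_line_fraction=int(f[4]) / 1000.0,
                    n_peak_centers=int(f[8]),
                    constitutive=f[9] == "1",
                )
            )
    return calls
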