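"""Gene panel, genome bin grid, and clinical record models with I/O.

Coordinate conventions: the packaged panel TSV stores 1-based inclusive
coordinates (as printed in the source table); the internal bin model is
0-based half-open (BED convention). Converters between the two are explicit
(:meth:`GenePanelEntry.start0` / :meth:`GenePanelEntry.end0`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PANEL_COLUMNS = [
    "chrom", "start", "end", "gene", "strand",
    "cnv_direction", "occurring_freq", "tcga_freq", "gene_class",
]

VALID_STAGES = {"I", "II", "III", "IV"}
VALID_HISTOLOGIES = {"HGSC", "LGSC", "mucinous", "endometrioid", "clear_cell"}
VALID_BRCA = {"pathogenic", "wild_type", "unknown"}


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel files."""


@dataclass(frozen=True)
class GenePanelEntry:
    """One panel gene with hg19 coordinates and expected CNV direction."""

    gene_symbol: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    direction: str  # "AMP" or "DEL"
    occurring_freq: float
    tcga_freq: float
    gene_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"{self.gene_symbol}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise PanelError(f"{self.gene_symbol}: bad strand {self.strand!r}")
        if self.direction not in {"AMP", "DEL"}:
            raise PanelError(f"{self.gene_symbol}: bad direction {self.direction!r}")
        for name in ("occurring_freq", "tcga_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PanelError(f"{self.gene_symbol}: {name}={v} outside [0, 1]")
        if self.gene_class not in {"oncogene", "tumor_suppressor"}:
            raise PanelError(f"{self.gene_symbol}: bad gene_class {self.gene_class!r}")

    @property
    def start0(self) -> int:
        """0-based half-open start (BED convention)."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end (equals the 1-based inclusive end)."""
        return self.end

    @property
    def length(self) -> int:
        return self.end0 - self.start0


def packaged_panel_path() -> Path:
    """Path of the panel TSV shipped with the package (33 ovarian-cancer genes)."""
    return Path(str(resources.files("giscan").joinpath("data/ovarian_panel_hg19.tsv")))


def load_gene_panel(path: str | Path | None = None) -> list[GenePanelEntry]:
    """Load a gene panel TSV; with no argument, loads the packaged 33-gene panel.

    Raises :class:`PanelError` on malformed coordinates (naming the line) or
    duplicate gene symbols. An empty file returns an empty list with a warning.
    """
    if path is None:
        path = packaged_panel_path()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("panel file %s contains no entries", path)
        return []

    entries: list[GenePanelEntry] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            start = int(str(row.start).replace(",", ""))
            end = int(str(row.end).replace(",", ""))
        except ValueError as exc:
            raise PanelError(f"{path} line {i}: malformed coordinates: {exc}") from exc
        try:
            entries.append(GenePanelEntry(
                gene_symbol=row.gene,
                chrom=row.chrom,
                start=start,
                end=end,
                strand=row.strand,
                direction=row.cnv_direction,
                occurring_freq=float(row.occurring_freq),
                tcga_freq=float(row.tcga_freq),
                gene_class=row.gene_class,
            ))
        except PanelError as exc:
            raise PanelError(f"{path} line {i}: {exc}") from exc

    symbols = [e.gene_symbol for e in entries]
    dupes = {s for s in symbols if symbols.count(s) > 1}
    if dupes:
        raise PanelError(f"{path}: duplicate gene symbols {sorted(dupes)}")
    return entries


def write_panel(entries: Sequence[GenePanelEntry], path: str | Path) -> None:
    """Write entries back to TSV in the canonical column order (round-trips load)."""
    df = pd.DataFrame({
        "chrom": [e.chrom for e in entries],
        "start": [e.start for e in entries],
        "end": [e.end for e in entries],
        "gene": [e.gene_symbol for e in entries],
        "strand": [e.strand for e in entries],
        "cnv_direction": [e.direction for e in entries],
        "occurring_freq": [e.occurring_freq for e in entries],
        "tcga_freq": [e.tcga_freq for e in entries],
        "gene_class": [e.gene_class for e in entries],
    })
    df.to_csv(path, sep="\t", index=False)


@dataclass
class BinGrid:
    """Genome tiling into fixed-size half-open bins with per-bin GC fraction.

    ``bins`` columns: chrom, start, end, gc (gc may be NaN when no source given).
    """

    bins: pd.DataFrame
    bin_size: int

    def __post_init__(self) -> None:
        b = self.bins
        required = {"chrom", "start", "end"}
        if not required.issubset(b.columns):
            raise ValueError(f"bin table needs columns {required}")
        if "gc" not in b.columns:
            self.bins = b = b.assign(gc=np.nan)
        lengths = b["end"] - b["start"]
        if (lengths <= 0).any():
            raise ValueError("bins must have positive length")
        for chrom, sub in b.groupby("chrom", sort=False):
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                raise ValueError(f"overlapping or unsorted bins on {chrom}")

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def feature_ids(self) -> list[str]:
        b = self.bins
        return [f"{c}:{s}-{e}" for c, s, e in zip(b["chrom"], b["start"], b["end"])]


def make_bin_grid(
    chrom_sizes: Mapping[str, int],
    bin_size: int,
    fasta: str | Path | None = None,
    gc_table: str | Path | pd.DataFrame | None = None,
) -> BinGrid:
    """Tile each chromosome into half-open ``[start, end)`` bins of ``bin_size``.

    GC fraction per bin is computed from ``fasta`` when given, read from
    ``gc_table`` (BED4: chrom, start, end, gc) otherwise, and left NaN when
    neither is provided. The terminal bin of each chromosome may be shorter.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has nonpositive size {size}")
        for start in range(0, size, bin_size):
            rows.append((chrom, start, min(start + bin_size, size)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    if fasta is not None:
        bins["gc"] = _gc_from_fasta(fasta, bins)
    elif gc_table is not None:
        bins["gc"] = _gc_from_table(gc_table, bins, chrom_sizes)
    else:
        bins["gc"] = np.nan
    return BinGrid(bins=bins, bin_size=bin_size)


def _gc_from_fasta(fasta: str | Path, bins: pd.DataFrame) -> np.ndarray:
    from pyfaidx import Fasta  # optional dependency, only needed for FASTA input

    fa = Fasta(str(fasta))
    gc = np.empty(len(bins))
    for i, (chrom, start, end) in enumerate(
        zip(bins["chrom"], bins["start"], bins["end"])
    ):
        seq = str(fa[chrom][start:end]).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        gc[i] = (seq.count("G") + seq.count("C")) / acgt if acgt else np.nan
    return gc


def _gc_from_table(
    gc_table: str | Path | pd.DataFrame,
    bins: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
) -> np.ndarray:
    if isinstance(gc_table, (str, Path)):
        tab = pd.read_csv(
            gc_table, sep="\t", header=None, names=["chrom", "start", "end", "gc"],
            comment="#",
        )
    else:
        tab = gc_table.copy()
        tab.columns = ["chrom", "start", "end", "gc"][: len(tab.columns)]
    unknown = set(tab["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"GC table chromosomes absent from chrom_sizes: {sorted(unknown)}")
    keyed = {(c, s, e): g for c, s, e, g in
             zip(tab["chrom"], tab["start"], tab["end"], tab["gc"])}
    gc = np.array([
        keyed.get((c, s, e), np.nan)
        for c, s, e in zip(bins["chrom"], bins["start"], bins["end"])
    ])
    bad = gc[~np.isnan(gc)]
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("gc fractions must lie in [0, 1]")
    return gc


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV of chromosome name and length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"], df["size"].astype(int)))


# ---------------------------------------------------------------------------
# Clinical records


@dataclass
class ClinicalRecord:
    patient_id: str
    ca125: float
    figo_stage: str
    histology: str
    dfs_months: float
    dfs_event: int
    os_months: float
    os_event: int
    brca_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.ca125 is not None and not np.isnan(self.ca125) and self.ca125 <= 0:
            raise ValueError(f"{self.patient_id}: CA125 must be positive")
        if self.figo_stage not in VALID_STAGES | {"unknown"}:
            raise ValueError(f"{self.patient_id}: bad FIGO stage {self.figo_stage!r}")
        if self.histology not in VALID_HISTOLOGIES | {"unknown"}:
            raise ValueError(f"{self.patient_id}: bad histology {self.histology!r}")
        if self.brca_status not in VALID_BRCA:
            raise ValueError(f"{self.patient_id}: bad brca_status {self.brca_status!r}")
        for name in ("dfs_event", "os_event"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{self.patient_id}: {name} must be 0/1")
        if (
            not np.isnan(self.dfs_months)
            and not np.isnan(self.os_months)
            and self.dfs_months > self.os_months + 1e-9
        ):
            raise ValueError(f"{self.patient_id}: dfs_months exceeds os_months")


CLINICAL_COLUMNS = [
    "patient_id", "ca125", "figo_stage", "histology",
    "dfs_months", "dfs_event", "os_months", "os_event", "brca_status",
]


def load_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing clinical columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(ClinicalRecord(
            patient_id=str(row.patient_id),
            ca125=float(row.ca125),
            figo_stage=str(row.figo_stage),
            histology=str(row.histology),
            dfs_months=float(row.dfs_months),
            dfs_event=int(row.dfs_event),
            os_months=float(row.os_months),
            os_event=int(row.os_event),
            brca_status=str(row.brca_status),
        ))
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records])[CLINICAL_COLUMNS].to_csv(path, index=False)


@dataclass
class CohortSummary:
    n: int
    median_ca125: float
    stage_counts: dict[str, int] = field(default_factory=dict)
    histology_counts: dict[str, int] = field(default_factory=dict)
    recurrence_count: int = 0
    brca_count: int = 0

    def percent(self, numerator: int, decimals: int = 0,
                denominator: int | None = None) -> float:
        """Half-up percentage helper (29/40 -> 73 at 0 decimals)."""
        den = self.n if denominator is None else denominator
        return percent_half_up(numerator, den, decimals)

    @property
    def stage_iii_iv_percent(self) -> float:
        return self.percent(
            self.stage_counts.get("III", 0) + self.stage_counts.get("IV", 0)
        )

    @property
    def hgsc_percent(self) -> float:
        return self.percent(self.histology_counts.get("HGSC", 0), decimals=1)

    @property
    def brca_percent(self) -> float:
        return self.percent(self.brca_count)

    @property
    def recurrence_percent(self) -> float:
        return self.percent(self.recurrence_count)


def percent_half_up(numerator: float, denominator: float, decimals: int = 0) -> float:
    """Percentage rounded half-up (not banker's) to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    q = Decimal(1).scaleb(-decimals)
    value = Decimal(numerator) / Decimal(denominator) * 100
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def summarize_cohort(records: Iterable[ClinicalRecord]) -> CohortSummary:
    """Cohort composition summary; unknown fields are excluded from counts.

    Median CA125 is computed over observed (non-NaN) values.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    ca125 = [r.ca125 for r in records if not np.isnan(r.ca125)]
    stage_counts: dict[str, int] = {}
    hist_counts: dict[str, int] = {}
    for r in records:
        if r.figo_stage in VALID_STAGES:
            stage_counts[r.figo_stage] = stage_counts.get(r.figo_stage, 0) + 1
        if r.histology in VALID_HISTOLOGIES:
            hist_counts[r.histology] = hist_counts.get(r.histology, 0) + 1
    return CohortSummary(
        n=len(records),
        median_ca125=float(np.median(ca125)) if ca125 else float("nan"),
        stage_counts=stage_counts,
        histology_counts=hist_counts,
        recurrence_count=sum(r.dfs_event for r in records),
        brca_count=sum(r.brca_status == "pathogenic" for r in records),
    )
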