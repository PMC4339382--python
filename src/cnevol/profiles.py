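"""Allele-specific segmented copy number profiles: data model, I/O, QC.

Profiles are integer copy numbers of the two parental alleles over a
segmentation of the genome.  SNP arrays report the unordered (major,
minor) pair per segment; on read the major >= minor convention is
enforced, and haplotype assignment is deferred to phasing.

Coordinates are 1-based and inclusive at both ends, the common convention
for segmentation tables.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Segment",
    "AlleleProfile",
    "SampleRecord",
    "PatientDataset",
    "QCReport",
    "read_cohort",
    "write_cohort",
    "harmonize_segmentation",
    "apply_qc_filters",
    "natural_chrom_key",
]

TIMEPOINTS = ("biopsy", "surgery", "relapse")


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key giving 1..22, X, Y order; other labels sort lexically after."""
    c = str(chrom)
    c = c[3:] if c.lower().startswith("chr") else c
    if c.isdigit():
        return (0, int(c), "")
    if c in ("X", "Y"):
        return (1, 0 if c == "X" else 1, "")
    return (2, 0, c)


@dataclass(frozen=True, order=True)
class Segment:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"segment start > end: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AlleleProfile:
    """One sample's integer copy numbers of two alleles over shared segments."""

    sample_id: str
    segments: tuple[Segment, ...]
    cn_a: tuple[int, ...]
    cn_b: tuple[int, ...]

    def __post_init__(self):
        if not (len(self.segments) == len(self.cn_a) == len(self.cn_b)):
            raise ValueError(f"{self.sample_id}: segment/copy-number length mismatch")
        if any(a < 0 or b < 0 for a, b in zip(self.cn_a, self.cn_b)):
            raise ValueError(f"{self.sample_id}: negative copy number")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def total_cn(self) -> np.ndarray:
        return np.asarray(self.cn_a) + np.asarray(self.cn_b)


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    patient_id: str
    site: str = ""
    timepoint: str = "biopsy"
    cellularity: float | None = None

    def __post_init__(self):
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}: {self.timepoint!r}")
        if self.cellularity is not None and not (0.0 <= self.cellularity <= 1.0):
            raise ValueError(f"cellularity out of [0,1]: {self.cellularity}")


@dataclass(frozen=True)
class PatientDataset:
    """All profiles and sample metadata for one patient, on one segment grid."""

    patient_id: str
    profiles: list[AlleleProfile]
    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self):
        if not self.profiles:
            raise ValueError(f"{self.patient_id}: dataset must hold >=1 profile")
        grid = self.profiles[0].segments
        for p in self.profiles[1:]:
            if p.segments != grid:
                raise ValueError(
                    f"{self.patient_id}: inconsistent segment grids; run "
                    "harmonize_segmentation first"
                )

    @property
    def n_segments(self) -> int:
        return self.profiles[0].n_segments

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    def record_for(self, sample_id: str) -> SampleRecord | None:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        return None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ["patient_id", "sample_id", "chrom", "start", "end", "cn_major", "cn_minor"]
METADATA_COLUMNS = ["sample_id", "patient_id", "site", "timepoint", "cellularity"]


def read_cohort(
    segment_table: str | Path,
    metadata_table: str | Path | None = None,
    harmonize: bool = True,
) -> list[PatientDataset]:
    """Read a cohort from the segment/metadata TSV dialect.

    Rows are grouped by patient and sample; copy numbers are validated as
    non-negative integers and swapped (with a warning) wherever minor >
    major.  Per-sample segmentations within a patient are harmonized onto
    the union-of-breakpoints grid unless ``harmonize=False``, in which case
    inconsistent grids raise.
    """
    seg = pd.read_csv(segment_table, sep="\t", dtype=str)
    missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
    if missing:
        raise ValueError(f"{segment_table}: missing columns {missing}")
    for col in ("start", "end", "cn_major", "cn_minor"):
        try:
            seg[col] = seg[col].astype(np.int64)
        except (TypeError, ValueError):
            bad = seg.index[pd.to_numeric(seg[col], errors="coerce").isna()]
            line = int(bad[0]) + 2  # +1 header, +1 1-based
            raise ValueError(f"{segment_table}: malformed integer in column {col!r} at line {line}")
    if (seg[["cn_major", "cn_minor"]] < 0).any().any():
        bad = seg.index[(seg.cn_major < 0) | (seg.cn_minor < 0)][0]
        raise ValueError(f"{segment_table}: negative copy number at line {int(bad) + 2}")
    swap = seg.cn_minor > seg.cn_major
    if swap.any():
        warnings.warn(
            f"{int(swap.sum())} segment rows had minor > major; values swapped "
            "to restore the major/minor convention"
        )
        seg.loc[swap, ["cn_major", "cn_minor"]] = seg.loc[swap, ["cn_minor", "cn_major"]].values

    records: dict[str, list[SampleRecord]] = {}
    if metadata_table is not None:
        meta = pd.read_csv(metadata_table, sep="\t", dtype=str)
        miss = [c for c in METADATA_COLUMNS if c not in meta.columns]
        if miss:
            raise ValueError(f"{metadata_table}: missing columns {miss}")
        for _, row in meta.iterrows():
            cell = row["cellularity"]
            cell = None if (pd.isna(cell) or cell == "") else float(cell)
            rec = SampleRecord(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                site=row["site"] if not pd.isna(row["site"]) else "",
                timepoint=row["timepoint"],
                cellularity=cell,
            )
            records.setdefault(rec.patient_id, []).append(rec)

    datasets: list[PatientDataset] = []
    for pid in sorted(seg.patient_id.unique()):
        sub = seg[seg.patient_id == pid]
        profiles = []
        for sid in sorted(sub.sample_id.unique()):
            rows = sub[sub.sample_id == sid].copy()
            rows["_key"] = rows.chrom.map(natural_chrom_key)
            rows = rows.sort_values(["_key", "start"], kind="stable")
            segments = tuple(
                Segment(c, int(s), int(e)) for c, s, e in zip(rows.chrom, rows.start, rows.end)
            )
            _check_non_overlapping(sid, segments)
            profiles.append(
                AlleleProfile(
                    sample_id=sid,
                    segments=segments,
                    cn_a=tuple(int(x) for x in rows.cn_major),
                    cn_b=tuple(int(x) for x in rows.cn_minor),
                )
            )
        if harmonize:
            profiles = harmonize_segmentation(profiles)
        datasets.append(PatientDataset(pid, profiles, records.get(pid, [])))
    return datasets


def _check_non_overlapping(sample_id: str, segments: Sequence[Segment]) -> None:
    by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(f"{sample_id}: overlapping segments on {chrom}: {a} / {b}")


def write_cohort(
    cohort: Iterable[PatientDataset],
    segment_table: str | Path,
    metadata_table: str | Path | None = None,
) -> None:
    """Write a cohort back to the TSV dialect read by :func:`read_cohort`."""
    rows = []
    meta_rows = []
    for ds in cohort:
        for p in ds.profiles:
            for seg, a, b in zip(p.segments, p.cn_a, p.cn_b):
                rows.append((ds.patient_id, p.sample_id, seg.chrom, seg.start, seg.end, a, b))
        for r in ds.records:
            meta_rows.append(
                (r.sample_id, r.patient_id, r.site, r.timepoint,
                 "" if r.cellularity is None else r.cellularity)
            )
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(segment_table, sep="\t", index=False)
    if metadata_table is not None:
        pd.DataFrame(meta_rows, columns=METADATA_COLUMNS).to_csv(
            metadata_table, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Segmentation harmonization
# ---------------------------------------------------------------------------


def harmonize_segmentation(profiles: list[AlleleProfile]) -> list[AlleleProfile]:
    """Project all profiles onto the union-of-breakpoints segment grid.

    Every sample's copy number is carried unchanged onto each sub-segment
    it spans; a base pair covered in one sample but not in another raises
    (no imputation).  Copy numbers at any base pair are never altered.
    """
    if not profiles:
        return []
    chroms = sorted({s.chrom for p in profiles for s in p.segments}, key=natural_chrom_key)
    # union breakpoints per chromosome
    grid: list[Segment] = []
    for chrom in chroms:
        cuts: set[int] = set()
        for p in profiles:
            for s in p.segments:
                if s.chrom == chrom:
                    cuts.add(s.start)
                    cuts.add(s.end + 1)
        pts = sorted(cuts)
        for lo, hi in zip(pts, pts[1:]):
            grid.append(Segment(chrom, lo, hi - 1))
    # drop grid cells not covered by the first profile's footprint; coverage
    # must agree across samples, checked below
    out = []
    for p in profiles:
        cov = {
            (s.chrom): [] for s in p.segments
        }
        for s, a, b in zip(p.segments, p.cn_a, p.cn_b):
            cov[s.chrom].append((s.start, s.end, a, b))
        cn_a, cn_b, kept = [], [], []
        for cell in grid:
            hit = None
            for start, end, a, b in cov.get(cell.chrom, []):
                if start <= cell.start and cell.end <= end:
                    hit = (a, b)
                    break
                if start <= cell.start <= end or start <= cell.end <= end:
                    raise ValueError(
                        f"{p.sample_id}: segment grid partially covers {cell}; no imputation"
                    )
            if hit is not None:
                kept.append(cell)
                cn_a.append(hit[0])
                cn_b.append(hit[1])
        out.append(AlleleProfile(p.sample_id, tuple(kept), tuple(cn_a), tuple(cn_b)))
    footprint = out[0].segments
    for p in out[1:]:
        if p.segments != footprint:
            missing = set(footprint) ^ set(p.segments)
            raise ValueError(
                f"{p.sample_id}: genome coverage differs between samples "
                f"({len(missing)} grid cells); no imputation is performed"
            )
    return out


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    excluded_samples: list[tuple[str, str, str]] = field(default_factory=list)  # (patient, sample, reason)
    excluded_patients: list[tuple[str, str]] = field(default_factory=list)  # (patient, reason)
    n_samples_retained: int = 0
    n_patients_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [(p, s, r) for p, s, r in self.excluded_samples]
        rows += [(p, "", r) for p, r in self.excluded_patients]
        return pd.DataFrame(rows, columns=["patient_id", "sample_id", "reason"])


def apply_qc_filters(
    cohort: list[PatientDataset],
    min_cellularity: float = 0.5,
    min_samples: int = 3,
    strict_cellularity: bool = False,
) -> tuple[list[PatientDataset], QCReport]:
    """Exclude low-cellularity samples, then patients with too few samples.

    Samples with cellularity below ``min_cellularity`` are removed; samples
    with unknown cellularity pass unless ``strict_cellularity`` is set.
    Patients left with fewer than ``min_samples`` samples are dropped.  The
    report lists every exclusion with its reason; an empty cohort is legal.
    The filter is idempotent.
    """
    report = QCReport()
    kept: list[PatientDataset] = []
    for ds in cohort:
        profiles = []
        for p in ds.profiles:
            rec = ds.record_for(p.sample_id)
            cell = rec.cellularity if rec is not None else None
            if cell is None:
                ok = not strict_cellularity
                reason = "cellularity unknown (strict mode)"
            else:
                ok = cell >= min_cellularity
                reason = f"cellularity {cell:.2f} < {min_cellularity:.2f}"
            if ok:
                profiles.append(p)
            else:
                report.excluded_samples.append((ds.patient_id, p.sample_id, reason))
        if len(profiles) < min_samples:
            report.excluded_patients.append(
                (ds.patient_id, f"{len(profiles)} samples after QC < {min_samples}")
            )
            continue
        keep_ids = {p.sample_id for p in profiles}
        kept.append(
            replace(ds, profiles=profiles, records=[r for r in ds.records if r.sample_id in keep_ids])
        )
    report.n_samples_retained = sum(len(ds.profiles) for ds in kept)
    report.n_patients_retained = len(kept)
    return kept, report
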