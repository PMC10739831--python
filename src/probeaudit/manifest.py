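"""Probe manifests and 51-bp probe-region coordinate arithmetic.

An Infinium methylation assay probe hybridizes to a 50-bp stretch of
bisulfite-converted DNA next to its target cytosine and is read out by a
single-base extension (SBE).  The genomic footprint that can harbour
interfering variants is therefore 51 positions: the 50-bp probe body plus
the extension position.  This module turns manifest rows (CpG id,
chromosome, 1-based plus-strand coordinate of the CpG cytosine, targeted
strand, Infinium chemistry type) into explicit genomic intervals with a
signed *probe-index* coordinate system in which

* index 0 is always the targeted cytosine (for reverse-strand probes this
  is the C of the minus strand, i.e. plus-strand position ``pos + 1``),
* index 1 is the other base of the CpG dinucleotide,
* increasing index runs into the probe body, away from the extension end.

Type II probes interrogate the cytosine itself at the extension position,
so their window covers indices 0..50.  Type I probes extend one base
before the cytosine; by default their window covers indices -1..49 with
the SBE at index -1.  The Type I window placement is a documented
convention and can be switched to mirror the Type II window
(``type1_window="same_as_type2"``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError, ValidationError

__all__ = [
    "Strand",
    "InfiniumType",
    "ProbeRecord",
    "ProbeRegion",
    "read_manifest",
    "compute_probe_region",
    "compute_probe_regions",
    "probe_index_of",
    "write_regions_bed",
    "read_regions_bed",
    "DEFAULT_MANIFEST_COLUMNS",
]

REGION_SPAN = 51  # probe body (50 bp) plus the single-base-extension position


class Strand(str, enum.Enum):
    """Targeted strand: F (forward/plus) or R (reverse/minus)."""

    F = "F"
    R = "R"


class InfiniumType(str, enum.Enum):
    """Infinium bead chemistry: Type I (two beads) or Type II (one bead)."""

    I = "I"
    II = "II"


_STRAND_TOKENS = {"F": Strand.F, "R": Strand.R, "f": Strand.F, "r": Strand.R,
                  "+": Strand.F, "-": Strand.R}
_TYPE_TOKENS = {"I": InfiniumType.I, "II": InfiniumType.II,
                "1": InfiniumType.I, "2": InfiniumType.II,
                "i": InfiniumType.I, "ii": InfiniumType.II}

#: Default manifest column names (Illumina-manifest style); every entry can
#: be overridden via the ``columns`` argument of :func:`read_manifest`.
DEFAULT_MANIFEST_COLUMNS = {
    "cpg_id": ("IlmnID", "Name"),
    "chrom": ("CHR",),
    "pos": ("MAPINFO",),
    "strand": ("Strand",),
    "infinium_type": ("Infinium_Design_Type",),
}


@dataclass(frozen=True)
class ProbeRecord:
    """One CpG assay probe as declared in a manifest.

    ``pos`` is the 1-based plus-strand coordinate of the CpG's plus-strand
    cytosine for both forward- and reverse-strand targeted probes
    (MAPINFO-style convention).
    """

    cpg_id: str
    chrom: str
    pos: int
    strand: Strand
    infinium_type: InfiniumType

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(
                f"probe {self.cpg_id}: coordinate must be >= 1, got {self.pos}"
            )
        if not isinstance(self.strand, Strand):
            raise ValidationError(f"probe {self.cpg_id}: invalid strand {self.strand!r}")
        if not isinstance(self.infinium_type, InfiniumType):
            raise ValidationError(
                f"probe {self.cpg_id}: invalid Infinium type {self.infinium_type!r}"
            )


@dataclass(frozen=True)
class ProbeRegion:
    """A probe's 51-position genomic window.

    ``start``/``end`` are a 0-based half-open plus-strand interval;
    ``target_c_pos`` is the 1-based plus-strand coordinate of the targeted
    cytosine (``pos`` for F probes, ``pos + 1`` for R probes).  The signed
    probe-index system spans ``[index_min, index_max]`` with index 0 at the
    targeted cytosine; ``sbe_index`` is the single-base-extension position
    (always ``index_min`` under both supported window conventions).
    """

    cpg_id: str
    chrom: str
    start: int
    end: int
    strand: Strand
    infinium_type: InfiniumType
    target_c_pos: int
    index_min: int
    index_max: int

    def __post_init__(self) -> None:
        if self.end - self.start != REGION_SPAN:
            raise ValidationError(
                f"region {self.cpg_id}: span {self.end - self.start} != {REGION_SPAN}"
            )
        if self.index_max - self.index_min != REGION_SPAN - 1:
            raise ValidationError(f"region {self.cpg_id}: bad index window")
        if not (self.start + 1 <= self.target_c_pos <= self.end):
            raise ValidationError(
                f"region {self.cpg_id}: target cytosine outside region"
            )

    @property
    def sbe_index(self) -> int:
        """Probe index of the single-base-extension position."""
        return self.index_min

    def contains(self, pos: int) -> bool:
        """True if 1-based plus-strand position ``pos`` lies in the region."""
        return self.start + 1 <= pos <= self.end


def _parse_strand(token: str) -> Strand:
    try:
        return _STRAND_TOKENS[token.strip()]
    except KeyError:
        raise DataError(f"unknown strand token {token!r} (expected F or R)") from None


def _parse_type(token: str) -> InfiniumType:
    try:
        return _TYPE_TOKENS[token.strip()]
    except KeyError:
        raise DataError(
            f"unknown Infinium type token {token!r} (expected I or II)"
        ) from None


def _normalize_chrom(chrom: str, strip_chr: bool) -> str:
    chrom = chrom.strip()
    if strip_chr and chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def read_manifest(
    path: str | Path,
    columns: dict[str, Sequence[str] | str] | None = None,
    strip_chr: bool = False,
) -> list[ProbeRecord]:
    """Read a probe manifest CSV into validated :class:`ProbeRecord` s.

    ``columns`` maps the logical fields (``cpg_id``, ``chrom``, ``pos``,
    ``strand``, ``infinium_type``) to the header names used in the file;
    defaults are the Illumina-style names in
    :data:`DEFAULT_MANIFEST_COLUMNS`.  Rows with missing or invalid values
    are rejected with diagnostics naming the offending row (1-based data
    row number) and field; duplicated CpG ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"manifest file not found: {path}")
    colmap = dict(DEFAULT_MANIFEST_COLUMNS)
    if columns:
        for key, val in columns.items():
            if key not in colmap:
                raise ValidationError(f"unknown manifest field {key!r}")
            colmap[key] = (val,) if isinstance(val, str) else tuple(val)

    df = pd.read_csv(path, dtype=str)
    resolved: dict[str, str] = {}
    for field, candidates in colmap.items():
        found = [c for c in candidates if c in df.columns]
        if not found:
            raise DataError(
                f"manifest {path} lacks a column for {field!r} "
                f"(looked for {', '.join(candidates)})"
            )
        resolved[field] = found[0]

    records: list[ProbeRecord] = []
    problems: list[str] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            cpg_id = str(rowd[resolved["cpg_id"]]).strip()
            if not cpg_id or cpg_id.lower() == "nan":
                raise DataError("missing probe id")
            raw_pos = rowd[resolved["pos"]]
            try:
                pos = int(float(raw_pos))
            except (TypeError, ValueError):
                raise DataError(f"invalid coordinate {raw_pos!r}") from None
            if pos < 1:
                raise DataError(f"non-positive coordinate {pos}")
            rec = ProbeRecord(
                cpg_id=cpg_id,
                chrom=_normalize_chrom(str(rowd[resolved["chrom"]]), strip_chr),
                pos=pos,
                strand=_parse_strand(str(rowd[resolved["strand"]])),
                infinium_type=_parse_type(str(rowd[resolved["infinium_type"]])),
            )
        except (DataError, ValidationError) as exc:
            problems.append(f"row {i}: {exc}")
            continue
        if rec.cpg_id in seen:
            problems.append(
                f"row {i}: duplicate probe id {rec.cpg_id!r} (first seen row {seen[rec.cpg_id]})"
            )
            continue
        seen[rec.cpg_id] = i
        records.append(rec)
    if problems:
        raise DataError(
            f"manifest {path}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return records


def compute_probe_region(
    probe: ProbeRecord, type1_window: str = "sbe_minus1"
) -> ProbeRegion:
    """Derive a probe's 51-position genomic window.

    Window conventions (1-based inclusive plus-strand spans):

    ========  =======  =====================  =============
    strand    type     span                   probe indices
    ========  =======  =====================  =============
    F         II       [pos, pos + 50]        [0, 50]
    F         I        [pos - 1, pos + 49]    [-1, 49]
    R         II       [pos - 49, pos + 1]    [0, 50]
    R         I        [pos - 48, pos + 2]    [-1, 49]
    ========  =======  =====================  =============

    With ``type1_window="same_as_type2"`` Type I probes use the Type II
    index window [0, 50] instead.
    """
    if type1_window not in ("sbe_minus1", "same_as_type2"):
        raise ValidationError(f"unknown type1_window {type1_window!r}")
    if probe.infinium_type is InfiniumType.I and type1_window == "sbe_minus1":
        index_min, index_max = -1, 49
    else:
        index_min, index_max = 0, 50

    if probe.strand is Strand.F:
        target_c_pos = probe.pos
        span_lo = target_c_pos + index_min
        span_hi = target_c_pos + index_max
    else:  # R: the targeted C is the minus-strand C at plus position pos + 1
        target_c_pos = probe.pos + 1
        span_lo = target_c_pos - index_max
        span_hi = target_c_pos - index_min
    if span_lo < 1:
        raise ValidationError(
            f"probe {probe.cpg_id}: region would start at coordinate {span_lo} < 1"
        )
    return ProbeRegion(
        cpg_id=probe.cpg_id,
        chrom=probe.chrom,
        start=span_lo - 1,
        end=span_hi,
        strand=probe.strand,
        infinium_type=probe.infinium_type,
        target_c_pos=target_c_pos,
        index_min=index_min,
        index_max=index_max,
    )


def compute_probe_regions(
    probes: Iterable[ProbeRecord], type1_window: str = "sbe_minus1"
) -> list[ProbeRegion]:
    """Vector convenience wrapper around :func:`compute_probe_region`."""
    return [compute_probe_region(p, type1_window) for p in probes]


def probe_index_of(region: ProbeRegion, strand: Strand, x: int) -> int:
    """Signed probe index of 1-based plus-strand position ``x``.

    For forward probes the index increases with the coordinate
    (``x - target_c_pos``); for reverse probes it decreases
    (``target_c_pos - x``), so plus-strand position ``pos + 1`` -- the C of
    the minus-strand CpG -- always maps to index 0.
    """
    if not region.contains(x):
        raise ValidationError(
            f"position {x} outside region {region.cpg_id} "
            f"[{region.start + 1}, {region.end}]"
        )
    if strand is Strand.F:
        return x - region.target_c_pos
    return region.target_c_pos - x


def write_regions_bed(regions: Iterable[ProbeRegion], path: str | Path) -> None:
    """Write probe regions as BED6 (name = CpG id, strand + for F, - for R).

    Rows are ordered by (chrom, start, cpg_id) so output is deterministic
    regardless of input order.
    """
    rows = sorted(regions, key=lambda r: (r.chrom, r.start, r.cpg_id))
    with open(path, "w") as fh:
        for r in rows:
            strand = "+" if r.strand is Strand.F else "-"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.cpg_id}\t0\t{strand}\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 file written by :func:`write_regions_bed`."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"BED file not found: {path}")
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "cpg_id", "score", "strand"],
            dtype={"chrom": str, "start": int, "end": int, "cpg_id": str,
                   "score": int, "strand": str},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "cpg_id", "score", "strand"]
        )
    return df
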