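"""Intersect probe regions with SNPs and roll results up per CpG.

A *probe SNP* is a variant whose position falls inside a probe's 51-bp
window.  Each hit is annotated with its signed probe index, its distance
to the target cytosine (|index|), whether it disrupts the CpG dinucleotide
itself (index 0 or 1), and whether it sits at the single-base-extension
position.  Type I probes read the extension base in a fixed colour
channel, so SNPs at their SBE position only matter when the substitution
switches the channel; the SBE rule drops the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError, ValidationError
from .manifest import InfiniumType, ProbeRegion, probe_index_of
from .variants import SNPRecord, is_color_switching

__all__ = [
    "ProbeSNPHit",
    "CpGAudit",
    "find_probe_snps",
    "apply_sbe_rule",
    "audit_cpgs",
    "hits_to_frame",
    "write_hits_tsv",
    "read_hits_tsv",
]


@dataclass(frozen=True)
class ProbeSNPHit:
    """One SNP falling inside one probe region."""

    cpg_id: str
    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    probe_index: int
    distance: int
    disrupts_cpg: bool
    at_sbe_position: bool
    infinium_type: InfiniumType
    passes_sbe_rule: bool

    def __post_init__(self) -> None:
        if self.distance != abs(self.probe_index):
            raise DataError(f"hit {self.cpg_id}/{self.snp_id}: inconsistent distance")
        if self.disrupts_cpg != (self.probe_index in (0, 1)):
            raise DataError(f"hit {self.cpg_id}/{self.snp_id}: inconsistent CpG flag")


@dataclass(frozen=True)
class CpGAudit:
    """Per-CpG rollup of retained probe-SNP hits.

    ``representative_hit`` is the retained hit closest to the target
    cytosine (ties broken by higher Fst when available, then by SNP id);
    ``max_fst_hit`` is the retained hit with the highest Fst, populated
    only when an Fst table is supplied.
    """

    cpg_id: str
    has_probe_snp: bool
    n_hits: int
    hits: tuple[ProbeSNPHit, ...]
    representative_hit: ProbeSNPHit | None
    max_fst_hit: ProbeSNPHit | None


def _make_hit(region: ProbeRegion, snp: SNPRecord) -> ProbeSNPHit:
    idx = probe_index_of(region, region.strand, snp.pos)
    at_sbe = idx == region.sbe_index
    passes = True
    if region.infinium_type is InfiniumType.I and at_sbe:
        passes = is_color_switching(snp.ref, snp.alt)
    return ProbeSNPHit(
        cpg_id=region.cpg_id,
        snp_id=snp.snp_id,
        chrom=snp.chrom,
        pos=snp.pos,
        ref=snp.ref,
        alt=snp.alt,
        probe_index=idx,
        distance=abs(idx),
        disrupts_cpg=idx in (0, 1),
        at_sbe_position=at_sbe,
        infinium_type=region.infinium_type,
        passes_sbe_rule=passes,
    )


def find_probe_snps(
    regions: Sequence[ProbeRegion], snps: Iterable[SNPRecord]
) -> list[ProbeSNPHit]:
    """All (region, SNP) pairs whose SNP position lies inside the region.

    Output order is deterministic — (chrom, pos, cpg_id, snp_id) — and
    independent of the input order of either collection.
    """
    trees: dict[str, IntervalTree] = {}
    by_interval: dict[tuple[str, int, int], list[ProbeRegion]] = {}
    for r in regions:
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, None)
        by_interval.setdefault((r.chrom, r.start, r.end), []).append(r)
    hits: list[ProbeSNPHit] = []
    for snp in snps:
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for iv in tree[snp.pos - 1]:  # 0-based point query
            for region in by_interval[(snp.chrom, iv.begin, iv.end)]:
                hits.append(_make_hit(region, snp))
    hits.sort(key=lambda h: (h.chrom, h.pos, h.cpg_id, h.snp_id))
    return hits


def apply_sbe_rule(hits: Iterable[ProbeSNPHit]) -> list[ProbeSNPHit]:
    """Drop Type I SBE-position hits that do not switch colour channel.

    All other hits pass through unchanged; the operation is idempotent.
    """
    return [h for h in hits if h.passes_sbe_rule]


def _fst_of(hit: ProbeSNPHit, fst: Mapping[str, float] | None) -> float:
    if fst is None:
        return -math.inf
    theta = fst.get(hit.snp_id)
    if theta is None or (isinstance(theta, float) and math.isnan(theta)):
        return -math.inf
    return float(theta)


def audit_cpgs(
    regions: Sequence[ProbeRegion],
    retained_hits: Iterable[ProbeSNPHit],
    fst: Mapping[str, float] | None = None,
) -> list[CpGAudit]:
    """One audit per probe region, including zero-hit CpGs.

    The representative hit minimises distance to the target cytosine, with
    ties broken by higher Fst (when ``fst`` is given) and then by
    lexicographic SNP id, so the result is invariant to input order.
    """
    known = {r.cpg_id for r in regions}
    grouped: dict[str, list[ProbeSNPHit]] = {}
    for h in retained_hits:
        if h.cpg_id not in known:
            raise DataError(f"hit references unknown CpG id {h.cpg_id!r}")
        grouped.setdefault(h.cpg_id, []).append(h)

    audits: list[CpGAudit] = []
    for r in sorted(regions, key=lambda r: r.cpg_id):
        hs = sorted(grouped.get(r.cpg_id, []),
                    key=lambda h: (h.distance, -_fst_of(h, fst), h.snp_id))
        rep = hs[0] if hs else None
        max_fst = None
        if hs and fst is not None:
            max_fst = max(hs, key=lambda h: (_fst_of(h, fst), ), default=None)
            # deterministic tie-break on snp_id
            best = _fst_of(max_fst, fst)
            cands = [h for h in hs if _fst_of(h, fst) == best]
            max_fst = min(cands, key=lambda h: h.snp_id)
        audits.append(
            CpGAudit(
                cpg_id=r.cpg_id,
                has_probe_snp=bool(hs),
                n_hits=len(hs),
                hits=tuple(hs),
                representative_hit=rep,
                max_fst_hit=max_fst,
            )
        )
    return audits


# ---------------------------------------------------------------------------
# tabular round-trip

_HIT_COLUMNS = [
    "cpg_id", "snp_id", "chrom", "pos", "ref", "alt", "probe_index",
    "distance", "disrupts_cpg", "at_sbe_position", "infinium_type",
    "passes_sbe_rule",
]


def hits_to_frame(hits: Sequence[ProbeSNPHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cpg_id": h.cpg_id, "snp_id": h.snp_id, "chrom": h.chrom,
                "pos": h.pos, "ref": h.ref, "alt": h.alt,
                "probe_index": h.probe_index, "distance": h.distance,
                "disrupts_cpg": h.disrupts_cpg,
                "at_sbe_position": h.at_sbe_position,
                "infinium_type": h.infinium_type.value,
                "passes_sbe_rule": h.passes_sbe_rule,
            }
            for h in hits
        ],
        columns=_HIT_COLUMNS,
    )


def write_hits_tsv(hits: Sequence[ProbeSNPHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | Path) -> list[ProbeSNPHit]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"hits table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        ProbeSNPHit(
            cpg_id=str(r.cpg_id), snp_id=str(r.snp_id), chrom=str(r.chrom),
            pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            probe_index=int(r.probe_index), distance=int(r.distance),
            disrupts_cpg=bool(r.disrupts_cpg),
            at_sbe_position=bool(r.at_sbe_position),
            infinium_type=InfiniumType(r.infinium_type),
            passes_sbe_rule=bool(r.passes_sbe_rule),
        )
        for r in df.itertuples(index=False)
    ]
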