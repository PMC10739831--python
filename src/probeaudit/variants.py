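"""Biallelic SNPs with per-population genotype counts, plus frequency filters.

Reads a VCF alongside a 1000 Genomes-style sample panel (sample id ->
population label) and reduces each biallelic SNV to the per-population
sufficient statistics used downstream: number of diploid individuals with
called genotypes, alternate-allele count, and observed heterozygote count.
Indels, multiallelic and symbolic records are skipped (and counted), not
decomposed.  Phased and unphased genotypes are treated identically;
half-calls count as missing for that individual at that site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationPanel",
    "PopCounts",
    "SNPRecord",
    "read_panel",
    "read_biallelic_snps",
    "allele_frequency",
    "minor_allele_frequency",
    "frequency_filter",
    "is_color_switching",
    "snps_to_frame",
    "write_snps_tsv",
    "read_snps_tsv",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PopulationPanel:
    """Mapping from sample id to population label."""

    sample_to_pop: dict[str, str]
    populations: tuple[str, ...]

    def samples_in(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def __len__(self) -> int:
        return len(self.sample_to_pop)


@dataclass(frozen=True)
class PopCounts:
    """Genotype-derived counts for one population at one site."""

    n_called: int
    alt_count: int
    het_count: int

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= 2 * self.n_called):
            raise DataError(f"alt count {self.alt_count} out of range for n={self.n_called}")
        if not (0 <= self.het_count <= self.n_called):
            raise DataError(f"het count {self.het_count} out of range for n={self.n_called}")


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNV with per-population counts."""

    chrom: str
    pos: int  # 1-based
    snp_id: str
    ref: str
    alt: str
    counts: dict[str, PopCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise DataError(f"{self.snp_id}: ref equals alt ({self.ref})")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise DataError(f"{self.snp_id}: non-ACGT alleles {self.ref}/{self.alt}")


def read_panel(
    path: str | Path, sample_col: int = 0, pop_col: int = 1
) -> PopulationPanel:
    """Read a whitespace-delimited sample panel.

    The first two columns are sample id and population by default (extra
    columns, e.g. super-population or sex, are ignored).  A header line
    whose sample column reads "sample" is tolerated and skipped.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"panel file not found: {path}")
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and fields[sample_col].lower() in ("sample", "sample_id", "iid"):
                continue
            try:
                sample, pop = fields[sample_col], fields[pop_col]
            except IndexError:
                raise DataError(f"panel {path} line {lineno}: too few columns") from None
            if sample in mapping:
                raise DataError(f"panel {path} line {lineno}: duplicate sample {sample!r}")
            mapping[sample] = pop
    if not mapping:
        raise DataError(f"panel {path} is empty")
    pops = tuple(sorted(set(mapping.values())))
    return PopulationPanel(sample_to_pop=mapping, populations=pops)


def _is_biallelic_snv(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(ref) == 1
        and ref in _BASES
        and len(alts) == 1
        and len(alts[0]) == 1
        and alts[0] in _BASES
    )


def read_biallelic_snps(
    vcf_path: str | Path,
    panel: PopulationPanel,
    populations: Sequence[str],
) -> list[SNPRecord]:
    """Read biallelic SNVs from a VCF, counting genotypes per population.

    Only samples present in both the VCF and the panel contribute; VCF
    samples absent from the panel are excluded with a logged warning.
    Non-SNV records (indels, multiallelics, symbolic alleles) are skipped
    and tallied in the log.  Missing and half-called genotypes do not
    contribute to that site's counts.
    """
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise ValidationError(f"VCF not found: {vcf_path}")
    unknown = [p for p in populations if p not in panel.populations]
    if unknown:
        raise ValidationError(f"population(s) not in panel: {', '.join(unknown)}")

    vcf = VCF(str(vcf_path), gts012=False)
    samples = vcf.samples
    unpaneled = [s for s in samples if s not in panel.sample_to_pop]
    if unpaneled:
        logger.warning(
            "%d VCF sample(s) absent from panel and excluded (e.g. %s)",
            len(unpaneled), unpaneled[0],
        )
    pop_indices = {
        pop: [i for i, s in enumerate(samples) if panel.sample_to_pop.get(s) == pop]
        for pop in populations
    }
    empty = [p for p, idx in pop_indices.items() if not idx]
    if empty:
        raise DataError(f"no VCF samples from population(s): {', '.join(empty)}")

    records: list[SNPRecord] = []
    n_skipped = 0
    for v in vcf:
        if not _is_biallelic_snv(v.REF, v.ALT):
            n_skipped += 1
            continue
        gts = v.genotypes  # [allele1, allele2, phased] per sample
        counts: dict[str, PopCounts] = {}
        for pop, idx in pop_indices.items():
            n_called = alt = het = 0
            for i in idx:
                a1, a2 = gts[i][0], gts[i][1]
                if a1 < 0 or a2 < 0:  # missing or half-call
                    continue
                n_called += 1
                alt += (a1 != 0) + (a2 != 0)
                het += a1 != a2
            counts[pop] = PopCounts(n_called=n_called, alt_count=alt, het_count=het)
        snp_id = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}:{v.ALT[0]}"
        records.append(
            SNPRecord(chrom=v.CHROM, pos=v.POS, snp_id=snp_id,
                      ref=v.REF, alt=v.ALT[0], counts=counts)
        )
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV record(s)", n_skipped)
    return records


def allele_frequency(snp: SNPRecord, pop: str) -> float:
    """Alternate-allele frequency in one population."""
    try:
        c = snp.counts[pop]
    except KeyError:
        raise ValidationError(f"{snp.snp_id}: no counts for population {pop!r}") from None
    if c.n_called == 0:
        raise DataError(f"{snp.snp_id}: frequency undefined in {pop} (no called genotypes)")
    return c.alt_count / (2 * c.n_called)


def minor_allele_frequency(snp: SNPRecord, pop: str) -> float:
    f = allele_frequency(snp, pop)
    return min(f, 1.0 - f)


def frequency_filter(
    snps: Iterable[SNPRecord],
    populations: Sequence[str],
    threshold: float,
    mode: str = "maf_any_pop",
) -> list[SNPRecord]:
    """Keep SNPs passing a frequency rule.

    ``maf_any_pop`` keeps a SNP when its minor-allele frequency is at least
    ``threshold`` in *at least one* of the listed populations (the
    "common in either population" rule).  ``freq_in_pop`` keeps a SNP
    segregating at minor-allele frequency >= ``threshold`` in the single
    named population.  Sites with no called genotypes in a population are
    treated as failing in that population rather than erroring.
    """
    populations = list(populations)
    if not populations:
        raise ValidationError("frequency_filter: empty population list")
    if mode == "maf_any_pop":
        if not (0.0 < threshold <= 0.5):
            raise ValidationError(f"MAF threshold must be in (0, 0.5], got {threshold}")
    elif mode == "freq_in_pop":
        if len(populations) != 1:
            raise ValidationError("freq_in_pop mode takes exactly one population")
        if not (0.0 < threshold <= 1.0):
            raise ValidationError(f"frequency threshold must be in (0, 1], got {threshold}")
    else:
        raise ValidationError(f"unknown filter mode {mode!r}")

    kept: list[SNPRecord] = []
    for snp in snps:
        mafs = []
        for pop in populations:
            c = snp.counts.get(pop)
            if c is None or c.n_called == 0:
                continue
            mafs.append(minor_allele_frequency(snp, pop))
        if mafs and max(mafs) >= threshold:
            kept.append(snp)
    return kept


def is_color_switching(ref: str, alt: str) -> bool:
    """True if the SNP switches the fluorescent colour channel.

    At the single-base-extension position the dye colour is determined by
    the incorporated nucleotide pair; substitutions within {A,T} or within
    {C,G} keep the same channel, all other substitutions switch it.
    """
    if ref not in _BASES or alt not in _BASES:
        raise ValidationError(f"non-ACGT allele pair {ref!r}/{alt!r}")
    pair = frozenset((ref, alt))
    return pair not in (frozenset("AT"), frozenset("CG"))


# ---------------------------------------------------------------------------
# tabular round-trip (for CLI chaining)

def snps_to_frame(snps: Sequence[SNPRecord], populations: Sequence[str]) -> pd.DataFrame:
    rows = []
    for s in snps:
        row: dict = {"snp_id": s.snp_id, "chrom": s.chrom, "pos": s.pos,
                     "ref": s.ref, "alt": s.alt}
        for pop in populations:
            c = s.counts[pop]
            row[f"{pop}_n_called"] = c.n_called
            row[f"{pop}_alt_count"] = c.alt_count
            row[f"{pop}_het_count"] = c.het_count
        rows.append(row)
    return pd.DataFrame(rows)


def write_snps_tsv(snps: Sequence[SNPRecord], populations: Sequence[str],
                   path: str | Path) -> None:
    snps_to_frame(snps, populations).to_csv(path, sep="\t", index=False)


def read_snps_tsv(path: str | Path) -> list[SNPRecord]:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"SNP table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    pops = sorted({c[: -len("_n_called")] for c in df.columns if c.endswith("_n_called")})
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        counts = {
            pop: PopCounts(
                n_called=int(d[f"{pop}_n_called"]),
                alt_count=int(d[f"{pop}_alt_count"]),
                het_count=int(d[f"{pop}_het_count"]),
            )
            for pop in pops
        }
        records.append(
            SNPRecord(chrom=str(d["chrom"]), pos=int(d["pos"]), snp_id=str(d["snp_id"]),
                      ref=str(d["ref"]), alt=str(d["alt"]), counts=counts)
        )
    return records
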