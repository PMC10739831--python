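"""End-to-end audit: regions -> SNPs -> cross-reference -> Fst -> report.

This is the composition the CLI's ``audit`` subcommand runs; each stage
is exactly the corresponding library call, so running the subcommands by
hand on the same inputs yields the same intermediates and report.
"""

from __future__ import annotations

import datetime
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .crossref import apply_sbe_rule, audit_cpgs, find_probe_snps, write_hits_tsv
from .errors import DataError, ValidationError
from .manifest import compute_probe_regions, read_manifest, write_regions_bed
from .meqtl_bias import (
    MeqtlRecord,
    build_report,
    classify_cpgs,
    compare_effect_sizes,
    disruption_impact,
    fit_polynomials,
    read_meqtl_table,
    select_degree,
    welch_test,
    write_report,
)
from .popgen import fst_table
from .variants import frequency_filter, read_biallelic_snps, read_panel, write_snps_tsv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_audit", "build_full_report"]


@dataclass
class RunConfig:
    """Paths, thresholds and conventions for one full audit run."""

    manifest: Path
    vcf: Path
    panel: Path
    meqtl: Path
    out_dir: Path
    populations: tuple[str, str] = ("EUR", "AFR")
    maf: float = 0.05
    fst_min: float = 0.1
    alpha: float = 0.05
    max_degree: int = 3
    type1_window: str = "sbe_minus1"
    strip_chr: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("manifest", "vcf", "panel", "meqtl", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(f"maf must be in (0, 0.5], got {self.maf}")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fst_min < 0:
            raise ValidationError("fst_min must be non-negative")
        for name in ("manifest", "vcf", "panel", "meqtl"):
            p = getattr(self, name)
            if not p.exists():
                raise ValidationError(f"{name} path does not exist: {p}")

    def provenance(self) -> dict:
        return {
            "package_version": __version__,
            "inputs": {k: str(getattr(self, k))
                       for k in ("manifest", "vcf", "panel", "meqtl")},
            "thresholds": {"maf": self.maf, "fst_min": self.fst_min,
                           "alpha": self.alpha, "max_degree": self.max_degree},
            "populations": list(self.populations),
            "type1_window": self.type1_window,
            "seed": self.seed,
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        }


def _stage(name: str):
    def wrap(func):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = func(*args, **kwargs)
            except (ValidationError, DataError) as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def _per_cpg_effect(records: list[MeqtlRecord], use: str) -> dict[str, float]:
    """One effect magnitude per CpG: the strongest association's value."""
    best: dict[str, float] = {}
    for r in records:
        val = abs(r.beta) if use == "beta" else r.delta
        if val is None:
            continue
        if r.cpg_id not in best or val > best[r.cpg_id]:
            best[r.cpg_id] = val
    return best


def run_audit(config: RunConfig) -> dict:
    """Execute the complete audit and write intermediates plus the report.

    Writes ``regions.bed``, ``snps.tsv``, ``hits.tsv``, ``fst.tsv`` and
    ``report.json`` under ``config.out_dir`` and returns the report dict.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    probes = _stage("regions")(read_manifest)(
        config.manifest, strip_chr=config.strip_chr)
    regions = compute_probe_regions(probes, config.type1_window)
    write_regions_bed(regions, out / "regions.bed")
    logger.info("computed %d probe regions", len(regions))

    panel = _stage("panel")(read_panel)(config.panel)
    snps = _stage("snps")(read_biallelic_snps)(
        config.vcf, panel, config.populations)
    common = frequency_filter(snps, config.populations, config.maf,
                              mode="maf_any_pop")
    write_snps_tsv(common, config.populations, out / "snps.tsv")
    logger.info("%d biallelic SNVs, %d pass MAF >= %g", len(snps),
                len(common), config.maf)

    hits = _stage("crossref")(find_probe_snps)(regions, common)
    retained = apply_sbe_rule(hits)
    write_hits_tsv(retained, out / "hits.tsv")
    logger.info("%d probe-SNP hits (%d after SBE rule)", len(hits), len(retained))

    fst_df = _stage("fst")(fst_table)(common, *config.populations)
    fst_df.to_csv(out / "fst.tsv", sep="\t", index=False)
    fst_map = dict(zip(fst_df["snp_id"], fst_df["theta"]))

    audits = audit_cpgs(regions, retained, fst_map)
    records = _stage("meqtl")(read_meqtl_table)(config.meqtl)

    report = _stage("report")(build_full_report)(
        audits, records, fst_map, fst_min=config.fst_min, alpha=config.alpha,
        max_degree=config.max_degree, provenance=config.provenance())
    write_report(report, out / "report.json")
    if not report["complete"]:
        raise DataError("report has null sections; see report.json")
    return report


def build_full_report(
    audits,
    records,
    fst_map,
    *,
    fst_min: float = 0.1,
    alpha: float = 0.05,
    max_degree: int = 3,
    provenance: dict | None = None,
) -> dict:
    """Compute every report section from audited CpGs, meQTL records and Fst."""
    meqtl_cpgs = {r.cpg_id for r in records}
    enrichment = classify_cpgs(meqtl_cpgs, audits)

    # per-SNP Fst, split by whether the probe SNP's CpG is meQTL-associated
    theta_meqtl, theta_non = [], []
    seen: set[str] = set()
    for a in audits:
        for h in a.hits:
            if h.snp_id in seen:
                continue
            seen.add(h.snp_id)
            theta = fst_map.get(h.snp_id)
            if theta is None or np.isnan(theta):
                continue
            (theta_meqtl if a.cpg_id in meqtl_cpgs else theta_non).append(theta)
    fst_section = None
    if len(theta_meqtl) >= 2 and len(theta_non) >= 2:
        wt = welch_test(theta_meqtl, theta_non,
                        names=("meqtl_probe_snps", "non_meqtl_probe_snps"))
        fst_section = {
            "meqtl": {"n": len(theta_meqtl),
                      "median": float(np.median(theta_meqtl)),
                      "mean": float(np.mean(theta_meqtl))},
            "non_meqtl": {"n": len(theta_non),
                          "median": float(np.median(theta_non)),
                          "mean": float(np.mean(theta_non))},
            "welch": {
                "mean_diff": wt.mean_diff, "t_stat": wt.t_stat, "df": wt.df,
                "p_value": wt.p_value, "ci95": [wt.ci_low, wt.ci_high],
            },
        }

    effect_beta = compare_effect_sizes(records, audits, use="beta")
    la_records = [r for r in records if r.delta is not None]
    effect_delta = None
    if la_records:
        try:
            effect_delta = compare_effect_sizes(records, audits, use="delta")
        except DataError:
            effect_delta = None

    rep_distance = {
        a.cpg_id: a.representative_hit.distance
        for a in audits if a.representative_hit is not None
    }

    def regression(recs: list[MeqtlRecord], use: str):
        per_cpg = _per_cpg_effect(recs, use)
        pairs = [(rep_distance[c], v) for c, v in per_cpg.items()
                 if c in rep_distance]
        if len(pairs) <= max_degree + 1:
            return None
        x, y = zip(*sorted(pairs))
        fits = fit_polynomials(x, y, max_degree)
        return fits, select_degree(fits, alpha)

    regression_beta = regression(records, "beta")
    regression_delta = regression(la_records, "delta") if la_records else None

    impact_naive = disruption_impact(records, audits, fst_map, fst_min)
    impact_aware = (disruption_impact(la_records, audits, fst_map, fst_min)
                    if la_records else None)

    return build_report(
        provenance=provenance or {},
        enrichment=enrichment,
        fst_comparison=fst_section,
        effect_beta=effect_beta,
        effect_delta=effect_delta,
        regression_beta=regression_beta,
        regression_delta=regression_delta,
        impact_naive=impact_naive,
        impact_aware=impact_aware,
    )
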