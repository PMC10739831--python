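"""Synthetic fixtures with the statistical structure the audit assumes.

The generator emulates, at desk scale, the situation the diagnostics are
built for: a methylation-array manifest whose probes may carry common
SNPs; two populations (labelled EUR and AFR) whose allele frequencies
diverge under the Balding–Nichols model; and meQTL tables in which effect
magnitude depends on the distance between the probe SNP and the target
cytosine — the signature of a hybridization artifact rather than biology.

Structure planted by default (sizes and rates follow the admixed-cohort
reanalysis setting this package targets):

* 2500 probes on one chromosome, all four strand x Infinium-type
  combinations, non-overlapping regions; 946 of them are designated
  meQTL-associated CpGs.
* meQTL probes carry a common probe SNP with probability 0.375 and those
  SNPs are strongly differentiated (Balding–Nichols F = 0.3); other
  probes carry one with probability 0.161 at background divergence
  (F = 0.01).  Planted probe SNPs are guaranteed common (sample minor
  allele frequency >= 5% in at least one population); 27% of them land on
  the CpG dinucleotide itself (probe index 0 or 1).
* genotypes are Hardy–Weinberg draws (Binomial(2, p_pop)) for 100 diploid
  samples per population, written as a plain-text VCF plus panel file.
* meQTL effect magnitudes follow a cubic polynomial in probe-SNP distance
  plus Gaussian noise (floored at 0); ancestry-specific effect-size
  differences (Δ) follow a quadratic, for a subset of 135 CpGs mirroring
  an LA-aware result set (58 of them with probe SNPs).

Everything is driven by a single ``numpy`` Generator seeded from
``SimulationConfig.seed``, so outputs are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .manifest import (
    InfiniumType,
    ProbeRecord,
    ProbeRegion,
    Strand,
    compute_probe_region,
)

__all__ = [
    "SimulationConfig",
    "simulate_manifest",
    "simulate_population_snps",
    "simulate_meqtl_table",
    "simulate_distance_effects",
    "simulate_balding_nichols_counts",
    "simulate_all",
]

_COMBOS = ((Strand.F, InfiniumType.I), (Strand.F, InfiniumType.II),
           (Strand.R, InfiniumType.I), (Strand.R, InfiniumType.II))


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults are the study conditions."""

    seed: int = 0
    chrom: str = "chr1"
    n_probes: int = 2500
    n_meqtl_probes: int = 946
    first_pos: int = 1000
    probe_spacing: int = 200
    strand_type_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    # probe-SNP planting
    p_probe_snp_meqtl: float = 0.375
    p_probe_snp_background: float = 0.161
    p_cpg_site_index: float = 0.27  # planted index in {0, 1}
    maf_floor: float = 0.05  # planted SNPs guaranteed common at this MAF

    # population model
    n_background_snps: int = 500
    f_differentiated: float = 0.3
    f_background: float = 0.01
    n_per_pop: int = 100
    pop_names: tuple[str, str] = ("EUR", "AFR")

    # effect models (distance d in bp, magnitudes in methylation SD units)
    beta_coeffs: tuple[float, float, float, float] = (2.2, -0.24, 0.0093, -1.05e-4)
    beta_sigma: float = 0.9
    beta_baseline_mean: float = 0.55
    beta_baseline_sd: float = 0.4
    delta_coeffs: tuple[float, float, float] = (1.8, -0.08, 0.001)
    delta_sigma: float = 0.8
    delta_baseline_mean: float = 0.4
    delta_baseline_sd: float = 0.35
    n_la_probe_snp: int = 58
    n_la_other: int = 77
    extra_assoc_rate_disrupted: float = 0.8
    extra_assoc_rate_other: float = 0.25

    type1_window: str = "sbe_minus1"

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValidationError("n_probes must be >= 1")
        if not (0 < self.n_meqtl_probes < self.n_probes):
            raise ValidationError("n_meqtl_probes must be in (0, n_probes)")
        if abs(sum(self.strand_type_mix) - 1.0) > 1e-9:
            raise ValidationError("strand_type_mix must sum to 1")
        for name in ("f_differentiated", "f_background"):
            f = getattr(self, name)
            if not (0.0 < f < 1.0):
                raise ValidationError(f"{name} must be in (0, 1), got {f}")
        if self.beta_sigma <= 0 or self.delta_sigma <= 0:
            raise ValidationError("noise standard deviations must be positive")
        if self.probe_spacing < 102:
            raise ValidationError(
                "probe_spacing must be >= 102 so 51-bp regions cannot overlap"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _combo_counts(n: int, mix: tuple[float, ...]) -> list[int]:
    """Deterministic counts per strand x type combo honouring the mixture.

    When n >= 4 every combo with positive weight appears at least once.
    """
    counts = [int(np.floor(w * n)) for w in mix]
    if n >= len(mix):
        counts = [max(c, 1) if w > 0 else 0 for c, w in zip(counts, mix)]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n:
        deficit = [w * n - c for w, c in zip(mix, counts)]
        counts[int(np.argmax(deficit))] += 1
    return counts


def simulate_manifest(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate a probe manifest as a DataFrame in manifest-CSV layout.

    Probes sit ``probe_spacing`` bp apart on one chromosome so regions
    never overlap; the strand/type mixture is honoured exactly (all four
    combinations present whenever ``n_probes >= 4``), with combo-to-probe
    assignment shuffled by the seeded generator.  An ``is_meqtl`` column
    marks the probes designated as meQTL-associated CpGs.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_probes
    counts = _combo_counts(n, config.strand_type_mix)
    combos = [c for c, k in zip(_COMBOS, counts) for _ in range(k)]
    rng.shuffle(combos)
    meqtl_idx = set(rng.choice(n, size=config.n_meqtl_probes, replace=False).tolist())
    rows = []
    width = len(str(n))
    for i, (strand, itype) in enumerate(combos):
        rows.append(
            {
                "IlmnID": f"cg{i:0{width}d}",
                "CHR": config.chrom,
                "MAPINFO": config.first_pos + i * config.probe_spacing,
                "Strand": strand.value,
                "Infinium_Design_Type": itype.value,
                "is_meqtl": i in meqtl_idx,
            }
        )
    return pd.DataFrame(rows)


def _planted_index(region: ProbeRegion, rng: np.random.Generator,
                   p_cpg: float) -> int:
    if rng.random() < p_cpg:
        return int(rng.integers(0, 2))
    others = [i for i in range(region.index_min, region.index_max + 1)
              if i not in (0, 1)]
    return int(others[rng.integers(0, len(others))])


def _balding_nichols(p_anc: float, f: float, rng: np.random.Generator,
                     size: int = 2) -> np.ndarray:
    shape = (1.0 - f) / f
    return rng.beta(p_anc * shape, (1.0 - p_anc) * shape, size=size)


def _draw_genotypes(p_pop: np.ndarray, n_per_pop: int,
                    rng: np.random.Generator) -> list[np.ndarray]:
    return [rng.binomial(2, p, size=n_per_pop) for p in p_pop]


def _sample_maf_ok(gts: list[np.ndarray], n_per_pop: int, floor: float) -> bool:
    for g in gts:
        f = g.sum() / (2 * n_per_pop)
        if min(f, 1.0 - f) >= floor:
            return True
    return False


def simulate_population_snps(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    regions: dict[str, ProbeRegion],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant probe SNPs and background SNPs; draw two-population genotypes.

    Returns ``(snp_truth, genotype_frame)``: per-SNP truth (class,
    ancestral and population frequencies, planted probe index) and the
    genotype matrix (rows = SNPs sorted by position, columns = samples).
    Planted probe SNPs are redrawn until their sample minor-allele
    frequency reaches ``maf_floor`` in at least one population, so every
    planted SNP is discoverable by the audit's frequency filter.
    """
    bases = np.array(list("ACGT"))
    truth_rows = []
    geno_rows = []

    def draw_alleles() -> tuple[str, str]:
        ref = bases[rng.integers(0, 4)]
        alt = bases[rng.integers(0, 4)]
        while alt == ref:
            alt = bases[rng.integers(0, 4)]
        return str(ref), str(alt)

    snp_serial = 0
    for row in manifest.itertuples(index=False):
        p_plant = (config.p_probe_snp_meqtl if row.is_meqtl
                   else config.p_probe_snp_background)
        if rng.random() >= p_plant:
            continue
        region = regions[row.IlmnID]
        idx = _planted_index(region, rng, config.p_cpg_site_index)
        if region.strand is Strand.F:
            pos = region.target_c_pos + idx
        else:
            pos = region.target_c_pos - idx
        f = config.f_differentiated if row.is_meqtl else config.f_background
        for _ in range(1000):
            p_anc = rng.uniform(0.05, 0.95)
            p_pop = _balding_nichols(p_anc, f, rng)
            gts = _draw_genotypes(p_pop, config.n_per_pop, rng)
            if _sample_maf_ok(gts, config.n_per_pop, config.maf_floor):
                break
        else:  # pragma: no cover - would need absurd maf_floor
            raise ValidationError("could not plant a common SNP; lower maf_floor")
        ref, alt = draw_alleles()
        snp_id = f"rs{snp_serial:06d}"
        snp_serial += 1
        truth_rows.append(
            {"snp_id": snp_id, "chrom": config.chrom, "pos": pos, "ref": ref,
             "alt": alt, "snp_class": "differentiated" if row.is_meqtl else "background",
             "p_anc": p_anc, "p_pop1": p_pop[0], "p_pop2": p_pop[1],
             "planted_cpg": row.IlmnID, "planted_index": idx}
        )
        geno_rows.append(np.concatenate(gts))

    # background SNPs outside every probe region
    last_pos = int(manifest["MAPINFO"].max())
    for j in range(config.n_background_snps):
        if j < config.n_probes:
            pos = config.first_pos + j * config.probe_spacing + 100
        else:
            pos = last_pos + 1000 + 10 * (j - config.n_probes)
        p_anc = rng.uniform(0.05, 0.95)
        p_pop = _balding_nichols(p_anc, config.f_background, rng)
        gts = _draw_genotypes(p_pop, config.n_per_pop, rng)
        ref, alt = draw_alleles()
        snp_id = f"rs{snp_serial:06d}"
        snp_serial += 1
        truth_rows.append(
            {"snp_id": snp_id, "chrom": config.chrom, "pos": pos, "ref": ref,
             "alt": alt, "snp_class": "intergenic", "p_anc": p_anc,
             "p_pop1": p_pop[0], "p_pop2": p_pop[1],
             "planted_cpg": "", "planted_index": np.nan}
        )
        geno_rows.append(np.concatenate(gts))

    truth = pd.DataFrame(truth_rows)
    order = np.argsort(truth["pos"].to_numpy(), kind="stable")
    truth = truth.iloc[order].reset_index(drop=True)
    genos = pd.DataFrame(
        np.asarray(geno_rows)[order],
        columns=[f"{pop}_{i:03d}" for pop in config.pop_names
                 for i in range(config.n_per_pop)],
    )
    return truth, genos


def write_vcf(truth: pd.DataFrame, genos: pd.DataFrame, chrom: str,
              path: str | Path) -> None:
    """Write planted SNPs + genotypes as a minimal valid plain-text VCF."""
    samples = list(genos.columns)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        mat = genos.to_numpy()
        for i, row in enumerate(truth.itertuples(index=False)):
            gts = "\t".join(gt_str[int(g)] for g in mat[i])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_panel(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpop\n")
        for pop in config.pop_names:
            for i in range(config.n_per_pop):
                fh.write(f"{pop}_{i:03d}\t{pop}\n")


def simulate_balding_nichols_counts(
    n_snps: int,
    f: float,
    n_per_pop: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-site genotype summaries for two populations diverged at F = f.

    For each site: ancestral frequency ~ Uniform(0.05, 0.95), population
    frequencies ~ Balding–Nichols Beta, diploid genotypes ~ Binomial(2, p)
    per sample.  Returns columns n1, p1, h1, n2, p2, h2 (sample allele
    frequencies and observed heterozygote fractions) ready for the
    Weir–Cockerham estimator.
    """
    rows = []
    for _ in range(n_snps):
        p_anc = rng.uniform(0.05, 0.95)
        p_pop = _balding_nichols(p_anc, f, rng)
        g1, g2 = _draw_genotypes(p_pop, n_per_pop, rng)
        rows.append({
            "n1": n_per_pop, "p1": g1.sum() / (2 * n_per_pop),
            "h1": (g1 == 1).sum() / n_per_pop,
            "n2": n_per_pop, "p2": g2.sum() / (2 * n_per_pop),
            "h2": (g2 == 1).sum() / n_per_pop,
        })
    return pd.DataFrame(rows)


def _poly(coeffs: tuple[float, ...], d: np.ndarray) -> np.ndarray:
    out = np.zeros_like(d, dtype=float)
    for k, c in enumerate(coeffs):
        out += c * d ** k
    return out


def simulate_distance_effects(
    n: int,
    coeffs: tuple[float, ...],
    sigma: float,
    rng: np.random.Generator,
    p_cpg_site: float = 0.27,
    max_distance: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (distance, effect magnitude) pairs from the planted model.

    Distances are 0 or 1 with probability ``p_cpg_site`` (CpG-site SNPs)
    and otherwise uniform on 2..max_distance; magnitudes are the
    polynomial in distance plus Gaussian noise, floored at 0.
    """
    at_cpg = rng.random(n) < p_cpg_site
    d = np.where(at_cpg, rng.integers(0, 2, n), rng.integers(2, max_distance + 1, n))
    d = d.astype(float)
    y = np.maximum(_poly(coeffs, d) + rng.normal(0.0, sigma, n), 0.0)
    return d, y


def simulate_meqtl_table(
    config: SimulationConfig,
    manifest: pd.DataFrame,
    snp_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate meQTL associations for the designated meQTL CpGs.

    CpGs with a planted probe SNP get |beta| from the cubic
    distance-effect model at the planted distance; CpGs without get a
    baseline folded-normal magnitude.  CpG-site (index 0/1) SNPs attract
    extra associations, mimicking the amplification of artifact signals.
    A subset of CpGs additionally receives ancestry-specific effect sizes
    whose difference Δ follows the quadratic distance model.
    """
    planted = snp_truth[snp_truth["planted_cpg"] != ""].set_index("planted_cpg")
    meqtl_cpgs = manifest[manifest["is_meqtl"]]["IlmnID"].tolist()

    rows = []
    assoc_serial = 0
    for cpg in meqtl_cpgs:
        if cpg in planted.index:
            d = abs(float(planted.loc[cpg, "planted_index"]))
            mu = float(_poly(config.beta_coeffs, np.array([d]))[0])
            beta = max(mu + rng.normal(0.0, config.beta_sigma), 0.0)
            disrupted = d in (0.0, 1.0)
            has_snp = True
        else:
            beta = abs(rng.normal(config.beta_baseline_mean, config.beta_baseline_sd))
            disrupted = False
            has_snp = False
        rate = (config.extra_assoc_rate_disrupted if disrupted
                else config.extra_assoc_rate_other)
        n_assoc = 1 + int(rng.poisson(rate))
        for _ in range(n_assoc):
            rows.append({"cpg_id": cpg, "snp_id": f"mq{assoc_serial:06d}",
                         "beta": beta * float(rng.uniform(0.85, 1.15)),
                         "has_probe_snp": has_snp})
            assoc_serial += 1
    df = pd.DataFrame(rows)

    # LA-aware subset: ancestry-specific effects with planted Δ structure
    with_snp = [c for c in meqtl_cpgs if c in planted.index]
    without = [c for c in meqtl_cpgs if c not in planted.index]
    n_with = min(config.n_la_probe_snp, len(with_snp))
    n_without = min(config.n_la_other, len(without))
    la_with = rng.choice(with_snp, size=n_with, replace=False).tolist()
    la_without = rng.choice(without, size=n_without, replace=False).tolist()
    la_set = set(la_with) | set(la_without)

    deltas = {}
    for cpg in la_with:
        d = abs(float(planted.loc[cpg, "planted_index"]))
        mu = float(_poly(config.delta_coeffs, np.array([d]))[0])
        deltas[cpg] = max(mu + rng.normal(0.0, config.delta_sigma), 0.0)
    for cpg in la_without:
        deltas[cpg] = abs(rng.normal(config.delta_baseline_mean,
                                     config.delta_baseline_sd))

    beta_eur = []
    beta_afr = []
    for r in df.itertuples(index=False):
        if r.cpg_id in la_set:
            delta = deltas[r.cpg_id]
            beta_eur.append(r.beta + delta / 2.0)
            beta_afr.append(r.beta - delta / 2.0)
        else:
            beta_eur.append(np.nan)
            beta_afr.append(np.nan)
    df["beta_eur"] = beta_eur
    df["beta_afr"] = beta_afr
    return df.drop(columns=["has_probe_snp"]).assign(
        has_probe_snp=df["has_probe_snp"]
    )


def simulate_all(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the full generator and write every fixture file.

    Produces ``manifest.csv``, ``variants.vcf``, ``panel.txt``,
    ``meqtl.tsv``, ``truth_probes.tsv`` and ``truth_snps.tsv`` under
    ``out_dir`` and returns their paths.  All draws come from one
    seeded generator, so identical configs yield identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()

    manifest_df = simulate_manifest(config, rng)
    probes = [
        ProbeRecord(cpg_id=r.IlmnID, chrom=r.CHR, pos=int(r.MAPINFO),
                    strand=Strand(r.Strand),
                    infinium_type=InfiniumType(r.Infinium_Design_Type))
        for r in manifest_df.itertuples(index=False)
    ]
    regions = {p.cpg_id: compute_probe_region(p, config.type1_window)
               for p in probes}
    snp_truth, genos = simulate_population_snps(config, manifest_df, regions, rng)
    meqtl_df = simulate_meqtl_table(config, manifest_df, snp_truth, rng)

    paths = {
        "manifest": out_dir / "manifest.csv",
        "vcf": out_dir / "variants.vcf",
        "panel": out_dir / "panel.txt",
        "meqtl": out_dir / "meqtl.tsv",
        "truth_probes": out_dir / "truth_probes.tsv",
        "truth_snps": out_dir / "truth_snps.tsv",
    }
    manifest_df.drop(columns=["is_meqtl"]).to_csv(paths["manifest"], index=False)
    write_vcf(snp_truth, genos, config.chrom, paths["vcf"])
    write_panel(config, paths["panel"])
    meqtl_df.drop(columns=["has_probe_snp"]).to_csv(paths["meqtl"], sep="\t",
                                                    index=False)
    manifest_df.to_csv(paths["truth_probes"], sep="\t", index=False)
    snp_truth.to_csv(paths["truth_snps"], sep="\t", index=False)
    return paths
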