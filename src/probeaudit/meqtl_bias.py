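"""Diagnostics linking probe SNPs to meQTL effect-size artifacts.

The question these statistics address: do reported meQTL effects behave
the way hybridization artifacts would?  Four complementary views:

* enrichment — are meQTL-associated CpGs more likely than other CpGs to
  carry a common probe SNP?
* differentiation — are probe SNPs of meQTL CpGs more differentiated
  between the two ancestral populations than those of other CpGs
  (Welch two-sample t-test on per-SNP Fst)?
* effect-size comparison — are effects (or ancestry-specific effect-size
  differences, Δ) larger at CpGs with probe SNPs?
* distance regression — does the distance between the probe SNP and the
  target cytosine predict effect magnitude?  Polynomials of increasing
  degree are fit by OLS and compared with sequential nested F-tests.

Disruption accounting counts CpGs whose probe SNP lands on the CpG
dinucleotide itself (probe index 0 or 1) while being strongly
differentiated: at such sites one haplotype class physically lacks the
CpG, so a low methylation readout is a genotype artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .crossref import CpGAudit
from .errors import DataError, ValidationError

__all__ = [
    "MeqtlRecord",
    "WelchTestResult",
    "PolyFit",
    "SelectionStep",
    "ModelSelection",
    "ImpactSummary",
    "read_meqtl_table",
    "classify_cpgs",
    "welch_test",
    "compare_effect_sizes",
    "fit_polynomials",
    "select_degree",
    "disruption_impact",
    "build_report",
    "write_report",
]


@dataclass(frozen=True)
class MeqtlRecord:
    """One meQTL association: a CpG, its associated variant, and effects.

    ``snp_id`` is the associated meQTL variant (not necessarily a probe
    SNP).  ``beta_eur``/``beta_afr`` are optional ancestry-specific effect
    sizes; ``delta`` (|beta_eur - beta_afr|) exists only when both do.
    """

    cpg_id: str
    snp_id: str
    beta: float
    beta_eur: float | None = None
    beta_afr: float | None = None

    def __post_init__(self) -> None:
        if (self.beta_eur is None) != (self.beta_afr is None):
            raise DataError(
                f"{self.cpg_id}/{self.snp_id}: ancestry-specific effects must "
                "be given in pairs"
            )

    @property
    def delta(self) -> float | None:
        if self.beta_eur is None or self.beta_afr is None:
            return None
        return abs(self.beta_eur - self.beta_afr)


@dataclass(frozen=True)
class WelchTestResult:
    """Welch (unequal-variance) two-sided t-test with 95% CI."""

    mean_diff: float
    t_stat: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class PolyFit:
    """One OLS polynomial fit (intercept-first coefficients)."""

    degree: int
    coefficients: tuple[float, ...]
    rss: float
    tss: float
    r2: float
    n: int


@dataclass(frozen=True)
class SelectionStep:
    degree: int
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


@dataclass(frozen=True)
class ModelSelection:
    """Result of forward sequential F-testing over nested polynomial fits."""

    chosen_degree: int
    alpha: float
    steps: tuple[SelectionStep, ...]


@dataclass(frozen=True)
class ImpactSummary:
    """Disruption accounting for one meQTL result set."""

    n_cpgs_total: int
    n_cpgs_disrupted_differentiated: int
    cpg_fraction: float
    n_assoc_total: int
    n_assoc_impacted: int
    assoc_fraction: float
    median_fst_implicated: float | None


def read_meqtl_table(path: str | Path) -> list[MeqtlRecord]:
    """Read a meQTL TSV (cpg_id, snp_id, beta[, beta_eur, beta_afr])."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"meQTL table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    for col in ("cpg_id", "snp_id", "beta"):
        if col not in df.columns:
            raise DataError(f"meQTL table {path} lacks column {col!r}")
    has_la = "beta_eur" in df.columns and "beta_afr" in df.columns
    records = []
    for r in df.itertuples(index=False):
        be = ba = None
        if has_la and not (pd.isna(r.beta_eur) or pd.isna(r.beta_afr)):
            be, ba = float(r.beta_eur), float(r.beta_afr)
        records.append(
            MeqtlRecord(cpg_id=str(r.cpg_id), snp_id=str(r.snp_id),
                        beta=float(r.beta), beta_eur=be, beta_afr=ba)
        )
    return records


def classify_cpgs(
    meqtl_cpg_ids: Iterable[str], audits: Sequence[CpGAudit]
) -> tuple[float, float]:
    """Probe-SNP CpG fraction among meQTL CpGs vs all other audited CpGs."""
    by_id = {a.cpg_id: a for a in audits}
    meqtl = set(meqtl_cpg_ids)
    unknown = meqtl - by_id.keys()
    if unknown:
        raise DataError(
            f"{len(unknown)} meQTL CpG id(s) not audited (e.g. {sorted(unknown)[0]!r})"
        )
    non_meqtl = [a for a in audits if a.cpg_id not in meqtl]
    if not meqtl:
        raise ValidationError("empty meQTL CpG set")
    if not non_meqtl:
        raise DataError("no non-meQTL CpGs: complement fraction undefined")
    f_meqtl = sum(by_id[c].has_probe_snp for c in meqtl) / len(meqtl)
    f_non = sum(a.has_probe_snp for a in non_meqtl) / len(non_meqtl)
    return f_meqtl, f_non


def welch_test(
    values_a: Sequence[float], values_b: Sequence[float],
    names: tuple[str, str] = ("a", "b"),
) -> WelchTestResult:
    """Two-sided Welch t-test with a Welch–Satterthwaite 95% CI."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    for arr, name in ((a, names[0]), (b, names[1])):
        if arr.size < 2:
            raise ValidationError(f"group {name!r} needs >= 2 values, got {arr.size}")
        if np.var(arr) == 0.0:
            raise ValidationError(f"group {name!r} has zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return WelchTestResult(
        mean_diff=float(a.mean() - b.mean()),
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def compare_effect_sizes(
    meqtl_records: Sequence[MeqtlRecord],
    audits: Sequence[CpGAudit],
    use: str = "beta",
) -> tuple[WelchTestResult, int]:
    """Compare effect magnitudes between CpGs with and without probe SNPs.

    ``use="beta"`` compares |beta|; ``use="delta"`` compares the
    ancestry-specific effect difference Δ, silently excluding records that
    lack ancestry-specific effects (the count of exclusions is returned).
    Returns ``(welch_result, n_excluded)`` where group *a* is
    with-probe-SNP and group *b* is without.
    """
    if use not in ("beta", "delta"):
        raise ValidationError(f"unknown effect measure {use!r}")
    has_snp = {a.cpg_id: a.has_probe_snp for a in audits}
    missing = {r.cpg_id for r in meqtl_records} - has_snp.keys()
    if missing:
        raise DataError(
            f"{len(missing)} meQTL CpG(s) not audited (e.g. {sorted(missing)[0]!r})"
        )
    with_snp: list[float] = []
    without: list[float] = []
    n_excluded = 0
    for r in meqtl_records:
        if use == "delta":
            if r.delta is None:
                n_excluded += 1
                continue
            val = r.delta
        else:
            val = abs(r.beta)
        (with_snp if has_snp[r.cpg_id] else without).append(val)
    if not with_snp or not without:
        raise DataError(
            "cannot compare effect sizes: one of the probe-SNP groups is empty"
        )
    result = welch_test(with_snp, without, names=("with_probe_snp", "without_probe_snp"))
    return result, n_excluded


def fit_polynomials(
    x: Sequence[float], y: Sequence[float], max_degree: int = 3
) -> list[PolyFit]:
    """OLS polynomial fits of degree 1..max_degree (intercept included).

    R² is 1 - RSS/TSS, reported as 0 when the response is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if max_degree < 1:
        raise ValidationError("max_degree must be >= 1")
    n = x.size
    if n <= max_degree + 1:
        raise ValidationError(f"need more than {max_degree + 1} points, got {n}")
    if np.ptp(x) == 0.0:
        raise DataError("all x values identical: polynomial fit is rank-deficient")

    tss = float(((y - y.mean()) ** 2).sum())
    fits: list[PolyFit] = []
    for degree in range(1, max_degree + 1):
        X = np.vander(x, degree + 1, increasing=True)
        model = sm.OLS(y, X).fit()
        if model.df_model < degree:  # collinear design for this degree
            raise DataError(f"design matrix rank-deficient at degree {degree}")
        rss = float(model.ssr)
        r2 = 0.0 if tss == 0.0 else 1.0 - rss / tss
        fits.append(
            PolyFit(degree=degree, coefficients=tuple(map(float, model.params)),
                    rss=rss, tss=tss, r2=r2, n=n)
        )
    return fits


def select_degree(fits: Sequence[PolyFit], alpha: float = 0.05) -> ModelSelection:
    """Forward sequential nested F-tests over consecutive-degree fits.

    Each step tests degree k against degree k-1 (degree 0 = intercept-only,
    RSS = TSS) with F = (RSS_{k-1} - RSS_k) / (RSS_k / (n - k - 1)).
    Selection starts at the linear model and escalates while the step
    p-value is below ``alpha``; the linear model is the floor, so the
    chosen degree is at least 1.  A perfect fit (RSS_k = 0) reports an
    infinite F and p = 0.
    """
    if not fits:
        raise ValidationError("no fits supplied")
    fits = sorted(fits, key=lambda f: f.degree)
    degrees = [f.degree for f in fits]
    if degrees != list(range(1, len(fits) + 1)):
        raise ValidationError(f"need consecutive degrees starting at 1, got {degrees}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    n = fits[0].n
    if any(f.n != n or f.tss != fits[0].tss for f in fits):
        raise ValidationError("fits were not computed on identical data")

    steps: list[SelectionStep] = []
    prev_rss = fits[0].tss
    for fit in fits:
        k = fit.degree
        df_den = n - k - 1
        if fit.rss == 0.0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat = (prev_rss - fit.rss) / (fit.rss / df_den)
            p = float(stats.f.sf(f_stat, 1, df_den))
        steps.append(SelectionStep(degree=k, f_stat=float(f_stat),
                                   df_num=1, df_den=df_den, p_value=p))
        prev_rss = fit.rss
    # escalate while consecutive steps stay significant; linear is the floor
    chosen = 1
    for step in steps:
        if step.p_value < alpha:
            chosen = step.degree
        else:
            break
    return ModelSelection(chosen_degree=max(chosen, 1), alpha=alpha, steps=tuple(steps))


def disruption_impact(
    meqtl_records: Sequence[MeqtlRecord],
    audits: Sequence[CpGAudit],
    fst: Mapping[str, float],
    fst_min: float = 0.1,
) -> ImpactSummary:
    """Count meQTL CpGs whose CpG site is disrupted by a differentiated SNP.

    A CpG is counted when it has a retained probe-SNP hit at probe index 0
    or 1 with Fst >= ``fst_min``; the association-level fraction counts
    every meQTL record whose CpG qualifies.  The reported median Fst is
    taken over the highest-Fst qualifying hit of each counted CpG.
    """
    audit_by_id = {a.cpg_id: a for a in audits}
    meqtl_cpgs = sorted({r.cpg_id for r in meqtl_records})
    missing = [c for c in meqtl_cpgs if c not in audit_by_id]
    if missing:
        raise DataError(f"meQTL CpG(s) not audited: {', '.join(missing[:5])}")

    disrupted: set[str] = set()
    implicated_fst: list[float] = []
    for cpg in meqtl_cpgs:
        qual: list[float] = []
        for h in audit_by_id[cpg].hits:
            if not h.disrupts_cpg:
                continue
            if h.snp_id not in fst:
                raise DataError(f"no Fst available for probe SNP {h.snp_id!r}")
            theta = fst[h.snp_id]
            if theta is None or (isinstance(theta, float) and np.isnan(theta)):
                raise DataError(f"Fst undefined for probe SNP {h.snp_id!r}")
            if theta >= fst_min:
                qual.append(float(theta))
        if qual:
            disrupted.add(cpg)
            implicated_fst.append(max(qual))

    n_cpgs = len(meqtl_cpgs)
    n_assoc = len(meqtl_records)
    n_assoc_hit = sum(r.cpg_id in disrupted for r in meqtl_records)
    return ImpactSummary(
        n_cpgs_total=n_cpgs,
        n_cpgs_disrupted_differentiated=len(disrupted),
        cpg_fraction=len(disrupted) / n_cpgs if n_cpgs else 0.0,
        n_assoc_total=n_assoc,
        n_assoc_impacted=n_assoc_hit,
        assoc_fraction=n_assoc_hit / n_assoc if n_assoc else 0.0,
        median_fst_implicated=float(np.median(implicated_fst)) if implicated_fst else None,
    )


# ---------------------------------------------------------------------------
# report assembly


def _welch_dict(res: WelchTestResult | None) -> dict | None:
    if res is None:
        return None
    return {
        "mean_diff": res.mean_diff, "t_stat": res.t_stat, "df": res.df,
        "p_value": res.p_value, "ci95": [res.ci_low, res.ci_high],
        "n_a": res.n_a, "n_b": res.n_b,
    }


def _regression_dict(fits: Sequence[PolyFit] | None,
                     selection: ModelSelection | None) -> dict | None:
    if fits is None:
        return None
    return {
        "fits": [
            {"degree": f.degree, "coefficients": list(f.coefficients),
             "rss": f.rss, "r2": f.r2, "n": f.n}
            for f in fits
        ],
        "selection": None if selection is None else {
            "chosen_degree": selection.chosen_degree,
            "alpha": selection.alpha,
            "steps": [
                {"degree": s.degree, "f_stat": s.f_stat, "df_num": s.df_num,
                 "df_den": s.df_den, "p_value": s.p_value}
                for s in selection.steps
            ],
        },
    }


def _impact_dict(imp: ImpactSummary | None) -> dict | None:
    if imp is None:
        return None
    return {
        "n_cpgs_total": imp.n_cpgs_total,
        "n_cpgs_disrupted_differentiated": imp.n_cpgs_disrupted_differentiated,
        "cpg_fraction": imp.cpg_fraction,
        "n_assoc_total": imp.n_assoc_total,
        "n_assoc_impacted": imp.n_assoc_impacted,
        "assoc_fraction": imp.assoc_fraction,
        "median_fst_implicated": imp.median_fst_implicated,
    }


def build_report(
    provenance: dict,
    enrichment: tuple[float, float] | None = None,
    fst_comparison: dict | None = None,
    effect_beta: tuple[WelchTestResult, int] | None = None,
    effect_delta: tuple[WelchTestResult, int] | None = None,
    regression_beta: tuple[Sequence[PolyFit], ModelSelection] | None = None,
    regression_delta: tuple[Sequence[PolyFit], ModelSelection] | None = None,
    impact_naive: ImpactSummary | None = None,
    impact_aware: ImpactSummary | None = None,
) -> dict:
    """Assemble the full diagnostic report as a JSON-serialisable dict.

    Sections whose inputs were unavailable appear explicitly as null.
    ``complete`` is True only when every section is populated.
    """
    report = {
        "provenance": provenance,
        "enrichment": None if enrichment is None else {
            "meqtl_probe_snp_fraction": enrichment[0],
            "non_meqtl_probe_snp_fraction": enrichment[1],
        },
        "fst_comparison": fst_comparison,
        "effect_size": {
            "beta": None if effect_beta is None else {
                "welch": _welch_dict(effect_beta[0]),
                "n_excluded": effect_beta[1],
                "regression": _regression_dict(*regression_beta)
                if regression_beta else None,
            },
            "delta": None if effect_delta is None else {
                "welch": _welch_dict(effect_delta[0]),
                "n_excluded": effect_delta[1],
                "regression": _regression_dict(*regression_delta)
                if regression_delta else None,
            },
        },
        "impact": {
            "la_naive": _impact_dict(impact_naive),
            "la_aware": _impact_dict(impact_aware),
        },
    }
    report["complete"] = all(
        v is not None
        for v in (
            report["enrichment"], report["fst_comparison"],
            report["effect_size"]["beta"], report["impact"]["la_naive"],
        )
    )
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
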