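"""Binning and the Menzerath's-Law correlation battery.

Menzerath's Law (ML) — "the larger the construct, the smaller its
constituents" — is tested here as a significant negative association
between a protein's secondary-structure count x and the average length y
of those structures.  The battery mirrors the field's standard reporting:
Pearson r, Spearman ρ and the correlation ratio η on per-protein points,
plus Pearson and Spearman on the binned representation.

A *bin* collects all proteins sharing the same x; its pooled mean ȳ is
total residues in secondary structures divided by total segments (not the
mean of per-protein means), and its fitting weight is w = n·x, which is
proportional to the inverse sampling variance of ȳ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .ss_io import ProteinRecord

__all__ = [
    "Bin",
    "CorrelationResult",
    "MLReport",
    "DegenerateDataError",
    "make_bins",
    "pearson_test",
    "spearman_test",
    "correlation_ratio",
    "ml_test_battery",
    "write_bins_tsv",
    "write_ml_report_json",
]

#: Reporting convention for declaring the negative trend significant.
ML_ALPHA = 0.001


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined (e.g. zero variance)."""


@dataclass(frozen=True)
class Bin:
    """All proteins sharing one secondary-structure count x."""

    x: int
    n: int
    total_segments: int
    total_residues: int

    def __post_init__(self) -> None:
        if self.x < 1 or self.n < 1:
            raise ValueError("bins require x >= 1 and n >= 1")
        if self.total_segments != self.n * self.x:
            raise ValueError(f"bin x={self.x}: total_segments {self.total_segments} != n*x {self.n * self.x}")

    @property
    def y_bar(self) -> float:
        """Pooled average segment length (amino acids)."""
        return self.total_residues / self.total_segments

    @property
    def weight(self) -> float:
        """Fitting weight w = n·x."""
        return float(self.n * self.x)


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation estimate with its 95% CI and p-value."""

    statistic_name: str  # pearson_r | spearman_rho | eta
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_points: int
    binned: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"{self.statistic_name}: CI [{self.ci_low}, {self.ci_high}] "
                f"does not contain estimate {self.estimate}"
            )


@dataclass(frozen=True)
class MLReport:
    """The five-statistic battery plus the ML verdict."""

    results: tuple[CorrelationResult, ...]
    ml_not_rejected: bool
    alpha: float = ML_ALPHA


def make_bins(proteins: Sequence[ProteinRecord]) -> list[Bin]:
    """Group proteins by x and pool their segments, ascending in x."""
    if not proteins:
        raise ValueError("cannot bin an empty protein list")
    acc: dict[int, list[int]] = {}
    for p in proteins:
        if p.x < 1:
            raise ValueError(f"{p.accession}: x must be >= 1")
        entry = acc.setdefault(p.x, [0, 0])
        entry[0] += 1
        entry[1] += sum(s.length for s in p.segments)
    return [
        Bin(x=x, n=n, total_segments=n * x, total_residues=residues)
        for x, (n, residues) in sorted(acc.items())
    ]


def _check_pair(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("zero variance in x or y")
    return xa, ya


def pearson_test(x: Sequence[float], y: Sequence[float], *, binned: bool = False) -> CorrelationResult:
    """Pearson product-moment correlation with Fisher-z 95% CI and t-test p."""
    xa, ya = _check_pair(x, y)
    res = stats.pearsonr(xa, ya)
    ci = res.confidence_interval(0.95)
    return CorrelationResult(
        statistic_name="pearson_r",
        estimate=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=float(res.pvalue),
        n_points=xa.size,
        binned=binned,
    )


def _fisher_ci(estimate: float, n: int, sd_scale: float) -> tuple[float, float]:
    # Fisher z interval; sd_scale is the variance multiplier (1.0 Pearson, 1.06 Spearman).
    if n <= 3 or abs(estimate) >= 1.0:
        return -1.0, 1.0
    z = math.atanh(estimate)
    half = stats.norm.ppf(0.975) * math.sqrt(sd_scale / (n - 3))
    return math.tanh(z - half), math.tanh(z + half)


def spearman_test(
    x: Sequence[float],
    y: Sequence[float],
    *,
    binned: bool = False,
    seed: int = 0,
    n_resamples: int = 9999,
) -> CorrelationResult:
    """Spearman rank correlation (midranks for ties).

    The 95% CI uses the Fisher z transform with variance 1.06/(n−3).  The
    p-value uses the t approximation for n > 50 and a seeded permutation
    test (exact for very small n) otherwise.
    """
    xa, ya = _check_pair(x, y)
    res = stats.spearmanr(xa, ya)
    rho = float(res.statistic)
    n = xa.size
    if n > 50:
        p = float(res.pvalue)
    else:
        perm = stats.permutation_test(
            (xa, ya),
            lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=n_resamples,
            alternative="two-sided",
            rng=np.random.default_rng(seed),
        )
        p = float(perm.pvalue)
    lo, hi = _fisher_ci(rho, n, 1.06)
    lo, hi = min(lo, rho), max(hi, rho)
    return CorrelationResult(
        statistic_name="spearman_rho",
        estimate=rho,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_points=n,
        binned=binned,
    )


def _eta_from_arrays(codes: np.ndarray, y: np.ndarray, n_groups: int) -> float:
    grand = y.mean()
    counts = np.bincount(codes, minlength=n_groups)
    sums = np.bincount(codes, weights=y, minlength=n_groups)
    nz = counts > 0
    ss_between = float(np.sum(counts[nz] * (sums[nz] / counts[nz] - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    if ss_total == 0:
        raise DegenerateDataError("zero total variance")
    return math.sqrt(min(ss_between / ss_total, 1.0))


def correlation_ratio(
    groups: Mapping[int, Sequence[float]],
    *,
    n_boot: int = 2000,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation ratio η = √(SS_between / SS_total) with ANOVA F-test p.

    η measures association strength without assuming linearity or even
    monotonicity: η² is the fraction of total variance explained by the
    group (here: distinct x) means.  The 95% CI is a seeded percentile
    bootstrap over observations (``n_boot`` resamples).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    keys = sorted(groups)
    codes = np.concatenate([np.full(len(groups[k]), i) for i, k in enumerate(keys)])
    y = np.concatenate([np.asarray(groups[k], dtype=float) for k in keys])
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0:
        raise DegenerateDataError("zero total variance")
    n_groups = len(keys)
    eta = _eta_from_arrays(codes, y, n_groups)

    # One-way ANOVA F on the same decomposition.
    n = y.size
    df_between = n_groups - 1
    df_within = n - n_groups
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_between = eta**2 * ss_total
    ss_within = ss_total - ss_between
    if df_within <= 0 or ss_within <= 0:
        p = 0.0  # saturated: all variance between groups
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if np.ptp(yb) == 0:
            boot[b] = 0.0
            continue
        boot[b] = _eta_from_arrays(codes[idx], yb, n_groups)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    lo, hi = min(float(lo), eta), max(float(hi), eta)
    return CorrelationResult(
        statistic_name="eta",
        estimate=eta,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n_points=n,
    )


def ml_test_battery(proteins: Sequence[ProteinRecord], *, seed: int = 0) -> MLReport:
    """Run the five-statistic ML battery on a protein dataset.

    Per-protein Pearson r, Spearman ρ and η on (x, y) pairs, plus Pearson
    and Spearman on the binned (x, ȳ) pairs.  ML is declared "not
    rejected" iff both Pearson coefficients are negative and significant
    at the p < 0.001 reporting convention.
    """
    if len(proteins) < 3:
        raise ValueError("need at least 3 proteins")
    x = [p.x for p in proteins]
    y = [p.y for p in proteins]
    if len(set(x)) < 3:
        raise ValueError("need at least 3 distinct x values")
    groups: dict[int, list[float]] = {}
    for p in proteins:
        groups.setdefault(p.x, []).append(p.y)
    bins = make_bins(proteins)
    bx = [b.x for b in bins]
    by = [b.y_bar for b in bins]

    results = (
        pearson_test(x, y),
        spearman_test(x, y, seed=seed),
        correlation_ratio(groups, seed=seed),
        pearson_test(bx, by, binned=True),
        spearman_test(bx, by, binned=True, seed=seed),
    )
    pearsons = [r for r in results if r.statistic_name == "pearson_r"]
    verdict = all(r.estimate < 0 and r.p_value < ML_ALPHA for r in pearsons)
    return MLReport(results=results, ml_not_rejected=verdict)


def write_bins_tsv(bins: Sequence[Bin], path: str | Path) -> None:
    """Write bins as TSV: x, n, total_segments, total_residues, y_bar, weight."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("x\tn\ttotal_segments\ttotal_residues\ty_bar\tweight\n")
        for b in bins:
            fh.write(
                f"{b.x}\t{b.n}\t{b.total_segments}\t{b.total_residues}\t"
                f"{b.y_bar:.6f}\t{b.weight:.1f}\n"
            )


def write_ml_report_json(report: MLReport, path: str | Path) -> None:
    """Write the battery results as JSON."""
    payload = {
        "alpha": report.alpha,
        "ml_not_rejected": report.ml_not_rejected,
        "results": [asdict(r) for r in report.results],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
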