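"""Per-protein outlier detection and location-category enrichment.

Proteins deviating from the fitted MAL curve are flagged by internally
studentized residuals: the raw residual e_i = y_i − ŷ(x_i) divided by
σ̂·√(1 − h_i), where σ̂ is the global dispersion of per-protein residuals
around the curve and h_i is the leverage of the protein's bin in the
weighted fit's hat matrix.  The thresholds are asymmetric: proteins more
than +3 studentized deviations above the curve are outliers, while the
below-curve threshold is relaxed to −2 (symmetric ±3 typically flags
nothing below, because the scale σ̂ is dominated by the extreme
above-curve proteins).

Over-representation of an annotation category among the outliers is then
tested with the exact upper-tail hypergeometric probability

    P(X ≥ x) = Σ_{k=x}^{n} C(M,k)·C(N−M,n−k) / C(N,n)

for x annotated outliers among n outliers, M annotated proteins among N
total, with Bonferroni correction α′ = α/c over the c categories tested.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .mal_models import MODELS, FitResult
from .ss_io import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierRecord",
    "OutlierReport",
    "EnrichmentResult",
    "hat_diagonal",
    "internally_studentized",
    "studentized_residuals",
    "detect_outliers",
    "hypergeom_tail",
    "bonferroni",
    "enrich_categories",
    "write_outliers_tsv",
    "write_enrichment_tsv",
]

UPPER_THRESHOLD = 3.0
LOWER_THRESHOLD = -2.0


@dataclass(frozen=True)
class OutlierRecord:
    """One protein's position relative to the fitted curve."""

    accession: str
    x: int
    y: float
    predicted: float
    residual: float
    studentized: float
    flag: str  # above | below | none


@dataclass(frozen=True)
class OutlierReport:
    """Studentized residuals for every protein, with thresholds used."""

    records: tuple[OutlierRecord, ...]
    upper: float
    lower: float
    sigma_hat: float
    model_id: int

    @property
    def above(self) -> tuple[OutlierRecord, ...]:
        return tuple(r for r in self.records if r.flag == "above")

    @property
    def below(self) -> tuple[OutlierRecord, ...]:
        return tuple(r for r in self.records if r.flag == "below")


def hat_diagonal(J: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Diagonal of the weighted hat matrix W^½ J (JᵀWJ)⁻¹ Jᵀ W^½."""
    Jw = np.sqrt(w)[:, None] * J
    gram_inv = np.linalg.inv(J.T @ (w[:, None] * J))
    return np.einsum("ij,jk,ik->i", Jw, gram_inv, Jw)


def internally_studentized(residuals: np.ndarray, leverages: np.ndarray, df: int) -> np.ndarray:
    """Internally studentized residuals e_i / (σ̂ √(1 − h_i)).

    σ̂² = Σe²/df.  Leverages ≥ 1 yield NaN (reported, not fatal).
    """
    if df < 1:
        raise ValueError("need positive residual degrees of freedom")
    sigma = float(np.sqrt(np.sum(residuals**2) / df))
    out = np.full_like(residuals, np.nan, dtype=float)
    ok = leverages < 1.0
    if sigma > 0:
        out[ok] = residuals[ok] / (sigma * np.sqrt(1.0 - leverages[ok]))
    else:
        out[ok] = 0.0
    return out


def studentized_residuals(
    fit: FitResult,
    proteins: Sequence[ProteinRecord],
    *,
    upper: float = UPPER_THRESHOLD,
    lower: float = LOWER_THRESHOLD,
) -> OutlierReport:
    """Studentize every protein's residual against a bin-fitted curve.

    Leverage is taken from the weighted fit's hat matrix at the protein's
    bin (0 for an x outside the fitted bins, i.e. a prediction treated as
    leverage-free); σ̂ is estimated from the dispersion of *per-protein*
    residuals with n − p degrees of freedom, so individual proteins are
    compared on a common scale regardless of their weight and position on
    the x-axis.
    """
    if not fit.converged:
        raise ValueError("outlier detection requires a converged fit")
    if not proteins:
        raise ValueError("no proteins")
    spec = MODELS[fit.model_id]
    J = spec.jacobian(fit.theta, fit.x)
    h_bin = hat_diagonal(J, fit.w)
    h_by_x = {int(xv): float(h) for xv, h in zip(fit.x, h_bin)}

    xs = np.array([p.x for p in proteins], dtype=float)
    ys = np.array([p.y for p in proteins], dtype=float)
    yhat = spec.predict(fit.theta, xs)
    e = ys - yhat
    h = np.array([h_by_x.get(int(xv), 0.0) for xv in xs])
    df = len(proteins) - fit.p
    t = internally_studentized(e, h, df)
    n_bad = int(np.sum(~np.isfinite(t)))
    if n_bad:
        logger.warning("%d proteins had leverage >= 1; studentized residual undefined", n_bad)

    records = []
    for p_rec, yh, ei, ti in zip(proteins, yhat, e, t):
        if np.isfinite(ti) and ti > upper:
            flag = "above"
        elif np.isfinite(ti) and ti < lower:
            flag = "below"
        else:
            flag = "none"
        records.append(
            OutlierRecord(
                accession=p_rec.accession,
                x=p_rec.x,
                y=float(p_rec.y),
                predicted=float(yh),
                residual=float(ei),
                studentized=float(ti),
                flag=flag,
            )
        )
    sigma = float(np.sqrt(np.sum(e**2) / df))
    return OutlierReport(records=tuple(records), upper=upper, lower=lower, sigma_hat=sigma, model_id=fit.model_id)


def detect_outliers(
    report: OutlierReport,
    *,
    upper: float = UPPER_THRESHOLD,
    lower: float = LOWER_THRESHOLD,
) -> tuple[list[OutlierRecord], list[OutlierRecord]]:
    """Partition the report into (above, below) lists by the thresholds.

    Ordering is deterministic: descending |studentized residual|.
    """
    finite = [r for r in report.records if np.isfinite(r.studentized)]
    above = sorted((r for r in finite if r.studentized > upper), key=lambda r: -abs(r.studentized))
    below = sorted((r for r in finite if r.studentized < lower), key=lambda r: -abs(r.studentized))
    return above, below


def hypergeom_tail(x: int, n: int, M: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X ≥ x).

    Probability that at least ``x`` of ``n`` draws without replacement
    from ``N`` items carry the feature held by ``M`` of them.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= x):
        raise ValueError(f"invalid counts x={x}, n={n}, M={M}, N={N}")
    if x > min(n, M):
        return 0.0
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, M, n))


def bonferroni(alpha: float, c: int) -> float:
    """Bonferroni-corrected significance level α′ = α/c."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not isinstance(c, int) or c < 1:
        raise ValueError(f"c must be a positive integer, got {c!r}")
    return alpha / c


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment verdict for one annotation category."""

    category: str
    N: int
    M: int
    n: int
    x: int
    p_value: float
    alpha_corrected: float
    significant: bool
    direction: str  # over | under


def enrich_categories(
    outliers: Sequence[ProteinRecord],
    dataset: Sequence[ProteinRecord],
    *,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test each location category for over-representation among outliers.

    The test is one-sided (upper tail, over-representation); categories
    rarer among outliers than in the dataset are labelled ``under``
    descriptively but tested in the same tail.  Significance is assessed
    at the Bonferroni level α/c, with c the number of distinct categories
    in the dataset.  Results are sorted by ascending p-value.
    """
    dataset_accessions = {p.accession for p in dataset}
    stray = [o.accession for o in outliers if o.accession not in dataset_accessions]
    if stray:
        raise ValueError(f"outliers not in dataset: {stray[:5]}")
    if not outliers:
        warnings.warn("empty outlier set: no enrichment computed", stacklevel=2)
        return []
    categories = sorted({c for p in dataset for c in p.locations})
    if not categories:
        warnings.warn("dataset carries no location labels", stacklevel=2)
        return []
    c = len(categories)
    alpha_corr = bonferroni(alpha, c)
    N, n = len(dataset), len(outliers)
    dataset_counts = Counter(cat for p in dataset for cat in p.locations)
    outlier_counts = Counter(cat for p in outliers for cat in p.locations)
    results = []
    for cat in categories:
        M = dataset_counts[cat]
        x = outlier_counts.get(cat, 0)
        p_val = hypergeom_tail(x, n, M, N)
        direction = "over" if x / n >= M / N else "under"
        results.append(
            EnrichmentResult(
                category=cat,
                N=N,
                M=M,
                n=n,
                x=x,
                p_value=p_val,
                alpha_corrected=alpha_corr,
                significant=p_val < alpha_corr,
                direction=direction,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.category))
    return results


def write_outliers_tsv(report: OutlierReport, path: str | Path) -> None:
    """Write the per-protein outlier report as TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("accession\tx\ty\tpredicted\tresidual\tstudentized\tflag\n")
        for r in report.records:
            fh.write(
                f"{r.accession}\t{r.x}\t{r.y:.6f}\t{r.predicted:.6f}\t"
                f"{r.residual:.6f}\t{r.studentized:.6f}\t{r.flag}\n"
            )


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    """Write enrichment results as TSV, sorted as given."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category\tN\tM\tn\tx\tp_value\talpha_corrected\tsignificant\tdirection\n")
        for r in results:
            fh.write(
                f"{r.category}\t{r.N}\t{r.M}\t{r.n}\t{r.x}\t{r.p_value:.6e}\t"
                f"{r.alpha_corrected:.6e}\t{str(r.significant).lower()}\t{r.direction}\n"
            )
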