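"""Synthetic protein datasets with the statistical structure the analysis assumes.

The generator emulates the features of a curated structural dataset that
the downstream pipeline relies on, without any remote resources:

* a right-skewed distribution of secondary-structure counts x on
  [1, 142] (most proteins have few structures, a long tail has many);
* segment lengths whose conditional mean follows a chosen MAL formula
  (default: model 4 with a ≈ 11, d ≈ 7, the minimal-structure-length
  form), with integer lengths ≥ 1 drawn as 1 + Poisson(mean − 1);
* a flat vocabulary of ~211 subcellular-location labels;
* optionally, planted outlier proteins (segment means inflated by a
  multiplier) and one planted enriched category occurring at different
  rates among outliers and background — the ground truth for power and
  recovery experiments, reported by :func:`truth_report`.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .binning_stats import Bin
from .mal_models import eval_model
from .ss_io import CoverageRecord, ProteinRecord, SegmentKind, SSegment, min_required_observed

__all__ = [
    "SyntheticConfig",
    "EnrichedCategory",
    "TruthReport",
    "generate_dataset",
    "generate_dataset_with_truth",
    "generate_coverage_records",
    "simulate_bins",
    "truth_report",
    "write_truth_json",
]


@dataclass(frozen=True)
class EnrichedCategory:
    """A location label planted at different rates in outliers vs background."""

    name: str
    background_rate: float
    outlier_rate: float

    def __post_init__(self) -> None:
        for r in (self.background_rate, self.outlier_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rates must be in [0, 1], got {r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_proteins: int = 5000
    x_max: int = 142
    zipf_exponent: float = 1.5  # right-skewed x: P(x) ∝ x^(−zipf_exponent)
    model_id: int = 4
    params: dict = field(default_factory=lambda: {"a": 11.0, "d": 7.0})
    noise: str = "poisson"  # poisson | constant | lognormal
    lognormal_sigma: float = 0.35
    outlier_fraction: float = 0.0
    outlier_inflation: float = 3.0
    n_categories: int = 211
    enriched: EnrichedCategory | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.x_max < 1:
            raise ValueError("n_proteins and x_max must be positive")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.outlier_inflation <= 0:
            raise ValueError("outlier_inflation must be positive")
        if self.noise not in ("poisson", "constant", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        means = [float(eval_model(self.model_id, self.params, x)) for x in (1, self.x_max)]
        if any(m <= 0 for m in means):
            raise ValueError("config produces non-positive mean segment lengths")


@dataclass(frozen=True)
class TruthReport:
    """Generating truth for use as a test oracle."""

    model_id: int
    params: dict
    noise: str
    planted_outliers: tuple[str, ...]
    enriched_category: str | None
    seed: int
    n_proteins: int


def _draw_x(rng: np.random.Generator, n: int, x_max: int, exponent: float) -> np.ndarray:
    support = np.arange(1, x_max + 1, dtype=float)
    probs = support**-exponent
    probs /= probs.sum()
    return rng.choice(np.arange(1, x_max + 1), size=n, p=probs)


def _segment_lengths(rng: np.random.Generator, mean: float, count: int, noise: str, ln_sigma: float) -> np.ndarray:
    """Integer segment lengths ≥ 1 with the requested conditional mean."""
    if noise == "constant":
        return np.full(count, max(int(round(mean)), 1))
    if noise == "poisson":
        lam = max(mean - 1.0, 0.0)
        return 1 + rng.poisson(lam, count)
    # lognormal with matched mean, rounded and floored at 1
    mu = np.log(max(mean, 1e-9)) - 0.5 * ln_sigma**2
    draws = np.round(rng.lognormal(mu, ln_sigma, count)).astype(int)
    return np.maximum(draws, 1)


def _generate(config: SyntheticConfig) -> tuple[list[ProteinRecord], TruthReport]:
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    xs = _draw_x(rng, n, config.x_max, config.zipf_exponent)
    is_outlier = rng.random(n) < config.outlier_fraction

    cat_probs = np.arange(1.0, config.n_categories + 1.0) ** -1.0
    cat_probs /= cat_probs.sum()
    width = len(str(config.n_categories))
    base_cats = rng.choice(config.n_categories, size=n, p=cat_probs)
    if config.enriched is not None:
        rates = np.where(is_outlier, config.enriched.outlier_rate, config.enriched.background_rate)
        has_enriched = rng.random(n) < rates
    else:
        has_enriched = np.zeros(n, dtype=bool)

    # Conditional mean length per protein, memoised over the x support.
    mean_by_x = {x: float(eval_model(config.model_id, config.params, x)) for x in np.unique(xs)}

    records: list[ProteinRecord] = []
    planted: list[str] = []
    for i in range(n):
        x = int(xs[i])
        accession = f"SYN{i:06d}"
        mean = mean_by_x[x]
        if is_outlier[i]:
            mean *= config.outlier_inflation
            planted.append(accession)
        lengths = _segment_lengths(rng, mean, x, config.noise, config.lognormal_sigma)
        kinds = rng.random(x) < 0.5
        segments = tuple(
            SSegment(SegmentKind.HELIX if k else SegmentKind.STRAND, int(length))
            for k, length in zip(kinds, lengths)
        )
        locations = {f"loc_{int(base_cats[i]) + 1:0{width}d}"}
        if has_enriched[i]:
            locations.add(config.enriched.name)  # type: ignore[union-attr]
        total = int(lengths.sum())
        # Sequence length: segments plus realistic loop/terminal slack.
        seq_length = total + int(rng.integers(2, max(3, total // 2)))
        records.append(
            ProteinRecord(
                accession=accession,
                seq_length=seq_length,
                segments=segments,
                locations=frozenset(locations),
            )
        )
    truth = TruthReport(
        model_id=config.model_id,
        params=dict(config.params),
        noise=config.noise,
        planted_outliers=tuple(planted),
        enriched_category=config.enriched.name if config.enriched else None,
        seed=config.seed,
        n_proteins=config.n_proteins,
    )
    return records, truth


def generate_dataset(config: SyntheticConfig) -> list[ProteinRecord]:
    """Generate one synthetic protein dataset (deterministic in the seed)."""
    return _generate(config)[0]


def generate_dataset_with_truth(config: SyntheticConfig) -> tuple[list[ProteinRecord], TruthReport]:
    """Generate a dataset together with its ground truth in one draw."""
    return _generate(config)


def truth_report(config: SyntheticConfig) -> TruthReport:
    """The generating truth for ``config`` (same draw as generate_dataset)."""
    return _generate(config)[1]


def generate_coverage_records(
    n: int, seed: int = 0
) -> list[tuple[CoverageRecord, bool]]:
    """Coverage records with known pass/fail labels for filter testing.

    The first entries are forced boundary cases: sequence lengths 14, 33
    and 75 observed exactly at the admission threshold (pass) and one
    residue short of it (fail); the remainder is a random mixture with
    labels derived from the same rule used to construct each interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[CoverageRecord, bool]] = []
    boundaries = []
    for L in (14, 33, 75):
        need = min_required_observed(L)
        boundaries.append((L, need, True))
        if need > 1:
            boundaries.append((L, need - 1, False))
    for i, (L, observed, label) in enumerate(boundaries[: n]):
        start = 1 if observed == L else int(rng.integers(1, L - observed + 2))
        out.append(
            (
                CoverageRecord(
                    accession=f"COV{i:06d}",
                    seq_length=L,
                    observed_start=start,
                    observed_end=start + observed - 1,
                ),
                label,
            )
        )
    for i in range(len(out), n):
        L = int(rng.integers(7, 2128))
        # concentrate observed fractions around the 95% boundary so both
        # outcomes are well represented
        lo = max(1, int(0.85 * L))
        observed = int(rng.integers(lo, L + 1))
        start = int(rng.integers(1, L - observed + 2))
        rec = CoverageRecord(
            accession=f"COV{i:06d}",
            seq_length=L,
            observed_start=start,
            observed_end=start + observed - 1,
        )
        out.append((rec, observed >= min_required_observed(L)))
    return out


def simulate_bins(
    model_id: int,
    params: dict,
    *,
    n_bins: int = 100,
    sigma: float = 1.0,
    seed: int = 0,
    n_per_bin: Sequence[int] | None = None,
) -> list[Bin]:
    """Bins whose means follow a MAL formula plus noise of sd σ/√wⱼ.

    A direct bin-level simulator for parameter-recovery experiments: bin
    j has x = j, population count n_j (right-skewed by default), weight
    w = n·x, and observed mean ȳⱼ = f(xⱼ) + εⱼ with εⱼ ~ N(0, σ²/wⱼ) —
    the heteroscedastic structure the w = n·x weighting assumes.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(1, n_bins + 1)
    if n_per_bin is None:
        n_arr = np.maximum((800 / x**1.2).astype(int), 2)
    else:
        n_arr = np.asarray(n_per_bin, dtype=int)
        if n_arr.shape != (n_bins,):
            raise ValueError("n_per_bin must have one entry per bin")
    w = n_arr * x
    mean = np.asarray(eval_model(model_id, params, x.astype(float)))
    y = mean + rng.normal(0.0, sigma / np.sqrt(w))
    if np.any(y <= 0):
        raise ValueError("simulated bin means must be positive; lower sigma")
    bins = []
    for xj, nj, yj in zip(x, n_arr, y):
        total_segments = int(nj * xj)
        # Encode the noisy mean through integer total_residues at high resolution.
        bins.append(
            _FractionalBin(
                x=int(xj), n=int(nj), total_segments=total_segments, total_residues=1, _y_bar=float(yj)
            )
        )
    return bins


@dataclass(frozen=True)
class _FractionalBin(Bin):
    """A Bin carrying a real-valued mean (for bin-level simulation only)."""

    _y_bar: float = 1.0

    @property
    def y_bar(self) -> float:  # type: ignore[override]
        return self._y_bar


def write_truth_json(truth: TruthReport, path: str | Path) -> None:
    """Write the generating truth as JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(truth), fh, indent=2, sort_keys=True)
        fh.write("\n")
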