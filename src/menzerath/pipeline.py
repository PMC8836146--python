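"""End-to-end pipeline: filter → bin → ML test → fit → outliers → enrichment.

One :func:`run_pipeline` call executes the stages in order on a protein
table (optionally admission-filtered by a coverage table), writing

* ``bins.tsv`` — the binned (x, ȳ, w) representation,
* ``ml_report.json`` — the five-statistic Menzerath's-Law battery,
* ``fits.json`` — per-formula NWLS fits and the s/AIC ranking,
* ``outliers.tsv`` — per-protein studentized residuals and flags,
* ``enrichment.tsv`` — location-category enrichment among outliers,
* ``manifest.json`` — config hash, seed, stage record counts and output
  checksums.  The manifest contains no volatile fields, so identical
  inputs, config and seed reproduce it byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .binning_stats import make_bins, ml_test_battery, write_bins_tsv, write_ml_report_json
from .mal_models import compare_models, fit_nwls, write_fits_json
from .outlier_enrichment import (
    detect_outliers,
    enrich_categories,
    studentized_residuals,
    write_enrichment_tsv,
    write_outliers_tsv,
)
from .ss_io import filter_by_coverage, read_coverage_table, read_protein_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records which."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    protein_table: str
    outdir: str
    coverage_table: str | None = None
    models: tuple[int, ...] = (1, 2, 3, 4, 5)
    weighted: bool = True
    outlier_model: int | None = None  # default: best by AIC
    upper: float = 3.0
    lower: float = -2.0
    alpha: float = 0.05
    seed: int = 0
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        for t in (self.upper, self.lower):
            if not (t == t and abs(t) < float("inf")):
                raise ValueError("thresholds must be finite")
        unknown = set(self.models) - {1, 2, 3, 4, 5}
        if unknown:
            raise ValueError(f"unknown model ids: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    protein_path = Path(config.protein_table)
    if not protein_path.exists():
        raise PipelineError(f"protein table not found: {protein_path}")
    coverage_path = Path(config.coverage_table) if config.coverage_table else None
    if coverage_path is not None and not coverage_path.exists():
        raise PipelineError(f"coverage table not found: {coverage_path}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "failed_stage": None,
    }

    def _finish(stage: str, exc: Exception) -> PipelineError:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return PipelineError(f"stage {stage!r} failed: {exc}")

    # Stage: read + admission filter
    try:
        parsed = read_protein_table(protein_path)
        proteins = parsed.records
        n_in = len(proteins) + parsed.n_zero_segment
        if coverage_path is not None:
            coverage = read_coverage_table(coverage_path)
            proteins, dropped = filter_by_coverage(proteins, coverage)
            n_dropped = len(dropped)
        else:
            n_dropped = 0
        manifest["stages"]["filter"] = {
            "proteins_in": n_in,
            "zero_segment_excluded": parsed.n_zero_segment,
            "ignored_segment_tokens": parsed.n_ignored_segments,
            "coverage_rejected": n_dropped,
            "proteins_admitted": len(proteins),
        }
        if not proteins:
            raise ValueError("no proteins admitted")
    except Exception as exc:  # noqa: BLE001 - manifest must record the stage
        raise _finish("filter", exc) from exc

    # Stage: binning
    try:
        bins = make_bins(proteins)
        write_bins_tsv(bins, outdir / "bins.tsv")
        manifest["stages"]["bins"] = {"n_bins": len(bins), "members": sum(b.n for b in bins)}
    except Exception as exc:  # noqa: BLE001
        raise _finish("bins", exc) from exc

    # Stage: Menzerath's-Law correlation battery
    try:
        battery = ml_test_battery(proteins, seed=config.seed)
        write_ml_report_json(battery, outdir / "ml_report.json")
        manifest["stages"]["ml_test"] = {"ml_not_rejected": battery.ml_not_rejected}
    except Exception as exc:  # noqa: BLE001
        raise _finish("ml_test", exc) from exc

    # Stage: formula fitting and comparison
    try:
        fits = [
            fit_nwls(m, bins, weighted=config.weighted, seed=config.seed, n_restarts=config.n_restarts)
            for m in config.models
        ]
        write_fits_json(fits, outdir / "fits.json")
        ranking = compare_models(fits) if len(fits) > 1 else None
        manifest["stages"]["fit"] = {
            "models": list(config.models),
            "weighted": config.weighted,
            "by_aic_worst_to_best": list(ranking.by_aic) if ranking else list(config.models),
        }
    except Exception as exc:  # noqa: BLE001
        raise _finish("fit", exc) from exc

    # Stage: outlier detection
    try:
        if config.outlier_model is not None:
            chosen = next(f for f in fits if f.model_id == config.outlier_model)
        else:
            chosen = min(fits, key=lambda f: f.aic)
        report = studentized_residuals(chosen, proteins, upper=config.upper, lower=config.lower)
        write_outliers_tsv(report, outdir / "outliers.tsv")
        above, below = detect_outliers(report, upper=config.upper, lower=config.lower)
        manifest["stages"]["outliers"] = {
            "model_id": chosen.model_id,
            "n_above": len(above),
            "n_below": len(below),
        }
    except Exception as exc:  # noqa: BLE001
        raise _finish("outliers", exc) from exc

    # Stage: enrichment of above-model outliers
    try:
        accessions = {r.accession for r in above}
        outlier_recs = [p for p in proteins if p.accession in accessions]
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            enrichment = enrich_categories(outlier_recs, proteins, alpha=config.alpha)
        write_enrichment_tsv(enrichment, outdir / "enrichment.tsv")
        manifest["stages"]["enrich"] = {
            "n_categories": len(enrichment),
            "n_significant": sum(r.significant for r in enrichment),
        }
    except Exception as exc:  # noqa: BLE001
        raise _finish("enrich", exc) from exc

    for name in ("bins.tsv", "ml_report.json", "fits.json", "outliers.tsv", "enrichment.tsv"):
        manifest["outputs"][name] = _sha256(outdir / name)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def render_report(outdir: str | Path) -> str:
    """Human-readable summary of a completed run, from its own outputs."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {outdir}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "Menzerath-Altmann analysis report",
        "=" * 34,
        f"package version : {manifest.get('package_version')}",
        f"config hash     : {manifest.get('config_hash')}",
        f"seed            : {manifest.get('seed')}",
        "",
    ]
    if manifest.get("failed_stage"):
        lines.append(f"WARNING: run failed at stage {manifest['failed_stage']!r}; report is partial.")
    stages = manifest.get("stages", {})
    if "filter" in stages:
        st = stages["filter"]
        lines += [
            "Admission funnel",
            f"  proteins in table        : {st['proteins_in']}",
            f"  zero-segment excluded    : {st['zero_segment_excluded']}",
            f"  coverage-filter rejected : {st['coverage_rejected']}",
            f"  admitted to analysis     : {st['proteins_admitted']}",
            "",
        ]
    ml_path = outdir / "ml_report.json"
    if ml_path.exists():
        ml = json.loads(ml_path.read_text())
        lines.append("Menzerath's Law battery (estimate [95% CI], p)")
        for r in ml["results"]:
            label = ("(binned) " if r["binned"] else "") + r["statistic_name"]
            lines.append(
                f"  {label:24s} {r['estimate']: .3f} "
                f"[{r['ci_low']: .3f}, {r['ci_high']: .3f}]  p={r['p_value']:.3g}"
            )
        lines.append(f"  ML not rejected: {ml['ml_not_rejected']}")
        lines.append("")
    fits_path = outdir / "fits.json"
    if fits_path.exists():
        fits = json.loads(fits_path.read_text())
        lines.append("Formula fits (parameter (SE); s; AIC)")
        for f in fits["fits"]:
            params = ", ".join(
                f"{k}={v:.3f} (±{f['std_errors'][k]:.3f})" for k, v in sorted(f["estimates"].items())
            )
            lines.append(f"  model {f['model_id']}: {params}; s={f['s']:.3f}; AIC={f['aic']:.1f}")
        if fits.get("ranking"):
            lines.append(f"  worst→best by s   : {fits['ranking']['by_s_worst_to_best']}")
            lines.append(f"  worst→best by AIC : {fits['ranking']['by_aic_worst_to_best']}")
        lines.append("")
    if "outliers" in stages:
        st = stages["outliers"]
        lines += [
            f"Outliers vs model {st['model_id']}: {st['n_above']} above (+3), {st['n_below']} below (−2)",
        ]
        if st["n_above"] == 0:
            lines.append("  no outliers: enrichment not informative")
    if "enrich" in stages:
        st = stages["enrich"]
        lines.append(
            f"Enrichment: {st['n_significant']} of {st['n_categories']} categories significant after Bonferroni"
        )
    return "\n".join(lines) + "\n"
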