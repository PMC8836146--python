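"""Test Menzerath's Law: is the secondary-structure count negatively
associated with the average structure length?

Bins the simulated proteins by their structure count and runs the
five-statistic battery (Pearson, Spearman, correlation ratio η on
per-protein points; Pearson and Spearman on the binned means).
"""

from pathlib import Path

from menzerath.binning_stats import make_bins, ml_test_battery, write_bins_tsv, write_ml_report_json
from menzerath.ss_io import read_protein_table

DATA = Path("results/data")
OUT = Path("results/tables")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    proteins = read_protein_table(DATA / "proteins.tsv").records
    bins = make_bins(proteins)
    write_bins_tsv(bins, OUT / "bins.tsv")
    report = ml_test_battery(proteins, seed=SEED)
    write_ml_report_json(report, OUT / "ml_report.json")

    print(f"{len(proteins)} proteins in {len(bins)} bins "
          f"(binned means {min(b.y_bar for b in bins):.1f}-{max(b.y_bar for b in bins):.1f} AA)")
    print(f"{'statistic':26s} {'estimate':>9s} {'95% CI':>20s} {'p':>10s}")
    for r in report.results:
        label = ("(binned) " if r.binned else "") + r.statistic_name
        print(f"{label:26s} {r.estimate:9.3f} [{r.ci_low: .3f}, {r.ci_high: .3f}]  {r.p_value:9.2e}")
    verdict = "not rejected" if report.ml_not_rejected else "rejected"
    print(f"Menzerath's Law (negative trend at p < {report.alpha}): {verdict}")


if __name__ == "__main__":
    main()
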