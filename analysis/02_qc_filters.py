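#!/usr/bin/env python
"""Apply the per-SNP QC filters to the synthetic panel.

Reads results/sim/panel.{ped,map} back through the pedigree reader (so
the full file path is exercised), applies the no-call / Mendelian-error /
MAF / Hardy-Weinberg filters at their default thresholds, and writes
results/qc_report.tsv.
"""

from pathlib import Path

from poescan import qc_filter
from poescan.pedio import read_annotation, read_ped

ROOT = Path(__file__).resolve().parent.parent / "results"
PANEL = Path(__file__).resolve().parent.parent / "scratch" / "sim"


def main() -> None:
    annotation = read_annotation(PANEL / "panel.annot.tsv")
    panel = read_ped(
        PANEL / "panel.ped", PANEL / "panel.map",
        annotation=annotation,
    )
    passed, report = qc_filter(panel)
    report.to_csv(ROOT / "qc_report.tsv", sep="\t", index=False)
    n_fail = int((~report["pass"]).sum())
    print(f"{passed.n_snps}/{panel.n_snps} SNPs pass QC ({n_fail} excluded)")
    if n_fail:
        failed = report.loc[~report["pass"], ["snp_id", "fail_reasons"]]
        print(failed.to_string(index=False))
    print(f"wrote {ROOT}/qc_report.tsv")


if __name__ == "__main__":
    main()
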