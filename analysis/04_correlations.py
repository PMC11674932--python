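"""Run the partial-correlation battery on the harmonized cohort.

Three Bonferroni-corrected families: (a) inter- vs intrahemispheric
measure pairs in HC and patients separately — the conservation-principle
check (a negative commissural-vs-efficiency and positive
commissural-vs-SPL correlation is the conservation signature); (b)
agreement between the two interhemispheric measures; (c) measures and
inter/intra ratios against GMF/WMF/LVF/EDSS/SDMT in patients.
"""

import argparse
from pathlib import Path

import pandas as pd

from hemiconn.pipeline import PipelineConfig, _annotated_csv, read_annotated_csv
from hemiconn.stats import battery_report, run_correlation_battery


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    h_metrics = read_annotated_csv(args.outdir / "harmonized_metrics.csv",
                                   index_col="id")
    h_records = read_annotated_csv(args.outdir / "harmonized_records.csv",
                                   index_col="id")
    results = run_correlation_battery(h_metrics, h_records)

    _annotated_csv(pd.DataFrame([r.as_dict() for r in results]),
                   args.outdir / "correlations.csv", PipelineConfig(),
                   index=False)
    report = battery_report(results)
    (args.outdir / "report.txt").write_text(report)
    print(report)


if __name__ == "__main__":
    main()
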