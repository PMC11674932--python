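"""Compute the four hemispheric connectivity measures per subject.

Chain per subject: divide weights by fiber length, keep cortical regions,
take the commissural ratio from the raw streamline counts, invert the
normalized weights into distances, and compute per-hemisphere mean
shortest path length and efficiency plus the four inter/intra ratios.
"""

import argparse
from pathlib import Path

from hemiconn.pipeline import (PipelineConfig, _annotated_csv,
                               compute_metrics_table, read_cohort)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/metrics.csv"))
    args = ap.parse_args()

    connectomes, records, _ = read_cohort(args.data)
    table = compute_metrics_table(connectomes, records)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    _annotated_csv(table, args.out, PipelineConfig())

    print(f"metrics for {len(table)} subjects -> {args.out}")
    for col in ("commissural_ratio", "cc_ratio", "spl_mean", "eff_mean"):
        print(f"  {col:20s} {table[col].mean():.4g} +/- {table[col].std():.3g}")


if __name__ == "__main__":
    main()
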