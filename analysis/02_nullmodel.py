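"""Subsampling variability: the null model and field-vs-lab comparison.

For each paired sample the total count is re-subsampled 1000 times to the
median of the field/lab counts; field and lab subsamples are scored with
the relative taxon-deviation statistic against the null mean.  Reports the
pooled mean absolute deviation for each method (all taxa and taxa above 5%
null relative abundance), the paired t-test on per-sample means, and the
correlation of deviation with subsample count.

Reads results/data/pairs.csv; writes deviations.csv and
nullmodel_summary.json under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from streamcits import io as sio
from streamcits.nullmodel import (
    deviation_table,
    deviation_vs_count_correlation,
    median_target,
    paired_t_test,
    per_sample_means,
    resample_null,
    summarize_deviation,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--replicates", type=int, default=1000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    pairs = sio.read_paired_samples(args.data / "pairs.csv")
    rng = np.random.default_rng(args.seed)

    rows, field_tables, lab_tables, field_counts = [], [], [], []
    for s in pairs:
        m = median_target(s.field_total, s.lab_total)
        null = resample_null(s.total_counts, m, args.replicates, rng)
        ft = deviation_table(s.field_counts, null, s.sample_id)
        lt = deviation_table(s.lab_counts, null, s.sample_id)
        field_tables.append(ft)
        lab_tables.append(lt)
        field_counts.append(s.field_total)
        for method, table in (("field", ft), ("lab", lt)):
            for fam, dev in table.signed_deviation.items():
                rows.append((s.sample_id, s.stream, method, fam, dev, abs(dev)))

    pd.DataFrame(
        rows, columns=["sample_id", "stream", "method", "family", "signed", "absolute"]
    ).to_csv(args.out / "deviations.csv", index=False)

    summary = {"replicates": args.replicates, "seed": args.seed, "n_pairs": len(pairs)}
    for label, flt in (("all_taxa", 0.0), ("above_5pct", 0.05)):
        f_mean, f_sd, f_n = summarize_deviation(field_tables, flt)
        l_mean, l_sd, l_n = summarize_deviation(lab_tables, flt)
        t, df, p = paired_t_test(
            per_sample_means(field_tables, flt), per_sample_means(lab_tables, flt)
        )
        summary[label] = {
            "field": {"mean": f_mean, "sd": f_sd, "n": f_n},
            "lab": {"mean": l_mean, "sd": l_sd, "n": l_n},
            "paired_t": {"t": t, "df": df, "p": p},
        }
        print(
            f"[{label}] field {100*f_mean:.0f}% (SD {100*f_sd:.0f}%)  "
            f"lab {100*l_mean:.0f}% (SD {100*l_sd:.0f}%)  "
            f"paired t = {t:.2f}, df = {df}, p = {p:.3g}"
        )

    r = deviation_vs_count_correlation(field_tables, field_counts)
    summary["deviation_vs_count_r"] = r
    print(f"field deviation vs subsample count: Pearson R = {r:.2f}")
    (args.out / "nullmodel_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
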