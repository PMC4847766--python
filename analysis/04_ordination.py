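"""Assemblage structure: NMDS ordinations, ANOSIM, and field/lab PROTEST.

Ordinations of event-level relative abundance (Bray-Curtis, 2-D NMDS) are
tested for stream separation (ANOSIM across all events) and seasonal
separation within each stream.  The paired field/lab samples are ordinated
separately and superimposed with Procrustes; PROTEST gives the
significance of their concordance.

Writes nmds_coordinates.csv and ordination_summary.json under results/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from streamcits import io as sio
from streamcits.ordination import (
    AbundanceMatrix,
    anosim,
    axis_variance,
    bray_curtis,
    counts_to_matrix,
    nmds,
    protest,
    relative_abundance_matrix,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=4)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--permutations", type=int, default=999)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    dataset = sio.read_survey(args.data / "survey.csv")
    matrix = relative_abundance_matrix(dataset)
    dist = bray_curtis(matrix)
    ordn = nmds(dist, seed=rng)
    av = axis_variance(dist, ordn)

    coords = pd.DataFrame(ordn.coordinates, index=ordn.ids, columns=["axis1", "axis2"])
    coords = coords.join(matrix.labels)
    coords.to_csv(args.out / "nmds_coordinates.csv")

    summary = {
        "stress": ordn.stress,
        "axis_variance": list(av),
        "seed": args.seed,
    }
    res = anosim(dist, matrix.labels["stream"].to_numpy(), args.permutations, rng)
    summary["anosim_streams"] = {"R": res.R, "p": res.p}
    print(f"streams: ANOSIM R = {res.R:.2f}, p = {res.p:.3g} "
          f"(stress {ordn.stress:.3f}, axis variance {av.round(2).tolist()})")

    for stream in dataset.streams:
        sub = matrix.labels["stream"] == stream
        ids = matrix.labels.index[sub]
        m = AbundanceMatrix(data=matrix.data.loc[ids], labels=matrix.labels.loc[ids])
        d = bray_curtis(m)
        res = anosim(d, m.labels["season"].to_numpy(), args.permutations, rng)
        summary[f"anosim_seasons_{stream}"] = {"R": res.R, "p": res.p}
        print(f"{stream} seasons: ANOSIM R = {res.R:.2f}, p = {res.p:.3g}")

    # paired field vs lab ordinations
    pairs = sio.read_paired_samples(args.data / "pairs.csv")
    field = {s.sample_id: s.field_counts for s in pairs}
    lab = {s.sample_id: s.lab_counts for s in pairs}
    mf, ml = counts_to_matrix(field), counts_to_matrix(lab)
    ml = AbundanceMatrix(
        data=ml.data.reindex(columns=mf.data.columns, fill_value=0.0), labels=ml.labels
    )
    of = nmds(bray_curtis(mf), seed=rng)
    ol = nmds(bray_curtis(ml), seed=rng)
    res = protest(of.coordinates, ol.coordinates, args.permutations, rng)
    summary["protest_field_vs_lab"] = {
        "m2": res.m2, "concordance": res.concordance, "p": res.p,
    }
    print(
        f"field vs lab ordinations: concordance {res.concordance:.2f} "
        f"(m2 = {res.m2:.2f}), PROTEST p = {res.p:.3g}"
    )
    (args.out / "ordination_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
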