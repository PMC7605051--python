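#!/usr/bin/env python
"""Group-level frequentist statistics.

Reads results/responses.csv and results/classification.csv, then computes per
classified group: the one-way ANOVA of %convex over disparity, per-level t
tests against chance, near/far coupling t tests, the paired near-vs-far test,
and the far-coupling-vs-depth-perception regression in the stereoscopic group.
Writes results/group_stats.json and results/subject_summaries.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from stereocoupling.groupstats import group_analysis, summarize_cohort
from stereocoupling.io import read_responses, write_json


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    responses = read_responses(args.outdir / "responses.csv")
    cls = pd.read_csv(args.outdir / "classification.csv", dtype={"subject_id": str})
    groups = dict(zip(cls["subject_id"], cls["group"]))
    summaries = summarize_cohort(responses)
    stats = group_analysis(summaries, groups)

    for label, g in stats["groups"].items():
        print(f"\n== {label} (n={g['n']}) ==")
        a = g["anova_disparity"]
        print(f"ANOVA over disparity: F{tuple(a['df'])} = {a['statistic']:.2f}, p = {a['p_value']:.3g}")
        for key in ("coupling_near_vs_chance", "coupling_far_vs_chance", "coupling_near_vs_far"):
            t = g[key]
            if "error" in t:
                print(f"{key}: {t['error']}")
            else:
                print(f"{key}: t({t['df']}) = {t['statistic']:.2f}, p = {t['p_value']:.3g}")
        if "far_coupling_vs_depth_fit" in g and "error" not in g["far_coupling_vs_depth_fit"]:
            f = g["far_coupling_vs_depth_fit"]
            print(f"far coupling vs depth perception: r = {f['r']:.2f}, "
                  f"SSE = {f['sse']:.2f}, df = {f['df']}")

    write_json(stats, args.outdir / "group_stats.json")
    pd.DataFrame(
        [
            {"subject_id": s.subject_id, "group": groups.get(s.subject_id),
             **{f"pct_convex_{lv:g}": p for lv, p in sorted(s.pct_convex_by_level.items())},
             "pct_coupling_near": s.pct_coupling_near,
             "pct_coupling_far": s.pct_coupling_far,
             "depth_perception": None if s.incomplete else s.depth_perception}
            for s in summaries.values()
        ]
    ).to_csv(args.outdir / "subject_summaries.csv", index=False)
    print(f"\nwrote {args.outdir / 'group_stats.json'} and {args.outdir / 'subject_summaries.csv'}")


if __name__ == "__main__":
    main()
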