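"""Design-weighted descriptive tables from the simulated survey records.

Reads results/survey/women.csv and writes, under results/tables/:
background characteristics (weighted percents per factor level), coverage and
method mix by subgroup, nearest-SDP distance summaries by region, and the
coverage-gap (disparity) contrasts between extreme subgroups.
"""

from pathlib import Path

import pandas as pd

from geocontracep import geodata, survey

IN = Path("results/survey/women.csv")
OUT = Path("results/tables")


def main() -> None:
    women = geodata.read_records(IN)
    OUT.mkdir(parents=True, exist_ok=True)

    bg = survey.background_table(women)
    bg.to_csv(OUT / "background.csv", index=False)

    mix = survey.method_mix_table(women)
    for factor in ("age_group", "education", "wealth", "sdp_distance",
                   "partner_discussion", "residence", "region"):
        mix = pd.concat([mix, survey.method_mix_table(women, by=factor)],
                        ignore_index=True)
    mix.to_csv(OUT / "method_mix.csv", index=False)

    dist = survey.distance_summary_table(women)
    dist.to_csv(OUT / "distance_by_region.csv", index=False)

    rows = []
    for factor, hi, lo in (("wealth", "high", "low"),
                           ("sdp_distance", "le2km", "gt6km"),
                           ("education", "secondary+", "never"),
                           ("residence", "urban", "rural")):
        rows.append(survey.coverage_disparity(women, factor, hi, lo, seed=0))
    pd.DataFrame(rows).to_csv(OUT / "disparity.csv", index=False)

    total = mix.iloc[0]
    print(f"{len(women)} records; coverage {total['mcp_percent']:.1f}% "
          f"(injectable {total['injectable_percent']:.1f}, implant "
          f"{total['implant_percent']:.1f}, pill {total['pill_percent']:.1f}, "
          f"other {total['other_percent']:.1f})")
    nat = dist[dist["region"] == "total"].iloc[0]
    print(f"nearest SDP: mean {nat['mean']:.2f} km, median {nat['median']:.2f} km; "
          f"{nat['pct_le2km']:.1f}% within 2 km, {nat['pct_gt6km']:.1f}% beyond 6 km")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
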