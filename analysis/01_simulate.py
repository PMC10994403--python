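"""Generate the default synthetic survey realization and write its records.

Produces results/survey/{women.csv,sdps.csv}: ~265 enumeration areas, ~4,400
women in need of contraception with socio-demographic covariates and design
weights, and 799 point-located service delivery points.
"""

from pathlib import Path

from geocontracep import geodata
from geocontracep.survey import weighted_proportion
from geocontracep.synthetic import SimConfig, generate_survey

OUT = Path("results/survey")


def main(seed: int = 0) -> None:
    cfg = SimConfig(seed=seed)
    real = generate_survey(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    geodata.write_records(real.women, OUT / "women.csv")
    geodata.write_sdps(real.sdps, OUT / "sdps.csv")
    est = weighted_proportion(real.women)
    print(f"realization seed={seed}: {len(real.women)} women in need across "
          f"{len(real.ea_centroids)} EAs, {len(real.sdps)} SDPs")
    print(f"weighted modern-use coverage {est.estimate*100:.1f}% "
          f"(95% CI {est.ci_low*100:.1f}-{est.ci_high*100:.1f})")
    print(f"wrote {OUT/'women.csv'} and {OUT/'sdps.csv'}")


if __name__ == "__main__":
    main()
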