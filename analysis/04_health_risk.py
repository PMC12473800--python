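#!/usr/bin/env python
"""Human health risk for child and adult receptors at every site.

Chronic daily doses by ingestion, inhalation and dermal contact for the
five priority metals (As, Cd, Cr, Ni, Pb), hazard quotients and Hazard
Index, carcinogenic risk and total carcinogenic risk, plus per-metal
contribution shares.  Writes health_risk.csv under results/ and prints
the site totals with their interpretation.
"""

from pathlib import Path

from sedrisk.pipeline import RunConfig, compute_health_risk
from sedrisk.sample_io import read_samples

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_samples(RESULTS / "samples.csv")
    cfg = RunConfig()
    frame = compute_health_risk(
        samples, cfg.exposure(), cfg.dose_response(), cfg.health_elements
    )
    frame.to_csv(RESULTS / "health_risk.csv", index=False, float_format="%.6g")

    totals = frame[frame["element"] == "TOTAL"]
    print("site totals:")
    for _, row in totals.iterrows():
        print(
            f"  {row['site']:>17} {row['receptor']:>5}:  "
            f"HI {row['hi']:8.4f} ({row['hi_category']})  "
            f"TCR {row['tcr']:10.3e} ({row['tcr_category']})"
        )

    shares = frame[(frame["route"] == "all") & (frame["element"] != "TOTAL")]
    top = shares.nlargest(3, "tcr_contrib_pct")
    print("\nlargest carcinogenic-risk contributors:")
    for _, row in top.iterrows():
        print(
            f"  {row['element']:>2} at {row['site']} ({row['receptor']}): "
            f"{row['tcr_contrib_pct']:.1f}% of TCR"
        )


if __name__ == "__main__":
    main()
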