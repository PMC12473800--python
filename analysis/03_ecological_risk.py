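#!/usr/bin/env python
"""Potential ecological risk (Er, RI) and Site Ranking Index per site.

Applies Hakanson-lineage toxic response factors to the site-mean
contamination factors for the ten-element risk set, under both
geochemical baselines, and ranks sites with the pooled Cf/Igeo rank
index.  Writes eco_risk_<baseline>.csv under results/.
"""

from pathlib import Path

from sedrisk.pipeline import compute_eco_risk
from sedrisk.reference_data import builtin_references, builtin_toxic_response_factors
from sedrisk.sample_io import read_samples

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_samples(RESULTS / "samples.csv")
    toxicity = builtin_toxic_response_factors()
    for reference in builtin_references():
        frame = compute_eco_risk(samples, reference, toxicity)
        out = RESULTS / f"eco_risk_{reference.name}.csv"
        frame.to_csv(out, index=False, float_format="%.6g")
        print(f"\n=== {reference.name} ===")
        for _, row in frame.sort_values("RI", ascending=False).iterrows():
            print(
                f"  {row['site']:>17} [{row['zone']:>5}]  "
                f"RI {row['RI']:7.1f} ({row['RI_category']:>12})  "
                f"SRI {row['SRI']:6.2f} ({row['SRI_category']})"
            )


if __name__ == "__main__":
    main()
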