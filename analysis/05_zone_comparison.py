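#!/usr/bin/env python
"""Between-zone rank-sum comparison for every measured element.

Exact (full-enumeration, tie-aware) two-sided rank-sum tests of the
upper versus lower reach, mirroring the N = 6 per zone design; raw
p-values plus a Holm-adjusted column.  Writes zone_tests.csv under
results/.
"""

from pathlib import Path

from sedrisk.pipeline import zone_compare_all
from sedrisk.sample_io import read_samples

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    samples = read_samples(RESULTS / "samples.csv")
    frame = zone_compare_all(samples, holm=True)
    frame.to_csv(RESULTS / "zone_tests.csv", index=False, float_format="%.6g")
    print("exact rank-sum tests, upper vs lower zone:")
    for _, row in frame.sort_values("p_value").iterrows():
        flag = "*" if row["significant_05"] else " "
        print(
            f"  {row['element']:>2}: U = {row['U']:5.1f}  "
            f"p = {row['p_value']:.4f}{flag}  (Holm {row['p_holm']:.4f})"
        )
    hits = frame[frame["significant_05"]]["element"].tolist()
    print(f"\nelements differing between zones at raw p<0.05: {', '.join(hits) or 'none'}")


if __name__ == "__main__":
    main()
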