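"""How bed nets multiply the encounters a mosquito needs per blood meal.

Sweeps net usage from 0 to 95% at the calibrated per-encounter block
probability and reports the expected number of human encounters (house
entries) required per blood meal. At 80% usage the requirement doubles —
the repeat house entry that a second indoor insecticide can exploit.

Writes results/encounter_amplification.csv.
"""

import pathlib

import numpy as np
import pandas as pd

from vectorcycle import DEFAULT_NET_BLOCK, expected_encounters

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    usage = np.round(np.arange(0.0, 0.96, 0.05), 2)
    rows = [
        {
            "net_usage": u,
            "blood_availability": expected_encounters(u).z_relative,
            "encounters_per_meal": expected_encounters(u).e_expected,
        }
        for u in usage
    ]
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "encounter_amplification.csv", index=False)

    at_80 = expected_encounters(0.8)
    print(f"per-encounter block probability b = {DEFAULT_NET_BLOCK}")
    print(
        f"at 80% net usage: blood availability falls to {at_80.z_relative:.2f}, "
        f"so a mosquito must enter {at_80.e_expected:.1f}x as many houses per meal"
    )
    print(f"wrote {OUT / 'encounter_amplification.csv'} ({len(df)} rows)")


if __name__ == "__main__":
    main()
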