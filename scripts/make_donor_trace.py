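"""Regenerate the packaged reference donor trace.

Runs one default full-scale simulation and stores the post-growth
extracellular-potassium trace of the stably oscillating colony as
``src/biofilmsig/data/donor_ke.csv`` (one value per tick), together with its
oscillation period.  This is the canned forcing waveform used by the CLI's
``sync`` command when no donor trace is supplied.

Usage: python scripts/make_donor_trace.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from biofilmsig import experiments


def main(seed: int = 2024) -> None:
    donor = experiments.make_donor(seed)
    out = Path(__file__).resolve().parents[1] / "src" / "biofilmsig" / "data"
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"k_e": donor.k_e_segment.round(5)})
    df.to_csv(out / "donor_ke.csv", index=False)
    print(f"wrote {out / 'donor_ke.csv'}: {len(df)} ticks, "
          f"period {donor.period:.1f}, growth end {donor.growth_end_tick}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 2024)
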