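"""Shared toy locus for the example scripts."""

import pandas as pd


def demo_locus() -> pd.DataFrame:
    """Nine oriented CTCF sites over 320 kb with a strong central site (s4)."""
    positions = [0, 40_000, 80_000, 120_000, 160_000, 200_000, 240_000, 280_000, 320_000]
    oris = ["forward", "reverse", "forward", "forward", "reverse",
            "forward", "reverse", "forward", "reverse"]
    xs = [20.0, 10.0, 15.0, 8.0, 60.0, 12.0, 25.0, 9.0, 18.0]
    return pd.DataFrame(
        {
            "site_id": [f"s{k}" for k in range(len(positions))],
            "chrom": "chr1",
            "peak_start": [p - 100 for p in positions],
            "peak_end": [p + 100 for p in positions],
            "pos": positions,
            "orientation": oris,
            "signal_raw": xs,
            "x": xs,
        }
    )
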