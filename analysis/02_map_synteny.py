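#!/usr/bin/env python
"""Map 200 kb reference windows to the other genome and apply retention filters.

A window is kept when more than 80% of its bases lift into one contiguous
target run whose span is between 180 and 220 kb; windows split across target
chromosomes, inflated by indels, poorly remapping or unmapped are rejected
with named verdicts. Writes results/window_map.tsv and reports the verdict
breakdown against the generator's truth.
"""

from pathlib import Path

import pandas as pd

from synpi.io import read_chain_file, read_chrom_sizes, write_tsv
from synpi.synteny import ChainIndex, build_window_map, tile_windows

SIM_DIR = Path("scratch/sim/default")
OUT = Path("results/window_map.tsv")


def main():
    windows = tile_windows(read_chrom_sizes(SIM_DIR / "ref.sizes"), 200_000)
    index = ChainIndex(read_chain_file(SIM_DIR / "a2b.chain"))
    wmap = build_window_map(windows, index)
    write_tsv(wmap, OUT)

    print(wmap["verdict"].value_counts().to_string())
    retained = (wmap["verdict"] == "retained").sum()
    print(f"\nretained {retained}/{len(wmap)} full windows "
          f"({100 * retained / len(wmap):.1f}%) -> {OUT}")

    truth = pd.read_csv(SIM_DIR / "truth.tsv", sep="\t")
    m = truth.merge(wmap[["window_id", "verdict"]], on="window_id")
    agree = (m["verdict"] == m["expected_verdict"]).mean()
    print(f"agreement with generator truth: {100 * agree:.1f}%")


if __name__ == "__main__":
    main()
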