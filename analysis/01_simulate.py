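#!/usr/bin/env python
"""Generate every synthetic input for the downstream analyses.

Writes phase-enriched single-cell libraries (4 x 800 cells, purity 0.7),
ploidy-sorted bulk profiles (3 phases x 2 sorts), control and ablated
PlaCCI track tables, and the fluorescence assay tables under results/data/.
"""

from pathlib import Path

from rootcycle.cli import run_cli

OUT = Path(__file__).resolve().parent.parent / "results" / "data"

if __name__ == "__main__":
    code = run_cli(["simulate", "--seed", "1", "--out", str(OUT),
                    "--cells-per-library", "800"])
    print(f"wrote synthetic inputs to {OUT} (exit {code})")
    raise SystemExit(code)
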