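#!/usr/bin/env python
"""Discover cell-cycle phase markers from the phase-enriched libraries.

QC -> log-normalize -> equalize cell-type composition -> one-vs-rest
Wilcoxon DE (p < 0.01, positive only) -> delta-pct ranking -> top 50 per
phase, plus the stricter in situ probe candidates. Reports how much of each
top-50 list is truly planted in that phase.
"""

from pathlib import Path

import pandas as pd

from rootcycle import pipeline as pl
from rootcycle.cli import run_cli
from rootcycle.io import PHASES

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    code = run_cli(["markers", "--counts", str(ROOT / "data" / "counts"),
                    "--meta", str(ROOT / "data" / "meta.tsv"),
                    "--config", str(ROOT / "data" / "config.yaml"),
                    "--out", str(ROOT / "markers")])
    if code:
        raise SystemExit(code)
    records = pd.read_csv(ROOT / "markers" / "markers.tsv", sep="\t")
    program = pd.read_csv(ROOT / "data" / "truth_program.tsv", sep="\t")
    truth = program.set_index("gene_id")["assigned_phase"].fillna("")
    for p in PHASES:
        genes = records[records["phase"] == p]["gene_id"]
        rec = (truth.reindex(genes).fillna("") == p).mean()
        print(f"{p}: {len(genes)} markers, {100 * rec:.1f}% planted in phase")
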