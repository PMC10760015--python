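#!/usr/bin/env python
"""Validate the single-cell markers against ploidy-sorted bulk profiles.

TPM-normalizes the bulk table, clusters standardized phase-mean profiles
with k-means (k = 8), annotates each cluster's peak phase and reports the
marker-vs-bulk phase agreement.
"""

import json
from pathlib import Path

from rootcycle.cli import run_cli

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    code = run_cli(["bulk-concordance", "--bulk", str(ROOT / "data" / "bulk"),
                    "--markers", str(ROOT / "markers" / "markers.tsv"),
                    "--config", str(ROOT / "data" / "config.yaml"),
                    "--out", str(ROOT / "bulk")])
    if code:
        raise SystemExit(code)
    res = json.loads((ROOT / "bulk" / "concordance.json").read_text())
    for p, frac in res["agreement"].items():
        print(f"{p}: {100 * frac:.1f}% of markers peak in the same bulk phase")
    print(f"{100 * res['fraction_markers_missing']:.1f}% of markers "
          f"missing from the clustered bulk set")
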