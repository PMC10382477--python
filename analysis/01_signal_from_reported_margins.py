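#!/usr/bin/env python
"""Pooled-class signal row from the published screening margins.

The published FAERS screen (2004Q1-2022Q4) reports four margins for the
SSRI class: 889 rhabdomyolysis cases with an SSRI as sole primary
suspect, 151,660 SSRI-PS reports, 33,574 rhabdomyolysis reports, and
16,011,277 deduplicated reports. That is everything the four
disproportionality algorithms need, so the headline result is
recomputable with no corpus at all.

Writes results/signal_from_margins.csv and prints the display row.
"""

from pathlib import Path

from faerspv.faers_io import write_signal_table
from faerspv.pipeline import format_margins_row, run_margins_only
from faerspv.synth import published_margins

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    m = published_margins()["SSRIs"]
    result = run_margins_only(m.a, m.drug_total, m.event_total, m.n, name="SSRIs")
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "signal_from_margins.csv"
    write_signal_table([result], out)
    print("Pooled SSRI class vs rhabdomyolysis, from published margins:")
    print(" ", format_margins_row(result))
    print(f"All four criteria met -> signal: {result.signal}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
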