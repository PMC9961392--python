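#!/usr/bin/env python
"""End-to-end report: every computed quantity beside its published value.

Thin driver over hgdiff.pipeline.reproduce_paper; writes
results/report.json and results/report.txt.
"""

from pathlib import Path

from hgdiff.io import RunConfig, write_report
from hgdiff.pipeline import report_text, reproduce_paper

OUT = Path(__file__).resolve().parents[1] / "results"

report = reproduce_paper(RunConfig())
write_report(report, OUT / "report.json")
text = report_text(report)
(OUT / "report.txt").write_text(text + "\n")
print(text)
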