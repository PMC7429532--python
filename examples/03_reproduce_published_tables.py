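"""Recompute every downstream number of the published 22-patient benchmark.

Loads the packaged per-patient clinical tables (treated lobes and Engel
outcome; per-patient metric averages; lobar percentages per method),
recomputes the cohort aggregates, the rank statistics, the four confusion
matrices and the prediction statistics, and compares each with the value
printed in the study this package reproduces.  Exits nonzero if any check
fails.
"""

import sys

from izbench import reproduce_paper

report = reproduce_paper()
print(report.to_text())
sys.exit(0 if report.ok else 1)
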