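"""Accuracy rates from a pre-tallied confusion table.

Feeds a field-scale confusion table (13731 monitoring slots) through the
four rate equations — the same path `henmon evaluate --counts` uses.
"""

from henmon import ConfusionCounts, metrics
from henmon.evaluation import round_half_up

counts = ConfusionCounts(tp=9108, tn=4283, fp=222, fn=118)
report = metrics(counts).rounded()

print(f"slots evaluated: {counts.total}")
print(f"sensitivity = {report.sensitivity}%   (share of occupied slots detected)")
print(f"specificity = {report.specificity}%   (share of empty slots kept silent)")
print(f"error rate  = {report.error_rate}%    (false alarms among positives)")
print(f"accuracy    = {report.accuracy}%")
print(f"missed slots: {counts.fn} "
      f"({round_half_up(100.0 * counts.fn / counts.total, 2)}% of all slots)")
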