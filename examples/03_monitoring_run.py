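"""A complete monitoring window: simulate, detect slot by slot, evaluate.

Renders a 40-slot sequence with a hen present in slots 10-25, runs the
slot-based monitoring loop (one 2-s slot per frame, TSV log), then scores
the log against the ground truth.
"""

import tempfile
from pathlib import Path

from henmon import (
    DetectorConfig,
    SceneConfig,
    metrics,
    run_monitoring,
    simulate_frames,
    tally,
)
from henmon.simulate import block_schedule

n_slots = 40
schedule = block_schedule(n_slots, 10, 25)
scene = SceneConfig(occupancy_schedule=schedule, seed=4)

log_path = Path(tempfile.mkdtemp()) / "monitoring_log.tsv"
frames = (frame for frame, _ in simulate_frames(scene, n_slots))
records = run_monitoring(frames, DetectorConfig(), log_path)

counts = tally(records, list(schedule))
report = metrics(counts).rounded()
print(f"log written to {log_path}")
print(f"slots: {len(records)}  positive: {sum(r.hd for r in records)}")
print(f"TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn}")
print(f"sensitivity={report.sensitivity}%  specificity={report.specificity}%  "
      f"error_rate={report.error_rate}%  accuracy={report.accuracy}%")
print()
print("Each log row is one closed 2-s slot; a slot is positive if any of")
print("its frames detected a hen. The occupancy block (slots 10-25) is")
print("recovered almost perfectly; the missed slots are hens whose body")
print("contrast was sampled barely above the 1 degC detection shift.")
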