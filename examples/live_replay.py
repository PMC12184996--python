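"""Replay a session through the live monitor, frame by frame.

The monitor keeps one trailing 2 s window plus 60 s of rolling context
(aperture baseline, body scale) and emits a score + status per frame; the
final emission matches the batch trailing-window score exactly.
"""

from collections import Counter

from stressface import AppConfig
from stressface.live_monitor import frames_from_table, replay, score_trailing_window
from stressface.session_simulator import SimulationConfig, simulate_session

config = AppConfig()
sim = simulate_session(
    SimulationConfig(
        seed=7,
        duration_s=12.0,
        state_schedule=[("relaxed", 6.0), ("stressed_combined", 6.0)],
    )
)

emissions = replay(frames_from_table(sim.table), config)
counts = Counter(e.status for e in emissions)
print(f"emissions: {dict(counts)}")
print(f"final    : {emissions[-1].score:.3f}/10 -> {emissions[-1].status}")

batch = score_trailing_window(sim.table, config)
print(f"batch    : {batch.total:.3f}/10 (trailing-window score on the same frames)")
# The stream warms up for one window (59 frames), reads "okay" through the
# relaxed half, then climbs through "caution" into "stressed" once the
# trailing window fills with squint/freeze behaviour; live and batch values
# agree to float precision because both are pure functions of the same
# window + context.
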