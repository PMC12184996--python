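"""Score a simulated recording session, end to end.

Simulates a 30 s session that starts relaxed and ends with combined stress
behaviours (squinting + freezing + ear fold), writes it to the standard
3-header-row CSV dialect, reads it back, cleans low-confidence points and
scores it window by window.
"""

import tempfile
from pathlib import Path

from stressface import (
    AppConfig,
    clean_trajectories,
    read_trajectories,
    score_session,
    write_trajectories,
)
from stressface.session_simulator import SimulationConfig, simulate_session

config = AppConfig()
sim = simulate_session(
    SimulationConfig(
        seed=42,
        duration_s=30.0,
        state_schedule=[("relaxed", 15.0), ("stressed_combined", 15.0)],
    )
)

# roundtrip through the on-disk format, as a real recording would arrive
path = Path(tempfile.mkdtemp()) / "session.csv"
write_trajectories(sim.table, path)
table = read_trajectories(path, fps=30.0)

report = score_session(clean_trajectories(table, config.cleaning), config=config)
print(f"windows scored : {len(report.windows)}")
for w in report.windows:
    t0 = w.start_frame / report.fps
    print(f"  {t0:5.1f}s  total {w.total:5.2f}  -> {w.status}")
print(f"session mean   : {report.session_mean:.2f}/10 -> {report.session_status}")
# The first half (relaxed behaviour) scores near 0 ("okay"); once squints,
# freezing and the folded ear start, window totals jump above the stressed
# cut point (20/3) and the session lands in between.
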