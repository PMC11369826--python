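#!/usr/bin/env python
"""Generate the synthetic study cohort and write one session to disk.

Simulates a small cohort (4 freezers with Parkinson's disease, 4
age-matched controls; four ~6.5 min runs each of the corridor gait task)
and summarises what the generator produced: per-participant freeze
counts, freeze-duration statistics and % time frozen.  The first
session's raw files (SNIRF-style recordings, kinematics, rater/protocol
event tables) are written under scratch/session_sub-01/ (bulky,
regenerable) so the file-based CLI stages can be exercised on them.
"""

import sys
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from fnirsgait import io
from fnirsgait.events import percent_time_frozen
from fnirsgait.synth import CohortSpec, generate_cohort

warnings.filterwarnings("ignore")
RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = CohortSpec(n_pd=4, n_hc=4)
    rows = []
    durations = []
    for i, session in enumerate(generate_cohort(cohort, seed=SEED)):
        n_freezes, pct = 0, []
        for run in session.runs:
            frz = run.protocol_events.of_type("freeze").df
            n_freezes += len(frz)
            durations.extend(frz["duration"])
            pct.append(percent_time_frozen(run.protocol_events,
                                           run.recording.duration_s))
        rows.append(dict(participant=session.participant, group=session.group,
                         age=round(session.age, 1),
                         speed_ms=round(session.meta["speed_ms"], 2),
                         n_freezes=n_freezes,
                         pct_time_frozen=round(float(np.mean(pct)), 2)))
        if i == 0:
            out = RESULTS.parent / "scratch" / "session_sub-01"
            out.mkdir(parents=True, exist_ok=True)
            io.write_montage(out / "montage.json", session.montage)
            import json
            (out / "session.json").write_text(json.dumps(
                {"participant": session.participant, "group": session.group,
                 "age": session.age}))
            run = session.runs[0]
            io.write_recording(out / "run-01_nirs.h5", run.recording, session.montage)
            io.write_kinematics(out / "run-01_kinematics.tsv", run.kinematics)
            io.write_events(out / "run-01_events_protocol.tsv", run.protocol_events)
            io.write_events(out / "run-01_events_raterA.tsv", run.events_rater_a)
            io.write_events(out / "run-01_events_raterB.tsv", run.events_rater_b)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "cohort_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    if durations:
        print(f"\nfreeze episodes: n={len(durations)}, "
              f"median duration {np.median(durations):.1f} s "
              f"(IQR {np.quantile(durations, 0.25):.1f}-"
              f"{np.quantile(durations, 0.75):.1f} s)")
    print(f"\nwrote {RESULTS/'cohort_summary.tsv'} and scratch/session_sub-01/")


if __name__ == "__main__":
    main()
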