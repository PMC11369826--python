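#!/usr/bin/env python
"""Gait-event bookkeeping on a synthetic session: detection accuracy,
rater merging, agreement metrics and the 10-s selection rules.

Writes results/gait_events_summary.tsv.
"""

import sys
import warnings
from pathlib import Path

import pandas as pd

from fnirsgait.events import (agreement_metrics, merge_annotations,
                              percent_time_frozen, select_events)
from fnirsgait.experiments import detection_accuracy
from fnirsgait.synth import GroundTruth, ProtocolSpec, generate_session

warnings.filterwarnings("ignore")
RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    session = generate_session(ProtocolSpec(), GroundTruth(), {"group": "PD"},
                               seed=SEED)
    rows = []
    for run in session.runs:
        consensus, disputed = merge_annotations(run.events_rater_a,
                                                run.events_rater_b)
        agree = agreement_metrics(run.events_rater_a, run.events_rater_b,
                                  total_duration_s=run.recording.duration_s)
        selected = select_events(consensus, run.protocol_events)
        rows.append(dict(
            run=run.run_id,
            true_freezes=len(run.protocol_events.of_type("freeze")),
            consensus_freezes=len(consensus), disputed=len(disputed),
            positive_agreement=round(agree.positive_agreement, 3),
            negative_agreement=round(agree.negative_agreement, 3),
            prevalence_index=round(agree.prevalence_index, 3),
            analysis_events=len(selected),
            pct_time_frozen=round(percent_time_frozen(
                consensus, run.recording.duration_s), 2)))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "gait_events_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    det = detection_accuracy(seed=SEED, n_runs=2)
    print(f"\nkinematic detection: {100 * det['frac_within_0p2s']:.0f}% of "
          f"{det['n_events']} clear events within 0.2 s of truth "
          f"(median error {det['median_error_s'] * 1000:.0f} ms)")
    print(f"wrote {RESULTS/'gait_events_summary.tsv'}")


if __name__ == "__main__":
    main()
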