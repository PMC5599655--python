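"""Plain-text persistence for synthetic cohorts and analysis tables.

Recordings are written as wide CSV (a time column plus one column per
channel, microvolts) with session spans in a JSON sidecar; environment,
task logs and thermograms as CSV; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectral import Recording
from .synthetic import SyntheticCohort


def write_recording_csv(recording: Recording, path) -> None:
    path = Path(path)
    t = np.arange(recording.samples.shape[1]) / recording.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for i, ch in enumerate(recording.channel_labels):
        df[ch] = recording.samples[i]
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {"sampling_rate": recording.sampling_rate,
               "participant": recording.participant,
               "condition": recording.condition,
               "rereferenced": recording.rereferenced,
               "session_spans": [[s, t0, t1] for s, t0, t1
                                 in recording.session_spans]}
    path.with_suffix(".sessions.json").write_text(json.dumps(sidecar))


def read_recording_csv(path) -> Recording:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".sessions.json").read_text())
    labels = [c for c in df.columns if c != "time_s"]
    return Recording(samples=df[labels].to_numpy().T,
                     sampling_rate=meta["sampling_rate"],
                     channel_labels=labels,
                     session_spans=[tuple(s) for s in meta["session_spans"]],
                     participant=meta.get("participant"),
                     condition=meta.get("condition"),
                     rereferenced=meta.get("rereferenced", False))


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write every component of a cohort under ``out_dir`` as CSV/JSON."""
    out = Path(out_dir)
    (out / "recordings").mkdir(parents=True, exist_ok=True)
    (out / "thermograms").mkdir(exist_ok=True)
    for (pid, cond), rec in cohort.recordings.items():
        write_recording_csv(rec, out / "recordings" / f"p{pid}_{cond}.csv")
    for cond, env in cohort.environment.items():
        env.to_csv(out / f"environment_{cond}.csv", index=False)
    rows = []
    for (pid, cond), log in cohort.task_logs.items():
        for s, presses in log.presses.items():
            for k, tp in enumerate(presses, start=1):
                rows.append((pid, cond, s, k, tp))
    pd.DataFrame(rows, columns=["participant", "condition", "session",
                                "press", "time_s"]).to_csv(
        out / "task_logs.csv", index=False)
    for (pid, cond, when), frame in cohort.thermograms.items():
        np.savetxt(out / "thermograms" / f"p{pid}_{cond}_{when}.csv",
                   frame.temperatures, fmt="%.4f", delimiter=",")
    (out / "truth.json").write_text(json.dumps(cohort.truth, indent=2,
                                               default=str))
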