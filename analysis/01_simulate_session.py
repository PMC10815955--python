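#!/usr/bin/env python
"""Simulate one demo subject: ASSR session (EDF + events), spontaneous EEG, behavior tables.

Writes results/demo/: session.edf, events.csv, spontaneous.edf, activity.csv,
social.csv. Scaled to 200 stimuli / 300 s of spontaneous EEG so the demo runs
in seconds; the analysis defaults elsewhere remain the full 1500-stimulus,
1-h protocol.
"""

import pathlib

from gammassr import (
    ArmSpec,
    BackgroundModel,
    BehaviorModel,
    EvokedModel,
    StimulusProtocol,
    StudyDesign,
    generate_behavior,
    generate_session,
    generate_spontaneous,
    write_events,
    write_recording,
)

SEED = 7
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "demo"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    protocol = StimulusProtocol(n_stimuli=200)
    evoked = EvokedModel(phase_concentration=4.0)
    background = BackgroundModel(artifact_rate=0.5)

    rec, events = generate_session(protocol, evoked, background, seed=SEED)
    write_recording(rec, str(OUT / "session.edf"), format="edf")
    write_events(events, str(OUT / "events.csv"))
    print(f"session: {rec.duration:.0f} s, {len(events)} stimuli, "
          f"channels {rec.channels}, seed {SEED}")

    spont = generate_spontaneous(background, duration=300.0, seed=SEED + 1)
    write_recording(spont, str(OUT / "spontaneous.edf"), format="edf")
    print(f"spontaneous: {spont.duration:.0f} s")

    arm = ArmSpec("vehicle", 8, evoked, background, BehaviorModel())
    design = StudyDesign(arms=(arm,), reference_arm="vehicle", seed=SEED)
    activity, social = generate_behavior(design)
    activity.to_csv(OUT / "activity.csv", index=False)
    social.to_csv(OUT / "social.csv", index=False)
    print(f"behavior: {activity['subject'].nunique()} subjects, "
          f"{len(social)} social pairs -> {OUT}")


if __name__ == "__main__":
    main()
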