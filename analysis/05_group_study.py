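#!/usr/bin/env python
"""Full synthetic two-arm study: vehicle vs NMDAr-antagonist-like arm, all endpoints.

Simulates every subject, runs the complete ASSR / qEEG / behavior chain, then
the 2-SD-outlier + ANOVA + Dunnett layer. Scaled to 300 stimuli, 300-s
spontaneous EEG and n=6/arm so it finishes in about a minute; writes
results/study_report.csv and study_provenance.json and prints the headline
percent-of-vehicle numbers.
"""

import json
import pathlib

from gammassr.pipeline import (
    PipelineConfig,
    QeegParams,
    default_two_arm_design,
    run_study,
)

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design, protocol = default_two_arm_design(
        seed=SEED, n_per_arm=6, plf_ratio=0.4, gamma_power_ratio=4.06,
        n_stimuli=300, qeeg_duration_s=300.0)
    cfg = PipelineConfig(design=design, protocol=protocol,
                         qeeg=QeegParams(duration_s=300.0),
                         channels=("global_cortex",))
    out = run_study(cfg)
    out.report.to_csv(OUT / "study_report.csv", index=False)
    (OUT / "study_provenance.json").write_text(json.dumps(out.provenance, indent=2))

    rep = out.report.set_index(["endpoint", "arm"])
    print("drug arm, percent of vehicle (mean ± SEM, Dunnett p):")
    for endpoint in rep.index.get_level_values(0).unique():
        row = rep.loc[(endpoint, "mk801")]
        print(f"  {endpoint:32s} {row['percent_of_reference']:7.1f} ± "
              f"{row['percent_sem']:5.1f} %   p={row['p_dunnett']:.4f} {row['stars']}")


if __name__ == "__main__":
    main()
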