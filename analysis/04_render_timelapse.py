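#!/usr/bin/env python
"""Render side-by-side parameter time-lapses for one participant.

For each parameter, applies the calibration fitted in step 03 to every
acquisition block of the first 45 mm participant and writes false-colour
MSI-vs-reference comparison frames (one PNG per minute) under
scratch/timelapse/<parameter>/.
"""

import json
from pathlib import Path

from msiperf import io as msio
from msiperf import perfusion, pipeline
from msiperf.perfusion import CalibrationModel

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    dataset = msio.read_dataset(ROOT / "scratch" / "dataset")
    report = json.loads((ROOT / "results" / "calibration_report.json").read_text())
    selections = perfusion.default_selections()
    for param, info in report["parameters"].items():
        model = CalibrationModel(
            info["msi_parameter"], info["model"]["slope"], info["model"]["intercept"]
        )
        meas = [
            m for m in dataset.measurements_for(param) if m.distance_mm == 45.0
        ]
        first = meas[0].participant_id
        run = sorted(
            (m for m in meas if m.participant_id == first), key=lambda m: m.minute
        )
        pims, refs = [], []
        for m in run:
            rr = pipeline.compute_rr_image(m, dataset, selections)
            pims.append(perfusion.parameter_image(rr, model))
            refs.append(m.reference)
        out = ROOT / "scratch" / "timelapse" / param
        paths = perfusion.render_timelapse(pims, refs, out)
        print(f"{param}: {len(paths)} comparison frames -> {out}")


if __name__ == "__main__":
    main()
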