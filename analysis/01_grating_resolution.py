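#!/usr/bin/env python
"""Line-grating resolution of the flying-spot scanner.

Scans noiseless binary bar targets over the 18-step 1.25-250 lines/mm ladder
with the 22 µm (1/e²) Gaussian spot, once with the 5 µm super-sampling raster
and once with the native 20 µm raster, and reports the highest frequency whose
modulation stays at or above 0.2.  The super-sampled raster should resolve
50 lines/mm; the native raster is Nyquist-limited at 25 lines/mm.

Writes results/grating_contrast.csv and results/grating_resolution.json.
"""

import json
from pathlib import Path

import pandas as pd

from mirfluor.pipeline import run_grating_validation

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    limits = {}
    for label, step in (("raster_5um", 5.0), ("raster_20um", 20.0)):
        curve, limit = run_grating_validation(raster_step=step)
        limits[label] = limit
        for f, c, aliased in zip(curve.frequencies, curve.contrasts, curve.aliased):
            rows.append(
                {"raster": label, "frequency_lp_mm": f, "contrast": c, "aliased": aliased}
            )
        print(f"{label}: resolution limit {limit:g} lp/mm")
    pd.DataFrame(rows).to_csv(OUT / "grating_contrast.csv", index=False)
    (OUT / "grating_resolution.json").write_text(json.dumps(limits, indent=2))


if __name__ == "__main__":
    main()
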