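"""Generate a synthetic CGM trace and write it as a Time,BGL CSV.

The generator emulates a single-patient continuous glucose monitor export:
15-minute sampling, a circadian drift, three daily meal excursions with
exponential decay, and autocorrelated sensor noise, clamped to the
physiological 2-25 mmol/L band.
"""

import numpy as np

from gluforecast import CgmSimParams, generate_cgm, inject_gaps, write_cgm_csv

params = CgmSimParams(n_points=96 * 7, seed=42)  # one week at 15-min spacing
series = generate_cgm(params)
print(f"{len(series)} readings; "
      f"mean {series.values.mean():.2f} mmol/L, "
      f"range [{series.values.min():.2f}, {series.values.max():.2f}]")
# mean near the 7 mmol/L baseline plus the average meal contribution;
# the range stays inside the physiological clamp

gappy = inject_gaps(series, [(100, 120)])  # a 5-hour sensor dropout
dt_minutes = np.diff(gappy.timestamps.astype("int64")) / 60e9
print(f"after dropout: {len(gappy)} readings, "
      f"largest sampling gap {dt_minutes.max():.0f} minutes")

path = write_cgm_csv(series, "synthetic_cgm.csv")
print(f"wrote {path} (two columns: Time, BGL in mmol/L)")
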