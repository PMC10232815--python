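"""Published reference values used as worked-example inputs.

``fullbody_p99_table`` reproduces a published table of 99th-percentile
stimulation strength (E/E_th, ultra-brief threshold 25 V/m) in the brain of
an anatomically realistic MRI-derived full-body model, for RUL and BL ECT at
100–900 mA across the five modelled extents.  Those absolute values depend
on the individual anatomy and are *not* reproduced by the synthetic phantom;
they serve as inputs to the desk-check examples (relative-error formula,
linearity of field with current) and as the qualitative yardstick for the
phantom experiment.
"""

from __future__ import annotations

import pandas as pd

from .phantom import FOVLevel

__all__ = ["fullbody_p99_table", "REPORTED_RE_PCT", "REPORTED_LATERALITY_RUL"]

_FOVS = [lv.value for lv in FOVLevel.ordered()]
_AMPS = [100, 200, 300, 400, 500, 600, 700, 800, 900]

_RUL = [
    # upper_head, full_head, neck, torso, full_body
    [0.9803, 0.9388, 0.9380, 0.9372, 0.9361],
    [1.9607, 1.8776, 1.8760, 1.8744, 1.8722],
    [2.9410, 2.8164, 2.8140, 2.8116, 2.8083],
    [3.9214, 3.7552, 3.7520, 3.7489, 3.7444],
    [4.9017, 4.6940, 4.6900, 4.6861, 4.6805],
    [5.8821, 5.6328, 5.6280, 5.6233, 5.6166],
    [6.8624, 6.5716, 6.5660, 6.5605, 6.5527],
    [7.8427, 7.5104, 7.5040, 7.4977, 7.4888],
    [8.8231, 8.4492, 8.4420, 8.4349, 8.4249],
]

_BL = [
    [1.3911, 0.9516, 0.9493, 0.9314, 0.9299],
    [2.7821, 1.9033, 1.8987, 1.8628, 1.8598],
    [4.1732, 2.8549, 2.8480, 2.7942, 2.7898],
    [5.5642, 3.8066, 3.7973, 3.7257, 3.7197],
    [6.9553, 4.7582, 4.7467, 4.6569, 4.6496],
    [8.3463, 5.7099, 5.6960, 5.5884, 5.5795],
    [9.7374, 6.6615, 6.6453, 6.5198, 6.5094],
    [11.1284, 7.6132, 7.5947, 7.4511, 7.4394],
    [12.5195, 8.5648, 8.5440, 8.3827, 8.3693],
]

#: Relative errors (%) of each extent vs. the full-body reference at 100 mA,
#: as reported alongside the table (to two decimals).
REPORTED_RE_PCT = {
    ("RUL", "upper_head"): 4.72,
    ("RUL", "full_head"): 0.28,
    ("RUL", "neck"): 0.20,
    ("RUL", "torso"): 0.11,
    ("BL", "upper_head"): 49.59,
    ("BL", "full_head"): 2.33,
    ("BL", "neck"): 2.08,
    ("BL", "torso"): 0.16,
}

#: Reported right/left hemisphere median |E| ratios for RUL (upper head and
#: full head & beyond).
REPORTED_LATERALITY_RUL = {"upper_head": 1.59, "full_head": 1.49}


def fullbody_p99_table(montage: str | None = None) -> pd.DataFrame:
    """The reference p99 E/E_th table as a tidy DataFrame.

    Columns: ``montage``, ``amplitude_mA``, one column per extent.  Pass
    ``montage`` ("RUL" or "BL") to select one montage.
    """
    frames = []
    for name, rows in (("RUL", _RUL), ("BL", _BL)):
        df = pd.DataFrame(rows, columns=_FOVS)
        df.insert(0, "amplitude_mA", _AMPS)
        df.insert(0, "montage", name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if montage is not None:
        out = out[out["montage"] == montage].reset_index(drop=True)
    return out
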