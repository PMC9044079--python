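"""Small published reference tables bundled for offline analysis."""

from __future__ import annotations

import pandas as pd

__all__ = ["scanner_doe_table", "SCANNER_DOE_LEVELS"]

#: Level meanings of the scanner-condition L9 experiment: the stage colour,
#: turntable rotation step and scanner elevation angle factors.
SCANNER_DOE_LEVELS = {
    "stage_color": {1: "black", 2: "red", 3: "blue"},
    "rotation_angle": {1: "60°", 2: "45°", 3: "30°"},
    "scanning_angle": {1: "30°", 2: "45°", 3: "37°"},
}

# L9(3^4) scanning-condition experiment: per-test MAPE of grain length,
# width, thickness and sulcus depth against caliper/slice ground truth.
_SCANNER_DOE_ROWS = [
    # stage_color, rotation_angle, scanning_angle, mape
    (1, 1, 1, 0.0407),
    (1, 2, 2, 0.0551),
    (1, 3, 3, 0.0269),
    (2, 1, 3, 0.0901),
    (2, 2, 1, 0.0811),
    (2, 3, 2, 0.1048),
    (3, 1, 2, 0.1826),
    (3, 2, 3, 0.0932),
    (3, 3, 1, 0.0913),
]


def scanner_doe_table() -> pd.DataFrame:
    """The published 9-test scanner-condition design with MAPE responses.

    Columns: three factor columns (levels 1-3, meanings in
    :data:`SCANNER_DOE_LEVELS`) and the ``mape`` response, suitable for
    :func:`grain3d.traits.orthogonal_analysis`.
    """
    return pd.DataFrame(
        _SCANNER_DOE_ROWS,
        columns=["stage_color", "rotation_angle", "scanning_angle", "mape"],
    )
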