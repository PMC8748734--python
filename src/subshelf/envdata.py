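"""Environmental profile of the water column sampled below the Ross Ice Shelf.

The bundled profile holds the published biogeochemical measurements at the
three sampled depths below the ice base (30, 180 and 330 m): temperature,
practical salinity, inorganic nutrient concentrations, flow-cytometric cell
abundances (with the low/high nucleic-acid-content split), prokaryotic
heterotrophic production (PHP, from :sup:`3`\\ H-leucine incorporation) and
the community carbon turnover time. Values are triplicate means; columns
ending in ``_sd`` carry the reported standard deviations.
"""

from __future__ import annotations

import pandas as pd

#: Column units, also written as header comments by :func:`subshelf.io.write_env_profile`.
ENV_UNITS = {
    "depth_m": "m below ice base",
    "temperature_c": "degC",
    "salinity_psu": "psu",
    "nh3_um": "uM",
    "nox_um": "uM",
    "po4_um": "uM",
    "sio2_um": "uM",
    "cells_per_ml": "cells mL-1",
    "lna_pct": "%",
    "hna_pct": "%",
    "php_umol_c_m3_d": "umol C m-3 d-1",
    "turnover_d": "d",
}

_TABLE1_ROWS = [
    # depth, temp, sal, NH3(sd), NOx(sd), PO4(sd), SiO2(sd), cells(sd, cells/mL),
    # LNA(sd), HNA(sd), PHP(sd), turnover
    (30, -2.13, 34.57, 0.44, 0.02, 7.35, 0.23, 0.720, 0.003, 165.0, 2.1,
     0.9e5, 0.1e5, 82.8, 0.2, 18.0, 0.4, 0.30, 0.02, 461),
    (180, -1.96, 34.69, 0.05, 0.02, 7.32, 0.04, 0.720, 0.004, 166.0, 0.7,
     1.20e5, 0.07e5, 85.5, 0.3, 15.1, 0.3, 0.60, 0.03, 339),
    (330, -1.91, 34.76, 0.04, 0.01, 7.37, 0.05, 0.710, 0.001, 165.0, 0.3,
     0.80e5, 0.07e5, 77.4, 0.9, 23.4, 0.7, 0.4, 0.1, 386),
]

_COLUMNS = [
    "depth_m", "temperature_c", "salinity_psu",
    "nh3_um", "nh3_sd", "nox_um", "nox_sd", "po4_um", "po4_sd",
    "sio2_um", "sio2_sd", "cells_per_ml", "cells_sd",
    "lna_pct", "lna_sd", "hna_pct", "hna_sd",
    "php_umol_c_m3_d", "php_sd", "turnover_d",
]


def table1_fixture() -> pd.DataFrame:
    """Return the packaged depth-profile of measured biogeochemistry.

    Returns
    -------
    pandas.DataFrame
        Indexed by depth (m below the ice base: 30, 180, 330), one column
        per measured quantity plus ``_sd`` columns for standard deviations.
        Units are listed in :data:`ENV_UNITS`.
    """
    df = pd.DataFrame(_TABLE1_ROWS, columns=_COLUMNS)
    return df.set_index("depth_m")
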