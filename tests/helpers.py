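"""Shared hand-built fixtures for unit tests."""

import numpy as np
import pandas as pd

from trophoscale.admin import AdminLayout


def one_unit_layout(land_cover_row) -> AdminLayout:
    """1 x n single-municipality layout with explicit land-cover codes.

    Codes: 0 forest, 1 open, 2 other; cell area 0.25 km^2.
    """
    n = len(land_cover_row)
    return AdminLayout(
        grid_shape=(1, n),
        cell_area=0.25,
        municipality_index=np.zeros((1, n), dtype=int),
        county_index=np.zeros((1, n), dtype=int),
        land_cover=np.array([land_cover_row]),
        units=pd.DataFrame(
            {
                "unit_id": ["m0000"],
                "county_id": ["c00"],
                "n_cells": [n],
                "forest_cells": [int(sum(c == 0 for c in land_cover_row))],
                "open_cells": [int(sum(c == 1 for c in land_cover_row))],
                "rangeland_area_km2": [
                    0.25 * sum(c in (0, 1) for c in land_cover_row)
                ],
            }
        ),
    )
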