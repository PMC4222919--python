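"""Reference data shipped with the package.

``plot_diversity_reference`` returns the published per-plot diversity
summary for the 14-plot Chihuahua spruce (Picea chihuahuana) gallery-forest
community in the Sierra Madre Occidental: species richness (nu_sp,0), the
effective (Simpson) number of species (nu_sp,2), the number of prevalent
species (nu_sp,inf), and the mean per-locus genetic diversity (nu_mean,2)
of the four dominant tree species genotyped with AFLP markers.  Missing
entries mean the species was not sampled in that plot.

These printed plot-level summaries serve as a fixed input for aggregate
checks (their column means define the "across all plots" row) and as a
realistic template for the synthetic-data generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_diversity_reference"]

_ROWS = [
    # code, location, nu_sp_0, nu_sp_2, nu_sp_inf, Picea, Pinus, Populus, Pseudotsuga
    ("TN", "La Tinaja", 6, 2.75, 2.30, 1.551, 1.237, 1.417, None),
    ("RC", "El Ranchito", 6, 3.85, 2.42, 1.567, 1.596, 1.719, None),
    ("CV", "El Cuervo", 5, 3.48, 2.56, 1.597, 1.596, None, None),
    ("TY", "Talayote", 7, 3.15, 2.07, 1.564, 1.575, None, 1.383),
    ("TR", "Las Trojas", 8, 4.24, 2.70, 1.577, 1.349, 1.510, None),
    ("VN", "El Venado", 8, 4.12, 2.41, 1.565, 1.667, None, None),
    ("LQ", "La Quebrada", 6, 3.70, 2.67, 1.485, 1.579, 1.414, None),
    ("PPR", "Paraje Piedra Rayada", 4, 2.29, 1.65, 1.430, 1.417, 1.299, 1.590),
    ("QD", "Quebrada de los Durán", 5, 2.04, 1.49, 1.459, 1.721, 1.231, 1.540),
    ("CB", "Cebollitas", 7, 4.34, 2.59, 1.525, 1.536, None, 1.696),
    ("SJ", "San José de las Causas", 7, 4.46, 3.00, 1.448, 1.654, None, None),
    ("SB", "Santa Bárbara", 9, 2.90, 1.86, 1.439, None, None, 1.740),
    ("ACH", "Arroyo del Chino", 4, 3.44, 2.73, 1.491, 1.574, None, 1.685),
    ("LP", "La Pista", 5, 1.92, 1.49, 1.511, None, 1.333, None),
]

_COLUMNS = [
    "plot",
    "location",
    "nu_sp_0",
    "nu_sp_2",
    "nu_sp_inf",
    "nu_mean2_Picea",
    "nu_mean2_Pinus",
    "nu_mean2_Populus",
    "nu_mean2_Pseudotsuga",
]


def plot_diversity_reference() -> pd.DataFrame:
    """Published per-plot diversity summaries of the 14 study plots."""
    frame = pd.DataFrame(_ROWS, columns=_COLUMNS).set_index("plot")
    for col in _COLUMNS[2:]:
        frame[col] = frame[col].astype(float)
    return frame
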