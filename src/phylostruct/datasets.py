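"""Bundled example data: the 12-community Neotropical snake summary table.

This is the published per-site summary for twelve Brazilian snake
communities — six in forest (Amazon and Atlantic Forest) and six in
non-forest vegetation (Cerrado savanna and southern Campos grassland) —
with site latitude (degree-minute coordinates converted to absolute
decimal degrees south), species richness, and the NRI/NTI structure
indices computed against regional-pool nulls.  It exercises the
regression and variation-partitioning stages exactly as a user's own
structure-index table would.
"""

from __future__ import annotations

import pandas as pd

from .community import parse_latitude

__all__ = ["snake_community_summary"]

_ROWS = [
    # site,            habitat,      latitude,   richness, NRI,    NTI
    ("Amazonian_1",    "forest",     "3°6'S",     61, -1.821,  0.607),
    ("Amazonian_2",    "forest",     "11°31'S",   45, -1.431,  1.413),
    ("Atlantic_1",     "forest",     "14°47'S",   55, -0.054,  1.709),
    ("Atlantic_2",     "forest",     "24°32'S",   28,  0.359,  1.030),
    ("Atlantic_3",     "forest",     "25°47'S",   20,  1.220, -0.592),
    ("Atlantic_4",     "forest",     "28°14'S",   13,  0.931,  0.932),
    ("Cerrado_1",      "non_forest", "8°50'S",    24, -0.488, -0.130),
    ("Cerrado_2",      "non_forest", "10°22'S",   27, -0.794,  0.275),
    ("Cerrado_3",      "non_forest", "15°48'S",   42,  0.941,  0.253),
    ("Cerrado_4",      "non_forest", "22°15'S",   29,  1.149, -1.173),
    ("Campos_1",       "non_forest", "29°26'S",    9,  2.743,  1.282),
    ("Campos_2",       "non_forest", "29°41'S",   18,  1.718,  0.654),
]


def snake_community_summary() -> pd.DataFrame:
    """Per-site habitat, latitude (decimal degrees S), richness, NRI, NTI."""
    df = pd.DataFrame(_ROWS, columns=["site", "habitat", "latitude",
                                      "richness", "NRI", "NTI"])
    df["latitude"] = df["latitude"].map(parse_latitude)
    return df.set_index("site")
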