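"""Published sampling layouts used in worked examples and tests.

``GREY_SEAL_WINTER_OCCUPANCY`` is the occupancy pattern of 24 adult female
grey seals sampled during the breeding season (WINTER) in two to five of the
seven seasons 1999-2004 and 2006 — the canonical unbalanced repeated-measures
layout for the harmonic-mean-k repeatability estimator (81 samples in total,
harmonic mean ~3.12).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["GREY_SEAL_WINTER_OCCUPANCY", "WINTER_YEARS", "winter_occupancy_frame"]

WINTER_YEARS = ("1999", "2000", "2001", "2002", "2003", "2004", "2006")

GREY_SEAL_WINTER_OCCUPANCY: dict[str, tuple[str, ...]] = {
    "Hg12": ("1999", "2002"),
    "Hg23": ("1999", "2000", "2001", "2002"),
    "Hg32": ("2000", "2002"),
    "Hg112": ("1999", "2000", "2001"),
    "Hg132": ("1999", "2001", "2002", "2004"),
    "Hg501": ("1999", "2001", "2004"),
    "Hg505": ("1999", "2000", "2002", "2003"),
    "Hg825": ("1999", "2000", "2002"),
    "Hg2675": ("1999", "2000", "2001", "2002"),
    "Hg3250": ("1999", "2000", "2002"),
    "Hg3263": ("1999", "2001"),
    "Hg3625": ("1999", "2001", "2003"),
    "Hg3817": ("1999", "2000", "2001", "2002"),
    "Hg3994": ("1999", "2000", "2001"),
    "Hg4374": ("1999", "2001", "2003"),
    "Hg4377": ("1999", "2000", "2003"),
    "Hg4388": ("1999", "2000", "2002"),
    "Hg4391": ("1999", "2000", "2001", "2002", "2004"),
    "Hg4393": ("1999", "2000", "2001", "2002"),
    "Hg4404": ("1999", "2000", "2002"),
    "Hg4489": ("1999", "2001", "2002", "2003", "2006"),
    "Hg4491": ("1999", "2000", "2001", "2002", "2003"),
    "Hg4735": ("1999", "2001", "2002", "2003"),
    "Hg6035": ("2001", "2002"),
}


def winter_occupancy_frame() -> pd.DataFrame:
    """Boolean seal x year occupancy table of the WINTER sampling layout."""
    data = np.zeros((len(GREY_SEAL_WINTER_OCCUPANCY), len(WINTER_YEARS)), dtype=bool)
    for i, years in enumerate(GREY_SEAL_WINTER_OCCUPANCY.values()):
        for y in years:
            data[i, WINTER_YEARS.index(y)] = True
    return pd.DataFrame(data, index=list(GREY_SEAL_WINTER_OCCUPANCY), columns=list(WINTER_YEARS))
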