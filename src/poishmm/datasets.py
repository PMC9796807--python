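"""Embedded example data.

The "arousal" series: 87 successive daily self-reports of emotional
arousal from a single tinnitus patient, collected through the Track Your
Tinnitus (TYT) mobile application.  Values are small non-negative integers
(higher = more excited); the series is a standard example of a short count
time series with regime switches and is well described by a two-state
Poisson HMM.
"""

from __future__ import annotations

import numpy as np

from .model_core import ObservationSeries

__all__ = ["load_tyt", "FIXTURES"]

_TYT = (
    6, 5, 3, 6, 4, 3, 5, 6, 6, 6, 4, 6, 6, 4, 6, 6, 6, 6, 6, 4, 6, 5,
    6, 7, 6, 5, 5, 5, 7, 6, 5, 6, 5, 6, 6, 6, 5, 6, 7, 7, 6, 7, 6, 6,
    6, 6, 5, 7, 6, 1, 6, 0, 2, 1, 6, 7, 6, 6, 6, 5, 5, 6, 6, 2, 5, 0,
    1, 1, 1, 2, 3, 1, 3, 1, 3, 0, 1, 1, 1, 4, 1, 4, 1, 2, 2, 2, 0,
)


def load_tyt() -> ObservationSeries:
    """The 87-day TYT arousal count series."""
    return ObservationSeries(np.asarray(_TYT, dtype=float))


#: Named fixtures available to the CLI via ``--data <name>``.
FIXTURES = {"tyt": load_tyt}
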