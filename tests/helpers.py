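"""Shared constants for the test suite."""

import numpy as np

PSTH_EDGES = np.arange(101) * 0.1  # 0.1 ms bins over 0-10 ms
PSTH_CENTERS = (PSTH_EDGES[:-1] + PSTH_EDGES[1:]) / 2
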