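"""Small shared numerics."""

import math


def round_half_up(x: float) -> int:
    """Round to the nearest integer with exact halves going up.

    All day counts reported by the package use this rule so that results
    do not depend on the platform's banker's rounding.
    """
    return int(math.floor(x + 0.5))
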