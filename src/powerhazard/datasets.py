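"""Bundled example dataset.

Ball-bearing fatigue endurance test: 23 bearings on test, 18 failures
observed under a fixed progressive withdrawal pattern (one unit withdrawn at
the 12th, 14th and 16th failures, two at the 18th).  Times are in units of
10**8 revolutions.  The shape parameter reported for this dataset is 0.332.
"""

from __future__ import annotations

from .censoring import CensoringScheme, ProgCensSample

__all__ = [
    "BALL_BEARING_TIMES",
    "BALL_BEARING_REMOVALS",
    "BALL_BEARING_N",
    "BALL_BEARING_BETA",
    "ball_bearing_sample",
]

BALL_BEARING_TIMES: tuple[float, ...] = (
    0.1788, 0.3300, 0.4152, 0.4560, 0.4848, 0.5186, 0.5196, 0.5412, 0.5556,
    0.6780, 0.6864, 0.8412, 0.9312, 0.9864, 1.0584, 1.2792, 1.2804, 1.7340,
)

BALL_BEARING_REMOVALS: tuple[int, ...] = (
    0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 1, 0, 2,
)

BALL_BEARING_N = 23

#: shape parameter estimated for this dataset (treated as known here)
BALL_BEARING_BETA = 0.332


def ball_bearing_sample() -> ProgCensSample:
    """The censored ball-bearing sample as a :class:`ProgCensSample`."""
    return ProgCensSample(
        scheme=CensoringScheme(n=BALL_BEARING_N, removals=BALL_BEARING_REMOVALS),
        times=BALL_BEARING_TIMES,
    )
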