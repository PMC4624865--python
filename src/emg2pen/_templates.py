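"""Hard-coded single-stroke control points for the digits 0-9.

Each template is an ordered list of (x, y) control points in a nominal
box roughly 1 unit wide and 2 units tall, traced as one continuous pen
stroke (no pen lifts). A parametric cubic spline through these points
yields the nominal trajectory; per-trial jitter is applied on top.
"""

import numpy as np

DIGIT_CONTROL_POINTS = {
    0: [  # closed oval, clockwise from the top
        (0.50, 1.90), (0.88, 1.55), (0.95, 0.95), (0.88, 0.35),
        (0.50, 0.05), (0.12, 0.35), (0.05, 0.95), (0.12, 1.55),
        (0.50, 1.90),
    ],
    1: [  # short flag, then straight down
        (0.38, 1.55), (0.50, 2.00), (0.50, 1.50), (0.50, 1.00),
        (0.50, 0.50), (0.50, 0.00),
    ],
    2: [
        (0.10, 1.60), (0.30, 1.95), (0.62, 2.00), (0.88, 1.65),
        (0.70, 1.15), (0.40, 0.70), (0.10, 0.10), (0.50, 0.05),
        (0.90, 0.00),
    ],
    3: [
        (0.15, 1.80), (0.50, 2.00), (0.85, 1.60), (0.52, 1.10),
        (0.88, 0.60), (0.50, 0.00), (0.15, 0.20),
    ],
    4: [  # diagonal, crossbar, then the stem drawn through it
        (0.62, 2.00), (0.35, 1.40), (0.12, 0.85), (0.50, 0.82),
        (0.90, 0.80), (0.70, 1.10), (0.68, 0.55), (0.66, 0.00),
    ],
    5: [
        (0.85, 2.00), (0.45, 2.00), (0.20, 1.95), (0.18, 1.50),
        (0.22, 1.25), (0.55, 1.30), (0.82, 1.00), (0.78, 0.45),
        (0.45, 0.00), (0.12, 0.20),
    ],
    6: [
        (0.80, 1.90), (0.45, 2.00), (0.22, 1.45), (0.12, 0.80),
        (0.22, 0.25), (0.50, 0.02), (0.78, 0.25), (0.80, 0.65),
        (0.55, 0.95), (0.25, 0.75),
    ],
    7: [
        (0.10, 1.90), (0.50, 2.00), (0.90, 1.95), (0.65, 1.30),
        (0.45, 0.65), (0.30, 0.00),
    ],
    8: [  # figure-eight with a crossing at mid-height
        (0.50, 1.95), (0.15, 1.55), (0.48, 1.08), (0.85, 0.58),
        (0.50, 0.05), (0.15, 0.52), (0.52, 1.02), (0.85, 1.50),
        (0.50, 1.95),
    ],
    9: [
        (0.82, 1.45), (0.55, 1.95), (0.20, 1.55), (0.28, 1.10),
        (0.62, 1.02), (0.85, 1.40), (0.78, 0.70), (0.65, 0.00),
    ],
}


def template_points(symbol: int) -> np.ndarray:
    """The (n, 2) control-point array for one digit."""
    return np.asarray(DIGIT_CONTROL_POINTS[symbol], dtype=float)
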