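"""Published summary statistics of the motivating porcine feasibility study.

These numbers are *inputs*: the per-animal recordings were never
deposited, so the summary table (per-group peak currents and tissue
thickness), the per-group success counts and the per-group threshold
means/SDs are the only anchors available.  They seed the synthetic-cohort
generator defaults and the reproduction report; nothing in the package
treats them as computed results.
"""

from __future__ import annotations

from .records_io import Group

#: animals in the study; each received all three applications
N_PIGS = 12

#: per-group peak current (mean, SD) in A, from the ablative characteristics table
GROUP_PEAK_CURRENT_A: dict[Group, tuple[float, float]] = {
    Group.SINGLE_50J: (25.3, 3.1),
    Group.SINGLE_100J: (32.4, 5.4),
    Group.SERIAL_4X50J: (22.4, 2.9),
}

#: tissue thickness between the paddles: integer-mm range spanning the
#: per-group reported ranges (4-10, 4-10, 5-12 mm)
THICKNESS_RANGE_MM: tuple[int, int] = (4, 12)

#: per-group current-density thresholds (mean, SD) in A/cm^2 as published
PUBLISHED_THRESHOLDS_A_PER_CM2: dict[Group, tuple[float, float]] = {
    Group.SINGLE_50J: (4.3, 0.8),
    Group.SINGLE_100J: (5.1, 0.9),
    Group.SERIAL_4X50J: (3.4, 0.5),
}

#: histologically successful ablations out of N_PIGS per group
SUCCESS_COUNTS: dict[Group, int] = {
    Group.SINGLE_50J: 5,
    Group.SINGLE_100J: 11,
    Group.SERIAL_4X50J: 12,
}

#: 25 mm diameter paediatric defibrillation paddles
PADDLE_RADIUS_MM = 12.5
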