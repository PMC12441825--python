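"""Counterbalanced 2x2 probabilistic-cueing trial schedules.

The design crosses *visual expectancy* (the cue orientation predicts the
target orientation with some validity, by default 75%) with *motor
expectancy* (the target appears immediately on button release with some
validity, by default 75%).  With both validities at 0.75 the four cells

    VEME (visual expected / motor expected)   : 9/16 of trials
    VEMU (visual expected / motor unexpected) : 3/16
    VUME (visual unexpected / motor expected) : 3/16
    VUMU (double violation)                   : 1/16

are balanced exactly at the experiment level, and a 720-trial session
carries 405/135/135/45 trials per cell.  ``match_trials`` equates cell
counts (and, by construction, cue-to-motor delay distributions) by keeping
the shortest-delay trials of each over-represented cell, yielding 45 trials
per cell for the default session.
"""

from __future__ import annotations

from fractions import Fraction
from math import lcm

import numpy as np
import pandas as pd

__all__ = [
    "CELLS",
    "SCHEDULE_COLUMNS",
    "generate_schedule",
    "sample_mu_delay",
    "match_trials",
    "cell_labels",
    "circular_orientation_distance",
]

#: Cell labels in canonical order: visual factor slowest, motor factor fastest.
CELLS = ("VEME", "VEMU", "VUME", "VUMU")

SCHEDULE_COLUMNS = (
    "trial_index",
    "block",
    "visual_expected",
    "motor_expected",
    "target_orientation_deg",
    "cue_orientation_deg",
    "cue_to_motor_delay_ms",
    "extra_target_delay_ms",
    "seed",
)

#: Minimum circular cue-target distance (deg) on invalid-cue trials.
MIN_INVALID_CUE_DISTANCE_DEG = 30.0


def circular_orientation_distance(a_deg, b_deg):
    """Circular distance between orientations on the 180-deg circle, in [0, 90]."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def _cell_counts(n_total: int, visual_validity: float, motor_validity: float) -> dict:
    """Exact per-cell counts, or raise if ``n_total`` cannot be split exactly."""
    pv = Fraction(visual_validity).limit_denominator(10**6)
    pm = Fraction(motor_validity).limit_denominator(10**6)
    probs = {
        "VEME": pv * pm,
        "VEMU": pv * (1 - pm),
        "VUME": (1 - pv) * pm,
        "VUMU": (1 - pv) * (1 - pm),
    }
    denominators = [p.denominator for p in probs.values() if p > 0]
    smallest_valid = lcm(*denominators)
    if n_total % smallest_valid != 0:
        raise ValueError(
            f"exact cell balancing impossible for {n_total} trials at validities "
            f"({visual_validity}, {motor_validity}); total must be a multiple of "
            f"{smallest_valid}"
        )
    return {cell: int(p * n_total) for cell, p in probs.items()}


def sample_mu_delay(delay_range_ms, rng, size=None):
    """Extra target delay for motor-unexpected trials.

    Drawn uniformly from ``(0, width/3]`` where ``width`` is the width of the
    visual-to-motor-cue delay range — one-third of the delay range, with zero
    excluded so a motor-unexpected trial always has a strictly positive delay.
    """
    lo, hi = float(delay_range_ms[0]), float(delay_range_ms[1])
    width = hi - lo
    if width <= 0:
        raise ValueError(f"delay range {delay_range_ms!r} has non-positive width")
    # 1 - U[0,1) has support (0, 1], giving the half-open interval (0, width/3]
    return (width / 3.0) * (1.0 - rng.uniform(0.0, 1.0, size=size))


def generate_schedule(
    n_blocks: int = 10,
    trials_per_block: int = 72,
    visual_validity: float = 0.75,
    motor_validity: float = 0.75,
    delay_range_ms=(250.0, 1500.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a counterbalanced trial schedule as a DataFrame.

    Cell counts are balanced exactly over the full experiment (per-block exact
    counts are impossible at 72 trials/block), and condition labels are
    pseudo-randomly interleaved across the whole session.  Target orientations
    are uniform on [0, 180); invalid cues sit at a circular distance in
    (30, 90] deg from their target; the visual-to-motor-cue delay is uniform
    on ``delay_range_ms``.  Deterministic for a fixed seed.
    """
    if not (0.0 < visual_validity <= 1.0) or not (0.0 < motor_validity <= 1.0):
        raise ValueError("validities must lie in (0, 1]")
    lo, hi = float(delay_range_ms[0]), float(delay_range_ms[1])
    if hi < lo:
        raise ValueError(f"empty delay range {delay_range_ms!r}")
    n_total = int(n_blocks) * int(trials_per_block)
    if n_total <= 0:
        raise ValueError("schedule must contain at least one trial")

    counts = _cell_counts(n_total, visual_validity, motor_validity)
    rng = np.random.default_rng(seed)

    cells = np.repeat(
        np.array(CELLS, dtype=object), [counts[c] for c in CELLS]
    )
    rng.shuffle(cells)

    visual_expected = np.isin(cells, ("VEME", "VEMU"))
    motor_expected = np.isin(cells, ("VEME", "VUME"))

    target = rng.uniform(0.0, 180.0, size=n_total)
    cue = target.copy()
    invalid = ~visual_expected
    n_invalid = int(invalid.sum())
    if n_invalid:
        # distance in (30, 90], side chosen at random, wrapped onto [0, 180)
        dist = 90.0 - rng.uniform(0.0, 60.0, size=n_invalid)
        side = rng.choice([-1.0, 1.0], size=n_invalid)
        cue[invalid] = (target[invalid] + side * dist) % 180.0

    cue_to_motor = rng.uniform(lo, hi, size=n_total)
    extra = np.zeros(n_total)
    mu = ~motor_expected
    if mu.any():
        extra[mu] = sample_mu_delay((lo, hi), rng, size=int(mu.sum()))

    return pd.DataFrame(
        {
            "trial_index": np.arange(n_total),
            "block": np.arange(n_total) // int(trials_per_block) + 1,
            "visual_expected": visual_expected,
            "motor_expected": motor_expected,
            "target_orientation_deg": target,
            "cue_orientation_deg": cue,
            "cue_to_motor_delay_ms": cue_to_motor,
            "extra_target_delay_ms": extra,
            "seed": np.full(n_total, seed, dtype=int),
        }
    )


def cell_labels(schedule: pd.DataFrame) -> np.ndarray:
    """Per-trial cell label ('VEME', 'VEMU', 'VUME', 'VUMU')."""
    v = np.where(schedule["visual_expected"].to_numpy(), "VE", "VU")
    m = np.where(schedule["motor_expected"].to_numpy(), "ME", "MU")
    return np.char.add(v, m)


def match_trials(schedule: pd.DataFrame) -> pd.DataFrame:
    """Equate trial counts (and delay distributions) across the four cells.

    Within each over-represented cell only the trials with the shortest
    visual-to-motor-cue delays are retained (ties broken by trial index), so
    that omitting the long-delay surplus of the expected cells matches both
    the number and the delay profile of trials across conditions.  The result
    preserves the original trial order and is idempotent.
    """
    labels = cell_labels(schedule)
    counts = {c: int((labels == c).sum()) for c in CELLS}
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"cannot match trials: empty cell(s) {empty}")
    n_keep = min(counts.values())

    keep = np.zeros(len(schedule), dtype=bool)
    delays = schedule["cue_to_motor_delay_ms"].to_numpy()
    idx = schedule["trial_index"].to_numpy()
    for cell in CELLS:
        members = np.flatnonzero(labels == cell)
        order = np.lexsort((idx[members], delays[members]))
        keep[members[order[:n_keep]]] = True
    return schedule.loc[keep].copy()
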