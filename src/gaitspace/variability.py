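"""Step-to-step variability of interlimb phase differences.

For each limb pair the sequence of phase differences (radians) within a
bout is smoothed with a circular exponential moving average

    S_0 = phi_0,    S_n = S_{n-1} + alpha * arg(exp(i (phi_n - S_{n-1})))

whose smoothing factor alpha derives from a cutoff frequency f_c (in units
of 1/step-cycles) as alpha = 2*pi*f_c / (2*pi*f_c + 1).  The per-bout
variability statistic ("madev") is the mean deviation of the phases from
their moving average, normalized by pi so it lies in [0, 1].

Because the moving average tracks systematic phase changes, an ordered gait
transition (a step change in the phase difference that then holds)
contributes less to madev than persistent or random drift of the same total
size -- which is what makes it a useful proxy for interlimb coupling
strength.

Two variants of the statistic are provided.  The default, ``abs-inside``,
averages the magnitudes of the wrapped deviations; the ``as-written``
variant takes the magnitude of the *summed* signed deviations, under which
deviations of opposite sign cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cycles import StepCycle

__all__ = [
    "LIMB_PAIRS",
    "DEFAULT_CUTOFF",
    "VariabilityResult",
    "ema_alpha",
    "circular_ema",
    "mean_deviation",
    "pair_phase_sequences",
    "bout_variability",
    "variability_frame",
]

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

#: default cutoff frequency, in units of 1/step-cycles
DEFAULT_CUTOFF = 0.125

#: the six limb pairs whose phase differences are tracked
LIMB_PAIRS = (
    "hind_lr",
    "fore_lr",
    "homolateral_left",
    "homolateral_right",
    "diagonal_lh_rf",
    "diagonal_rh_lf",
)


def ema_alpha(f_c: float) -> float:
    """Smoothing factor of the EMA for a cutoff frequency f_c > 0."""
    if not f_c > 0:
        raise ValueError(f"cutoff frequency must be positive, got {f_c}")
    w = f_c * TWO_PI
    return w / (w + 1.0)


def _wrap(x: np.ndarray | float) -> np.ndarray | float:
    """Principal value of an angle, in (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(x, dtype=float)))


def circular_ema(phases_rad: Sequence[float], alpha: float) -> np.ndarray:
    """Circular exponential moving average of an angle sequence.

    The innovation (phi_n - S_{n-1}) is wrapped to its principal value so
    the average always takes the short way around the circle; S itself is
    left unwrapped and may leave [0, 2*pi).
    """
    phases = np.asarray(phases_rad, dtype=float)
    if phases.size == 0:
        raise ValueError("circular_ema requires a non-empty sequence")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    out = np.empty_like(phases)
    out[0] = phases[0]
    for n in range(1, phases.size):
        out[n] = out[n - 1] + alpha * _wrap(phases[n] - out[n - 1])
    return out


def mean_deviation(
    phases_rad: Sequence[float],
    moving_average: Sequence[float],
    variant: str = "abs-inside",
) -> float:
    """Normalized mean deviation of phases from their moving average.

    ``abs-inside`` (default) averages |arg(exp(i(phi_n - S_n)))| and divides
    by pi, yielding a magnitude in [0, 1].  ``as-written`` instead takes the
    absolute value of the *sum* of the signed wrapped deviations before
    normalizing, under which symmetric deviations cancel.
    """
    phases = np.asarray(phases_rad, dtype=float)
    avg = np.asarray(moving_average, dtype=float)
    if phases.shape != avg.shape:
        raise ValueError(
            f"length mismatch: {phases.shape} phases vs {avg.shape} averages"
        )
    dev = _wrap(phases - avg)
    if variant == "abs-inside":
        return float(np.sum(np.abs(dev)) / (np.pi * dev.size))
    if variant == "as-written":
        return float(np.abs(np.sum(dev)) / (np.pi * dev.size))
    raise ValueError(f"unknown madev variant {variant!r}")


def pair_phase_sequences(
    cycles: Sequence[StepCycle],
) -> dict[str, np.ndarray]:
    """Normalized phase-difference sequences for the six limb pairs.

    All pairs are derived from the per-cycle phase vector (LR, HL, DIAG)
    relative to the left hindlimb:

    - hind left-right: LR
    - fore left-right: (DIAG - HL) mod 1
    - left homolateral (LH-LF): HL
    - right homolateral (RH-RF): (DIAG - LR) mod 1
    - diagonal LH-RF: DIAG
    - diagonal RH-LF: (HL - LR) mod 1
    """
    lr = np.array([c.phi_lr for c in cycles])
    hl = np.array([c.phi_hl for c in cycles])
    diag = np.array([c.phi_diag for c in cycles])
    return {
        "hind_lr": lr,
        "fore_lr": (diag - hl) % 1.0,
        "homolateral_left": hl,
        "homolateral_right": (diag - lr) % 1.0,
        "diagonal_lh_rf": diag,
        "diagonal_rh_lf": (hl - lr) % 1.0,
    }


@dataclass
class VariabilityResult:
    """madev of one limb pair over one bout, with the EMA trace."""

    bout_id: str
    animal_id: str
    condition: str
    limb_pair: str
    f_c: float
    alpha: float
    madev: float
    variant: str
    phases_rad: np.ndarray
    moving_average: np.ndarray


def bout_variability(
    cycles: Sequence[StepCycle],
    f_c: float = DEFAULT_CUTOFF,
    variant: str = "abs-inside",
) -> list[VariabilityResult]:
    """Circular-EMA variability of all six limb pairs for one bout.

    Returns an empty list (with a log diagnostic) for bouts with fewer than
    two step cycles, which carry no step-to-step variability information.
    """
    cycles = list(cycles)
    if len(cycles) < 2:
        bout = cycles[0].bout_id if cycles else "<empty>"
        log.info("bout %s skipped: fewer than two step cycles", bout)
        return []
    alpha = ema_alpha(f_c)
    first = cycles[0]
    results = []
    for pair, phases_cyc in pair_phase_sequences(cycles).items():
        phases_rad = TWO_PI * phases_cyc
        trace = circular_ema(phases_rad, alpha)
        results.append(
            VariabilityResult(
                bout_id=first.bout_id,
                animal_id=first.animal_id,
                condition=first.condition,
                limb_pair=pair,
                f_c=f_c,
                alpha=alpha,
                madev=mean_deviation(phases_rad, trace, variant),
                variant=variant,
                phases_rad=phases_rad,
                moving_average=trace,
            )
        )
    return results


def variability_frame(results: Iterable[VariabilityResult]) -> pd.DataFrame:
    """Tabulate variability results (one row per bout x limb pair)."""
    return pd.DataFrame.from_records(
        [
            {
                "bout_id": r.bout_id,
                "animal_id": r.animal_id,
                "condition": r.condition,
                "limb_pair": r.limb_pair,
                "f_c": r.f_c,
                "alpha": r.alpha,
                "madev": r.madev,
                "variant": r.variant,
            }
            for r in results
        ],
        columns=[
            "bout_id", "animal_id", "condition", "limb_pair",
            "f_c", "alpha", "madev", "variant",
        ],
    )
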