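"""Step-cycle extraction and per-cycle locomotor parameters.

A step cycle is delimited by two consecutive midstance times of the
reference limb (the left hindlimb unless stated otherwise).  Within each
cycle we compute, per limb, the stance and swing durations, the duty factor
(stance duration divided by the cycle period), the stride length (Euclidean
distance between consecutive contact points of the same limb), and the
normalized phase difference of its midstance relative to the reference.
The three-component phase vector

    Phi = (phi_LR, phi_HL, phi_DIAG)

collects the phases of the right hindlimb, the left forelimb and the right
forelimb relative to the left hindlimb; it is the coordinate used by the
gait classifier and the phase-space continuum models.

Cycles in which any limb does not contribute exactly one midstance, or in
which a limb lacks the previous contact needed for a stride length or the
next stance needed for a swing duration, are dropped and counted in the
returned diagnostics, mirroring the fact that such steps cannot be
parameterized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Bout, Limb, StanceInterval

__all__ = [
    "LimbTiming",
    "StepCycle",
    "ExtractionResult",
    "extract_step_cycles",
    "normalized_phase",
    "forelimb_lr_phase",
    "maximal_speed",
    "support_pattern",
    "cycles_to_frame",
    "per_gait_summary",
]

#: order of the non-reference phases in the phase vector (LH-referenced)
PHASE_LIMBS = (Limb.RH, Limb.LF, Limb.RF)


@dataclass(frozen=True)
class LimbTiming:
    """Per-limb timing and spatial parameters within one step cycle."""

    limb: Limb
    onset_s: float
    offset_s: float
    midstance_s: float
    stance_s: float
    swing_s: float
    duty_factor: float
    stride_cm: float
    phase: float  #: normalized phase relative to the reference limb, in [0, 1)


@dataclass(frozen=True)
class StepCycle:
    """One reference-limb step cycle with all derived parameters."""

    bout_id: str
    animal_id: str
    condition: str
    index_in_bout: int
    reference_limb: Limb
    t_start_s: float
    t_end_s: float
    period_s: float
    frequency_hz: float
    limbs: Mapping[Limb, LimbTiming]
    mean_duty_factor: float
    instantaneous_speed_cm_s: float
    #: (phi_LR, phi_HL, phi_DIAG) relative to the left hindlimb
    phase_point: tuple[float, float, float]
    touchdown_order: tuple[Limb, ...]

    @property
    def phi_lr(self) -> float:
        return self.phase_point[0]

    @property
    def phi_hl(self) -> float:
        return self.phase_point[1]

    @property
    def phi_diag(self) -> float:
        return self.phase_point[2]

    @property
    def phi_flr(self) -> float:
        """Forelimb left-right phase, (phi_DIAG - phi_HL) mod 1."""
        return forelimb_lr_phase(self.phase_point)


@dataclass
class ExtractionResult:
    """Extracted cycles plus a per-reason count of dropped candidates."""

    cycles: list[StepCycle]
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def _drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1


def normalized_phase(t_mid_ref: float, t_mid_other: float, period_s: float) -> float:
    """Delay between two midstance times divided by the period, mod 1."""
    if not period_s > 0:
        raise ValueError(f"period must be positive, got {period_s}")
    return ((t_mid_other - t_mid_ref) / period_s) % 1.0


def forelimb_lr_phase(phase_point: Sequence[float]) -> float:
    """Forelimb left-right phase from the three LH-referenced phases.

    The three phase differences of the phase vector determine the fourth:
    phi_FLR = (phi_DIAG - phi_HL) mod 1.
    """
    _, phi_hl, phi_diag = phase_point
    return (phi_diag - phi_hl) % 1.0


def maximal_speed(speeds: Sequence[float]) -> float:
    """Maximal locomotor speed: 95th percentile of instantaneous speeds."""
    arr = np.asarray(speeds, dtype=float)
    if arr.size == 0:
        raise ValueError("maximal_speed requires at least one speed")
    return float(np.percentile(arr, 95))


def extract_step_cycles(
    bout: Bout, reference_limb: Limb = Limb.LH
) -> ExtractionResult:
    """Extract all complete step cycles of a bout.

    One cycle candidate is formed per consecutive pair of reference-limb
    midstances. A candidate is kept only if every limb has exactly one
    midstance in the half-open window ``[t_start, t_end)``, a previous
    contact (for the stride length) and a following stance (for the swing
    duration); otherwise it is dropped and counted by reason.
    """
    result = ExtractionResult(cycles=[])
    per_limb: dict[Limb, list[StanceInterval]] = {
        limb: list(bout.intervals_for(limb)) for limb in Limb
    }
    ref_stances = per_limb[reference_limb]
    if len(ref_stances) < 2:
        result._drop("reference_limb_fewer_than_two_stances")
        return result

    mids = {
        limb: np.array([s.midstance_s for s in stances])
        for limb, stances in per_limb.items()
    }

    ref_mids = mids[reference_limb]
    for k in range(len(ref_stances) - 1):
        t0, t1 = float(ref_mids[k]), float(ref_mids[k + 1])
        period = t1 - t0
        timings: dict[Limb, LimbTiming] = {}
        reason = None
        for limb in Limb:
            stances = per_limb[limb]
            lo = int(np.searchsorted(mids[limb], t0, side="left"))
            hi = int(np.searchsorted(mids[limb], t1, side="left"))
            if hi - lo != 1:
                reason = "no_unique_midstance_in_window"
                break
            i = lo
            if i == 0:
                reason = "no_previous_contact_for_stride"
                break
            if i + 1 >= len(stances):
                reason = "no_next_stance_for_swing"
                break
            cur, prev, nxt = stances[i], stances[i - 1], stances[i + 1]
            stride = float(
                np.hypot(
                    cur.contact_x_cm - prev.contact_x_cm,
                    cur.contact_y_cm - prev.contact_y_cm,
                )
            )
            stance = cur.duration_s
            swing = nxt.onset_s - cur.offset_s
            duty = stance / period
            if not 0.0 < duty < 1.0:
                reason = "duty_factor_out_of_range"
                break
            timings[limb] = LimbTiming(
                limb=limb,
                onset_s=cur.onset_s,
                offset_s=cur.offset_s,
                midstance_s=cur.midstance_s,
                stance_s=stance,
                swing_s=swing,
                duty_factor=duty,
                stride_cm=stride,
                phase=normalized_phase(t0, cur.midstance_s, period),
            )
        if reason is not None:
            result._drop(reason)
            continue

        # re-express phases relative to the left hindlimb so the phase
        # vector always has the (LR, HL, DIAG) template semantics
        phi_lh = timings[Limb.LH].phase
        phase_point = tuple(
            (timings[l].phase - phi_lh) % 1.0 for l in PHASE_LIMBS
        )
        order = tuple(sorted(Limb, key=lambda l: timings[l].onset_s))
        speed = float(
            np.mean([timings[l].stride_cm for l in Limb]) / period
        )
        result.cycles.append(
            StepCycle(
                bout_id=bout.bout_id,
                animal_id=bout.animal_id,
                condition=bout.condition,
                index_in_bout=k,
                reference_limb=reference_limb,
                t_start_s=t0,
                t_end_s=t1,
                period_s=period,
                frequency_hz=1.0 / period,
                limbs=timings,
                mean_duty_factor=float(
                    np.mean([timings[l].duty_factor for l in Limb])
                ),
                instantaneous_speed_cm_s=speed,
                phase_point=phase_point,  # type: ignore[arg-type]
                touchdown_order=order,
            )
        )
    return result


def support_pattern(bout: Bout, cycle: StepCycle) -> tuple[float, ...]:
    """Proportions of the cycle spent with 0..4 limbs on the ground.

    All stance intervals of the bout are clipped to the cycle window (so
    stances entering from neighbouring cycles are counted), and the window
    is swept to accumulate the time with each possible number of supporting
    limbs. The five proportions sum to one; a nonzero proportion at zero
    limbs marks a suspension phase.
    """
    t0, t1 = cycle.t_start_s, cycle.t_end_s
    clipped = [
        (max(s.onset_s, t0), min(s.offset_s, t1))
        for s in bout.intervals
        if s.onset_s < t1 and s.offset_s > t0
    ]
    events = sorted({t0, t1, *(a for a, _ in clipped), *(b for _, b in clipped)})
    totals = [0.0] * 5
    for a, b in zip(events, events[1:]):
        mid = 0.5 * (a + b)
        n = sum(1 for lo, hi in clipped if lo <= mid < hi)
        totals[n] += b - a
    period = t1 - t0
    return tuple(t / period for t in totals)


def cycles_to_frame(
    cycles: Iterable[StepCycle], labels: Sequence | None = None
) -> pd.DataFrame:
    """Tabulate step cycles (optionally with their gait labels) as a DataFrame."""
    records = []
    for cyc in cycles:
        rec = {
            "bout_id": cyc.bout_id,
            "animal_id": cyc.animal_id,
            "condition": cyc.condition,
            "index_in_bout": cyc.index_in_bout,
            "reference_limb": cyc.reference_limb.value,
            "t_start_s": cyc.t_start_s,
            "t_end_s": cyc.t_end_s,
            "period_s": cyc.period_s,
            "frequency_hz": cyc.frequency_hz,
            "speed_cm_s": cyc.instantaneous_speed_cm_s,
            "mean_duty_factor": cyc.mean_duty_factor,
            "phi_lr": cyc.phi_lr,
            "phi_hl": cyc.phi_hl,
            "phi_diag": cyc.phi_diag,
            "phi_flr": cyc.phi_flr,
        }
        for limb in Limb:
            t = cyc.limbs[limb]
            tag = limb.value.lower()
            rec[f"stance_s_{tag}"] = t.stance_s
            rec[f"swing_s_{tag}"] = t.swing_s
            rec[f"duty_{tag}"] = t.duty_factor
            rec[f"stride_cm_{tag}"] = t.stride_cm
        rec["stride_length_cm"] = float(
            np.mean([cyc.limbs[l].stride_cm for l in Limb])
        )
        for girdle, pair in (("hind", (Limb.LH, Limb.RH)), ("fore", (Limb.LF, Limb.RF))):
            rec[f"{girdle}_duty_factor"] = 0.5 * sum(
                cyc.limbs[l].duty_factor for l in pair
            )
            rec[f"{girdle}_stance_s"] = 0.5 * sum(cyc.limbs[l].stance_s for l in pair)
            rec[f"{girdle}_swing_s"] = 0.5 * sum(cyc.limbs[l].swing_s for l in pair)
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    if labels is not None:
        labels = list(labels)
        if len(labels) != len(frame):
            raise ValueError("labels and cycles have different lengths")
        frame["gait"] = [lab.category for lab in labels]
        frame["template_distance"] = [lab.distance for lab in labels]
        frame["lead_forelimb"] = [
            lab.lead_forelimb.value if lab.lead_forelimb else "" for lab in labels
        ]
        frame["lead_hindlimb"] = [
            lab.lead_hindlimb.value if lab.lead_hindlimb else "" for lab in labels
        ]
    return frame


def per_gait_summary(labeled: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of speed, frequency, stride length and duty factor,
    grouped by condition and gait category."""
    cols = ["speed_cm_s", "frequency_hz", "stride_length_cm", "mean_duty_factor"]
    if labeled.empty:
        idx = pd.MultiIndex.from_arrays([[], []], names=["condition", "gait"])
        return pd.DataFrame(
            columns=[f"{c}_{s}" for c in cols for s in ("mean", "std")] + ["n"],
            index=idx,
        )
    grouped = labeled.groupby(["condition", "gait"])[cols]
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{c}_{s}" for c, s in out.columns]
    out["n"] = grouped.size()
    return out
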