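"""Synthetic footfall generator for intact and spinal-cord-injured gait.

The generator produces bouts of stance intervals with the statistical
structure the analysis pipeline assumes, together with ground truth for
every downstream stage (intended gait, phase triple, duty factors, speed
and lead limbs per cycle), so that extraction, classification, variability
and continuum fitting can be validated end to end.

Construction of a bout
----------------------
Reference-limb (left hindlimb) midstance times follow from a per-cycle
speed profile: the stride length follows a linear law in speed, and the
period is stride/speed.  Every other limb's midstance is placed at
``reference + phase * period``, where the phase is the intended gait
template plus von Mises noise (or, in contusion mode, a drifting latent
phase); stance intervals are centered on the midstances with duration
``duty * period`` (duty linear in speed, with an optional left-minus-right
hindlimb offset), which makes midstance-based extraction exact by
construction.  Contact positions advance by the per-cycle stride along the
runway; the lateral position is fixed per limb.

Presets
-------
``intact``
    full gait repertoire selected by speed (thresholds at midpoints between
    the per-gait mean speeds), left forelimb leading asymmetric gaits in
    ~37% of cycles.
``hemisection``
    no half-bound or bound; ~96.5% left-lead asymmetric steps; hind and
    fore left-right phases during trot biased to ~0.55; left-minus-right
    hindlimb duty asymmetry; reduced top speed.
``contusion``
    left-right phases locked near alternation (0.5) with von Mises noise
    while the homolateral phase performs a wrapped Gaussian random walk and
    the diagonal phase follows it half a cycle away -- the trot-pace
    continuum with weakened fore-hind coupling; low speed range.

Two extra cycles per bout (a lead-in and a trailing one) are generated so
that every one of the ``cycles_per_bout`` configured cycles has the
previous contact and following stance the extractor requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gaits import classify_phases, mirror_point
from .io import Bout, BoutValidationError, Limb, StanceInterval

__all__ = [
    "GAIT_MEAN_SPEEDS",
    "GAIT_TEMPLATES_LEFT",
    "ASYMMETRIC_GAITS",
    "GeneratorConfig",
    "GeneratedBout",
    "GenerationError",
    "speed_thresholds",
    "contusion_phase_sample",
    "simulate_bout",
    "simulate_cohort",
    "truth_table",
    "preset",
]

TWO_PI = 2.0 * np.pi

#: mean locomotor speed (cm/s) at which each gait is expressed
GAIT_MEAN_SPEEDS: dict[str, float] = {
    "walk": 77.1,
    "trot": 100.5,
    "canter": 106.3,
    "gallop": 122.4,
    "half-bound": 141.0,
    "bound": 173.9,
}

#: left-lead phase-triple templates (cycles) for the generated gaits
GAIT_TEMPLATES_LEFT: dict[str, tuple[float, float, float]] = {
    "walk": (0.5, 0.25, 0.75),        # lateral-sequence walk
    "trot": (0.5, 0.5, 0.0),
    "canter": (2 / 3, 1 / 3, 0.0),
    "gallop": (0.75, 0.5, 0.25),      # transverse gallop
    "half-bound": (0.0, 2 / 3, 1 / 3),
    "bound": (0.0, 0.5, 0.5),
    "pace": (0.5, 0.0, 0.5),
    "pronk": (0.0, 0.0, 0.0),
}

#: gaits with distinct left/right-lead forms (subject to the lead bias)
ASYMMETRIC_GAITS = frozenset({"canter", "gallop", "half-bound"})

_Y_OFFSETS = {Limb.LH: 1.5, Limb.RH: -1.5, Limb.LF: 2.0, Limb.RF: -2.0}
_X_OFFSETS = {Limb.LH: 0.0, Limb.RH: 0.0, Limb.LF: 9.0, Limb.RF: 9.0}


class GenerationError(ValueError):
    """The configuration produces physically impossible footfall timing."""


def speed_thresholds(
    gaits: Sequence[str] = ("walk", "trot", "canter", "gallop", "half-bound", "bound"),
) -> tuple[tuple[float, str], ...]:
    """Speed-to-gait rule with boundaries at midpoints between the
    per-gait mean speeds; the last gait is open-ended."""
    means = [GAIT_MEAN_SPEEDS[g] for g in gaits]
    if sorted(means) != means:
        raise ValueError("gaits must be ordered by increasing mean speed")
    rule = [
        (0.5 * (means[i] + means[i + 1]), gaits[i]) for i in range(len(gaits) - 1)
    ]
    rule.append((math.inf, gaits[-1]))
    return tuple(rule)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    ``speed_profile`` is either a ``(start, end)`` ramp applied within every
    bout or an explicit per-cycle speed sequence of length
    ``cycles_per_bout``.  ``gait_rule`` is either a fixed gait name or a
    sequence of ``(upper_speed, gait)`` thresholds (first match wins);
    ``None`` selects the full-repertoire threshold rule.  Phase noise is
    von Mises with concentration ``kappa`` on each limb's phase
    independently; ``phase_noise=False`` is the noiseless limit.
    """

    seed: int = 0
    condition: str = "intact"
    n_animals: int = 3
    bouts_per_animal: int = 5
    cycles_per_bout: int = 10
    speed_profile: tuple[float, float] | Sequence[float] = (60.0, 180.0)
    speed_jitter_cm_s: float = 3.0
    gait_rule: str | Sequence[tuple[float, str]] | None = None
    phase_templates: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(GAIT_TEMPLATES_LEFT)
    )
    kappa: float = 100.0
    phase_noise: bool = True
    #: duty factor = duty_law[0] + duty_law[1] * speed
    duty_law: tuple[float, float] = (0.66345, -0.00186)
    #: stride length (cm) = stride_law[0] + stride_law[1] * speed
    stride_law: tuple[float, float] = (10.64, 0.1088)
    #: probability that the left forelimb leads an asymmetric gait
    lead_bias: float = 0.374
    #: (hind, fore) left-right phase means during trot, if biased
    lr_trot_bias: tuple[float, float] | None = None
    #: "coupled" phase templates or a "random_walk" of the homolateral phase
    fore_hind_mode: str = "coupled"
    #: per-cycle step SD (cycles) of the homolateral random walk
    random_walk_sd: float = 0.05
    #: mean hind left-right phase in random-walk mode
    lr_center: float = 0.5
    #: additive left-minus-right hindlimb duty-factor offset
    duty_asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.lead_bias <= 1.0:
            raise ValueError("lead_bias must be a probability")
        if self.fore_hind_mode not in ("coupled", "random_walk"):
            raise ValueError(f"unknown fore_hind_mode {self.fore_hind_mode!r}")

    def resolved_gait_rule(self) -> str | tuple[tuple[float, str], ...]:
        if self.gait_rule is None:
            return speed_thresholds()
        if isinstance(self.gait_rule, str):
            return self.gait_rule
        return tuple((float(v), g) for v, g in self.gait_rule)


@dataclass
class GeneratedBout:
    """A synthetic bout together with its per-cycle ground truth."""

    bout: Bout
    truth: pd.DataFrame


def _wrap_half(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap to (-0.5, 0.5] cycles."""
    w = np.asarray(x, dtype=float) - np.floor(np.asarray(x, dtype=float) + 0.5)
    return np.where(w == -0.5, 0.5, w)


def _leads_from_phases(
    phi: Sequence[float], tol: float = 1e-9
) -> tuple[Limb | None, Limb | None]:
    """Intended lead limbs implied by a phase triple (None when the pair is
    synchronous or exactly alternating)."""
    lr, hl, diag = phi
    flr = (diag - hl) % 1.0

    def lead(delta: float, first: Limb, second: Limb) -> Limb | None:
        if min(delta, 1.0 - delta) < tol or abs(delta - 0.5) < tol:
            return None
        return second if delta < 0.5 else first

    return lead(flr, Limb.LF, Limb.RF), lead(lr, Limb.LH, Limb.RH)


def contusion_phase_sample(
    n: int,
    rng: np.random.Generator,
    step_sd: float = 0.05,
    kappa: float = 100.0,
    lr_center: float = 0.5,
    start_hl: float = 0.5,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Phase triples of the contusion drift process.

    The hind and fore left-right phases stay von Mises around ``lr_center``
    and 0.5 while the homolateral phase performs an (unwrapped) Gaussian
    random walk; the diagonal phase follows the homolateral one half a
    cycle away, so the triples drift along the trot-pace continuum.

    Returns ``(noisy, latent)``: the observed triples (LR, HL, DIAG) and the
    noiseless latent ones, both as (n, 3) arrays in cycles (unwrapped: the
    homolateral component is a cumulative walk).
    """
    h = start_hl + np.concatenate([[0.0], np.cumsum(rng.normal(0.0, step_sd, n - 1))])
    if noise:
        d_lr = rng.vonmises(0.0, kappa, n) / TWO_PI
        d_hl = rng.vonmises(0.0, kappa, n) / TWO_PI
        d_flr = rng.vonmises(0.0, kappa, n) / TWO_PI
    else:
        d_lr = d_hl = d_flr = np.zeros(n)
    lr = lr_center + d_lr
    hl = h + d_hl
    diag = hl + 0.5 + d_flr  # fore left-right phase = 0.5 + noise, exactly
    latent = np.stack([np.full(n, lr_center), h, h + 0.5], axis=1)
    return np.stack([lr, hl, diag], axis=1), latent


def _intended_phases(
    cfg: GeneratorConfig, speeds: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-cycle (noisy, latent, gait-name) phase plan for one bout."""
    n = speeds.size
    if cfg.fore_hind_mode == "random_walk":
        noisy, latent = contusion_phase_sample(
            n, rng, step_sd=cfg.random_walk_sd, kappa=cfg.kappa,
            lr_center=cfg.lr_center, noise=cfg.phase_noise,
        )
        return noisy, latent, ["drift"] * n

    rule = cfg.resolved_gait_rule()
    names: list[str] = []
    latent = np.empty((n, 3))
    # the lead limb persists within a bout (as it does in real gallop runs);
    # across bouts the left-lead fraction of asymmetric cycles equals the bias
    left_lead = bool(rng.random() < cfg.lead_bias)
    for i, v in enumerate(speeds):
        if isinstance(rule, str):
            gait = rule
        else:
            gait = next(g for upper, g in rule if v < upper)
        template = np.asarray(cfg.phase_templates[gait], dtype=float)
        if gait == "trot" and cfg.lr_trot_bias is not None:
            hind_bias, fore_bias = cfg.lr_trot_bias
            template = np.array([hind_bias, 0.5, (0.5 + fore_bias) % 1.0])
        if gait in ASYMMETRIC_GAITS and not left_lead:
            template = np.asarray(mirror_point(template))
        latent[i] = template
        names.append(gait)
    if cfg.phase_noise:
        noisy = latent + rng.vonmises(0.0, cfg.kappa, (n, 3)) / TWO_PI
    else:
        noisy = latent.copy()
    return noisy, latent, names


def simulate_bout(
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
    bout_id: str = "b1",
    animal_id: str = "A1",
) -> GeneratedBout:
    """Generate one bout of stance intervals plus its ground-truth table."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n_cycles = cfg.cycles_per_bout
    if n_cycles < 1:
        raise ValueError("cycles_per_bout must be at least 1")
    n_windows = n_cycles + 1  # window 0 is the lead-in

    # per-window speeds: ramp (or explicit profile) over the analyzable
    # cycles, the lead-in window repeating the first speed
    if isinstance(cfg.speed_profile, tuple) and len(cfg.speed_profile) == 2 \
            and np.isscalar(cfg.speed_profile[0]):
        core = np.linspace(cfg.speed_profile[0], cfg.speed_profile[1], n_cycles)
    else:
        core = np.asarray(cfg.speed_profile, dtype=float)
        if core.size != n_cycles:
            raise ValueError(
                f"speed_profile sequence must have length {n_cycles}"
            )
    if cfg.speed_jitter_cm_s > 0:
        core = core + rng.normal(0.0, cfg.speed_jitter_cm_s, core.size)
    core = np.clip(core, 5.0, None)
    speeds = np.concatenate([[core[0]], core])  # length n_windows

    strides = cfg.stride_law[0] + cfg.stride_law[1] * speeds
    if np.any(strides <= 0):
        raise GenerationError("stride law yields non-positive stride lengths")
    periods = strides / speeds
    t_ref = np.concatenate([[0.2], 0.2 + np.cumsum(periods)])  # n_windows + 1

    duty_base = cfg.duty_law[0] + cfg.duty_law[1] * speeds
    duties = {
        Limb.LH: duty_base + 0.5 * cfg.duty_asymmetry,
        Limb.RH: duty_base - 0.5 * cfg.duty_asymmetry,
        Limb.LF: duty_base,
        Limb.RF: duty_base,
    }
    for limb, d in duties.items():
        if np.any(d <= 0.0) or np.any(d >= 1.0):
            raise GenerationError(
                f"duty law leaves (0, 1) for limb {limb.value} over the speed range"
            )

    noisy, latent, gait_names = _intended_phases(cfg, speeds, rng)

    # place midstances; non-reference limbs track their (unwrapped) phase so
    # consecutive stances always keep close to one period of separation
    comp_of = {Limb.RH: 0, Limb.LF: 1, Limb.RF: 2}
    mids: dict[Limb, np.ndarray] = {}
    n_stances = n_windows + 1  # one trailing stance per limb
    mids[Limb.LH] = t_ref[:n_stances]
    for limb, c in comp_of.items():
        psi = np.empty(n_stances)
        psi[0] = noisy[0, c]
        targets = np.concatenate([noisy[1:, c], [noisy[-1, c]]])
        for k in range(1, n_stances):
            psi[k] = psi[k - 1] + float(_wrap_half(targets[k - 1] - psi[k - 1]))
        period_of = np.concatenate([periods, [periods[-1]]])
        mids[limb] = t_ref[:n_stances] + psi * period_of

    intervals = []
    for limb in Limb:
        duty = np.concatenate([duties[limb], [duties[limb][-1]]])
        width = duty * np.concatenate([periods, [periods[-1]]])
        x = _X_OFFSETS[limb] + np.concatenate(
            [[0.0], np.cumsum(np.concatenate([strides[1:], [strides[-1]]]))]
        )
        for k in range(n_stances):
            intervals.append(
                StanceInterval(
                    limb=limb,
                    onset_s=mids[limb][k] - 0.5 * width[k],
                    offset_s=mids[limb][k] + 0.5 * width[k],
                    contact_x_cm=float(x[k]),
                    contact_y_cm=_Y_OFFSETS[limb],
                )
            )
    try:
        bout = Bout(
            bout_id=bout_id,
            animal_id=animal_id,
            condition=cfg.condition,
            intervals=tuple(intervals),
        )
    except BoutValidationError as err:
        raise GenerationError(
            f"configuration produces overlapping stances: {err}"
        ) from err

    truth_rows = []
    for k in range(1, n_windows):
        phi = tuple(float(p % 1.0) for p in latent[k])
        _, category, _, _ = classify_phases(phi, float(duty_base[k]))
        gait = gait_names[k]
        if gait in ASYMMETRIC_GAITS or gait == "drift":
            lead_fore, lead_hind = _leads_from_phases(phi)
        else:
            lead_fore = lead_hind = None
        truth_rows.append(
            {
                "bout_id": bout_id,
                "animal_id": animal_id,
                "condition": cfg.condition,
                "cycle_index": k,
                "intended_gait": gait,
                "intended_category": category,
                "phi_lr": phi[0],
                "phi_hl": phi[1],
                "phi_diag": phi[2],
                "intended_duty": float(duty_base[k]),
                "speed_cm_s": float(speeds[k]),
                "lead_fore": lead_fore.value if lead_fore else "",
                "lead_hind": lead_hind.value if lead_hind else "",
            }
        )
    return GeneratedBout(bout=bout, truth=pd.DataFrame(truth_rows))


def simulate_cohort(cfg: GeneratorConfig) -> list[GeneratedBout]:
    """Generate a cohort: independent noise substreams per animal and bout,
    all derived from the master seed."""
    master = np.random.SeedSequence(cfg.seed)
    out = []
    for a, animal_seq in enumerate(master.spawn(cfg.n_animals), start=1):
        animal_id = f"A{a}"
        for b, bout_seq in enumerate(animal_seq.spawn(cfg.bouts_per_animal), start=1):
            out.append(
                simulate_bout(
                    cfg,
                    rng=np.random.default_rng(bout_seq),
                    bout_id=f"{animal_id}-b{b}",
                    animal_id=animal_id,
                )
            )
    return out


def truth_table(bouts: Sequence[GeneratedBout]) -> pd.DataFrame:
    """Concatenated ground-truth table of a generated cohort."""
    if not bouts:
        return pd.DataFrame()
    return pd.concat([g.truth for g in bouts], ignore_index=True)


_PRESETS: dict[str, dict] = {
    "intact": {},
    "hemisection": {
        "condition": "hemisection",
        "speed_profile": (50.0, 130.0),
        "gait_rule": None,  # filled below: repertoire without half-bound/bound
        "lead_bias": 0.965,
        "lr_trot_bias": (0.549, 0.546),
        "duty_asymmetry": 0.03,
        "duty_law": (0.70, -0.00232),
        "stride_law": (11.1, 0.10),
    },
    "contusion": {
        "condition": "contusion",
        "speed_profile": (40.0, 100.0),
        "fore_hind_mode": "random_walk",
        "duty_law": (0.65, -0.0018),
        "stride_law": (14.25, 0.05),
    },
}


def preset(name: str, **overrides) -> GeneratorConfig:
    """Generator configuration for the ``intact``, ``hemisection`` or
    ``contusion`` condition; keyword overrides are applied on top."""
    if name not in _PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; expected one of {sorted(_PRESETS)}"
        )
    kwargs = dict(_PRESETS[name])
    if name == "hemisection":
        kwargs["gait_rule"] = speed_thresholds(("walk", "trot", "canter", "gallop"))
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)
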