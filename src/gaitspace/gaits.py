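"""Nearest-template gait classification in circular phase space.

Each step cycle is represented by its normalized phase vector
``Phi = (phi_LR, phi_HL, phi_DIAG)`` and compared against the dictionary of
idealized one-, two-, three- and four-beat gaits with equal phase shifts
between beats.  The distance is Euclidean in the three wrapped phase
differences (in radians):

    d(Phi, Psi) = sqrt( sum_j arg[ exp(i (phi_j - psi_j)) ]^2 )

The step is assigned to the nearest template; templates that differ only by
their lead limb share a category, and the walking/running name is chosen by
whether the mean duty factor is at least 0.5 (walking) or below (running).
Lead limbs are read from the touchdown order of each fore/hind pair: the
limb of a pair that strikes the ground first is trailing, the second is the
lead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cycles import StepCycle
from .io import Limb

__all__ = [
    "GaitTemplate",
    "TEMPLATES",
    "CATEGORIES",
    "GaitLabel",
    "TransitionMatrix",
    "circular_gait_distance",
    "mirror_point",
    "classify_phases",
    "classify_step",
    "label_cycles",
    "transition_stats",
    "gait_prevalence",
    "transition_graph",
    "write_dot",
]

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

#: seconds within which two touchdowns count as simultaneous (no lead limb)
SIMULTANEITY_TOL_S = 1e-6


@dataclass(frozen=True)
class GaitTemplate:
    """One idealized gait: its phase triple and its two duty-branch names."""

    lr: float
    hl: float
    diag: float
    beats: int
    name_walking: str
    name_running: str

    @property
    def phases(self) -> tuple[float, float, float]:
        return (self.lr, self.hl, self.diag)

    def name(self, walking: bool) -> str:
        return self.name_walking if walking else self.name_running


def _t(lr, hl, diag, beats, walking, running=None) -> GaitTemplate:
    running = walking if running is None else running
    return GaitTemplate(
        float(Fraction(lr)), float(Fraction(hl)), float(Fraction(diag)),
        beats, walking, running,
    )


#: The idealized-gait dictionary: every one- to four-beat gait with equal
#: phase shifts between beats (plus the extra 2/3-shifted two-beat hop/bound
#: accounting for fore-hind asymmetry in bound), in table order.  The
#: dictionary is closed under left-right mirroring.
TEMPLATES: tuple[GaitTemplate, ...] = (
    # one-beat
    _t(0, 0, 0, 1, "pronk"),
    # two-beat
    _t("1/2", "1/2", 0, 2, "trot"),
    _t(0, "1/2", "1/2", 2, "hop", "bound"),
    _t(0, "2/3", "2/3", 2, "hop", "bound"),
    _t("1/2", 0, "1/2", 2, "pace"),
    # three-beat
    _t(0, "1/3", "2/3", 3, "hop", "half-bound gallop"),
    _t(0, "2/3", "1/3", 3, "hop", "half-bound gallop"),
    _t("2/3", "1/3", 0, 3, "canter"),
    _t("1/3", "1/3", "2/3", 3, "canter"),
    _t("1/3", "2/3", 0, 3, "other three-beat"),
    _t("2/3", "2/3", "1/3", 3, "other three-beat"),
    _t("1/3", "2/3", "2/3", 3, "other three-beat"),
    _t("2/3", "1/3", "1/3", 3, "other three-beat"),
    _t("1/3", 0, "2/3", 3, "other three-beat"),
    _t("2/3", 0, "1/3", 3, "other three-beat"),
    _t("1/3", "2/3", "1/3", 3, "other three-beat"),
    _t("2/3", "1/3", "2/3", 3, "other three-beat"),
    # four-beat
    _t("3/4", "1/4", "2/4", 4, "rotary walk", "rotary gallop"),
    _t("1/4", "3/4", "2/4", 4, "rotary walk", "rotary gallop"),
    _t("3/4", "2/4", "1/4", 4, "transverse walk", "transverse gallop"),
    _t("1/4", "2/4", "3/4", 4, "transverse walk", "transverse gallop"),
    _t("2/4", "1/4", "3/4", 4, "lateral-sequence walk", "lateral-sequence amble"),
    _t("2/4", "3/4", "1/4", 4, "diagonal-sequence walk", "diagonal-sequence amble"),
)

#: canonical category order (used for transition matrices and reports)
CATEGORIES: tuple[str, ...] = (
    "pronk",
    "lateral-sequence walk",
    "diagonal-sequence walk",
    "rotary walk",
    "transverse walk",
    "lateral-sequence amble",
    "diagonal-sequence amble",
    "trot",
    "pace",
    "hop",
    "canter",
    "other three-beat",
    "rotary gallop",
    "transverse gallop",
    "half-bound gallop",
    "bound",
)

_TEMPLATE_PHASES = np.array([t.phases for t in TEMPLATES])  # cycles, (23, 3)


def circular_gait_distance(
    phi: Sequence[float], psi: Sequence[float]
) -> float:
    """Circular phase-space distance between two normalized phase triples.

    Inputs are in cycles ([0, 1) per component); the result is in radians:
    each component difference is scaled by 2*pi and wrapped to its principal
    value in (-pi, pi] before the Euclidean norm is taken.
    """
    a = TWO_PI * np.asarray(phi, dtype=float)
    b = TWO_PI * np.asarray(psi, dtype=float)
    wrapped = np.angle(np.exp(1j * (a - b)))
    return float(np.sqrt(np.sum(wrapped**2, axis=-1)))


def mirror_point(phi: Sequence[float]) -> tuple[float, float, float]:
    """Left-right swap of a step, re-expressed relative to the left hindlimb.

    Swapping the left and right limbs of a step whose phases are
    ``(phi_LR, phi_HL, phi_DIAG)`` relative to the left hindlimb and
    re-referencing to the new left hindlimb (the old right hindlimb) gives

        ((1 - phi_LR) mod 1, (phi_DIAG - phi_LR) mod 1, (phi_HL - phi_LR) mod 1).

    The map is an involution and maps each template of the dictionary onto
    its opposite-lead counterpart (symmetric gaits are fixed points).
    """
    lr, hl, diag = (float(x) for x in phi)
    return ((1.0 - lr) % 1.0, (diag - lr) % 1.0, (hl - lr) % 1.0)


@dataclass(frozen=True)
class GaitLabel:
    """Classification result for one step cycle.

    Lead limbs are derived from the circular touchdown order of each pair,
    except the canter forelimb lead, which follows the gait's definition:
    the leading forelimb is the one that is not part of the synchronous
    diagonal pair (touchdown order is near-degenerate for canter's almost
    alternating fore pair; the touchdown-order value is kept as a
    cross-check field).
    """

    category: str
    lead_forelimb: Limb | None
    lead_hindlimb: Limb | None
    matched_template: GaitTemplate
    distance: float  #: radians-space distance to the matched template
    tie: bool = False
    #: forelimb lead by circular touchdown order (cross-check for canter,
    #: identical to lead_forelimb for every other category)
    touchdown_lead_forelimb: Limb | None = None


def _template_distances(phi: Sequence[float]) -> np.ndarray:
    wrapped = np.angle(
        np.exp(1j * TWO_PI * (np.asarray(phi, dtype=float)[None, :] - _TEMPLATE_PHASES))
    )
    return np.sqrt(np.sum(wrapped**2, axis=1))


def classify_phases(
    phi: Sequence[float], mean_duty_factor: float
) -> tuple[GaitTemplate, str, float, bool]:
    """Nearest template and category for a phase triple and duty factor.

    Returns ``(template, category, distance, tie)``.  Ties between templates
    are broken by table order (first row wins) and logged.  A mean duty
    factor of at least 0.5 selects the walking name; below 0.5 the running
    name.
    """
    d = _template_distances(phi)
    near = d <= d.min() + 1e-12
    idx = int(np.argmax(near))  # first table row among (near-)ties
    tie = bool(near.sum() > 1)
    if tie:
        log.info("template tie at phi=%s; keeping first table row", tuple(phi))
    template = TEMPLATES[idx]
    category = template.name(walking=mean_duty_factor >= 0.5)
    return template, category, float(d[idx]), tie


def _pair_lead(
    onset_first: float, onset_second: float, period: float,
    first: Limb, second: Limb,
) -> Limb | None:
    """Lead limb of a pair from circular touchdown order.

    The pair's two touchdowns split the cycle circle into two arcs; the lead
    limb is the one that strikes second within the shorter arc.  Touchdowns
    closer than the simultaneity tolerance have no lead.
    """
    delta = (onset_second - onset_first) % period
    if min(delta, period - delta) < SIMULTANEITY_TOL_S:
        return None
    return second if delta < 0.5 * period else first


def classify_step(step: StepCycle) -> GaitLabel:
    """Classify one step cycle against the idealized-gait dictionary."""
    template, category, distance, tie = classify_phases(
        step.phase_point, step.mean_duty_factor
    )
    lead_hind = _pair_lead(
        step.limbs[Limb.LH].onset_s, step.limbs[Limb.RH].onset_s,
        step.period_s, Limb.LH, Limb.RH,
    )
    lead_fore = _pair_lead(
        step.limbs[Limb.LF].onset_s, step.limbs[Limb.RF].onset_s,
        step.period_s, Limb.LF, Limb.RF,
    )
    touchdown_fore = lead_fore
    if category == "canter":
        # the synchronous diagonal pair contains the non-leading forelimb:
        # diag ~ 0 means LH-RF synchronous, so LF leads; otherwise RF leads
        lead_fore = Limb.LF if template.diag == 0.0 else Limb.RF
    return GaitLabel(
        category=category,
        lead_forelimb=lead_fore,
        lead_hindlimb=lead_hind,
        matched_template=template,
        distance=distance,
        tie=tie,
        touchdown_lead_forelimb=touchdown_fore,
    )


def label_cycles(cycles: Iterable[StepCycle]) -> list[GaitLabel]:
    return [classify_step(c) for c in cycles]


@dataclass
class TransitionMatrix:
    """Gait-transition counts and their two normalizations.

    ``counts[i, j]`` is the number of steps of gait *i* immediately followed
    by a step of gait *j* within the same bout.  ``conditional`` normalizes
    each row by its sum (transition probabilities given the current gait);
    ``frequencies`` normalizes by the total number of transitions.
    """

    counts: pd.DataFrame
    conditional: pd.DataFrame
    frequencies: pd.DataFrame


def transition_stats(
    bout_sequences: Iterable[Sequence[str]],
) -> TransitionMatrix:
    """Tally gait transitions from per-bout ordered category sequences.

    Transitions never span bout boundaries.
    """
    sequences = [list(seq) for seq in bout_sequences]
    observed = sorted(
        {g for seq in sequences for g in seq},
        key=lambda g: CATEGORIES.index(g) if g in CATEGORIES else len(CATEGORIES),
    )
    counts = pd.DataFrame(0, index=observed, columns=observed, dtype=int)
    for seq in sequences:
        for a, b in zip(seq, seq[1:]):
            counts.loc[a, b] += 1
    totals = counts.to_numpy().sum()
    row_sums = counts.sum(axis=1)
    conditional = counts.div(row_sums.where(row_sums > 0, other=1), axis=0).astype(
        float
    )
    frequencies = (counts / totals if totals > 0 else counts * 0.0).astype(float)
    return TransitionMatrix(counts=counts, conditional=conditional, frequencies=frequencies)


def gait_prevalence(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-condition gait prevalence: proportions, step counts, and the
    number of animals expressing each gait."""
    if labeled.empty:
        return pd.DataFrame(
            columns=["condition", "gait", "n_steps", "proportion", "n_animals"]
        )
    rows = []
    for condition, sub in labeled.groupby("condition"):
        total = len(sub)
        for gait, chunk in sub.groupby("gait"):
            rows.append(
                {
                    "condition": condition,
                    "gait": gait,
                    "n_steps": len(chunk),
                    "proportion": len(chunk) / total,
                    "n_animals": chunk["animal_id"].nunique(),
                }
            )
    out = pd.DataFrame(rows)
    out["gait_order"] = out["gait"].map(
        {g: i for i, g in enumerate(CATEGORIES)}
    )
    return (
        out.sort_values(["condition", "gait_order"])
        .drop(columns="gait_order")
        .reset_index(drop=True)
    )


def transition_graph(
    matrix: TransitionMatrix, prevalence: pd.DataFrame | None = None
) -> nx.DiGraph:
    """Directed gait-transition graph: node weight is gait prevalence,
    edge weight the globally normalized transition frequency."""
    graph = nx.DiGraph()
    prev_map = {}
    if prevalence is not None and not prevalence.empty:
        prev_map = dict(zip(prevalence["gait"], prevalence["proportion"]))
    for gait in matrix.counts.index:
        graph.add_node(gait, prevalence=float(prev_map.get(gait, 0.0)))
    for a in matrix.counts.index:
        for b in matrix.counts.columns:
            n = int(matrix.counts.loc[a, b])
            if n > 0:
                graph.add_edge(
                    a, b,
                    count=n,
                    frequency=float(matrix.frequencies.loc[a, b]),
                    conditional=float(matrix.conditional.loc[a, b]),
                )
    return graph


def write_dot(graph: nx.DiGraph, path: str | Path) -> None:
    """Write the transition graph in DOT format.

    Node size is proportional to gait prevalence and edge pen width to
    transition frequency.
    """
    lines = ["digraph gait_transitions {"]
    for node, data in graph.nodes(data=True):
        width = 0.5 + 2.5 * data.get("prevalence", 0.0)
        lines.append(
            f'    "{node}" [width={width:.3f}, fixedsize=false, '
            f'prevalence={data.get("prevalence", 0.0):.4f}];'
        )
    for a, b, data in graph.edges(data=True):
        pen = 0.5 + 10.0 * data.get("frequency", 0.0)
        lines.append(
            f'    "{a}" -> "{b}" [penwidth={pen:.3f}, '
            f'label="{data.get("conditional", 0.0):.2f}"];'
        )
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
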