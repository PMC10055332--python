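"""Phase-space continuum models: lines between gaits, fitted by projection.

Step cycles live on the 3-torus of normalized phase differences
``Phi = (phi_LR, phi_HL, phi_DIAG)``.  A *continuum model* is a line segment
between two gaits ``Psi_A`` and ``Psi_B`` (average or idealized); each step
is assigned the scalar projection ``lambda_i`` onto the line for which its
circular phase-space distance to the line point ``Psi_A + lambda_i * u_hat``
is minimal, with ``u_hat = (Psi_B - Psi_A)/||Psi_B - Psi_A||`` built from
the unwrapped representatives of the endpoints and ``|lambda| <= 2*pi``.

Because phases wrap, the minimizing ``lambda`` cannot be found by a single
dot product: every combination of per-component 2*pi shifts defines its own
quadratic branch of the squared distance.  ``project_phases`` minimizes
exactly, by evaluating the stationary point of every wrap branch (which
include the plain projection and the two reference positions shifted by
``+-2*pi*u_hat``), the branch-crossing kinks and the interval bounds.

Goodness of fit is summarized by the coefficient of determination against
the grand circular mean,

    R^2 = 1 - sum_i d(Phi_i, Psi_A + lambda_i u)^2 / sum_i d(Phi_i, mu_Phi)^2,

by an information criterion built from the mean (unsquared) residual
distance, AIC = 2k + n log( mean_i d_i ), and by Akaike weights across the
candidate models.

Asymmetric gaits come in left- and right-lead forms.  A model with
``use_mirror`` treats the line and its left-right mirrored counterpart as
one model: each step is also evaluated with its limbs relabelled
left-to-right (``mirror_point``) and keeps whichever branch has the smaller
residual.  Relabelling the step rather than displacing the endpoints keeps
the mirrored branch an exact image of the primary one; residuals from both
branches pool into a single R^2 and AIC.

The module is organized like a statsmodels estimator: build a
:class:`PhaseContinuum` model from the phase points, call :meth:`fit`, and
read estimates and diagnostics off the returned
:class:`PhaseContinuumResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gaits import mirror_point

__all__ = [
    "LineModel",
    "TROT_HALFBOUND",
    "TROT_PACE",
    "ContinuumFit",
    "PhaseContinuum",
    "PhaseContinuumResults",
    "project_step",
    "project_phases",
    "grand_circular_mean",
    "line_r_squared",
    "line_aic",
    "aic_weights",
    "fit_continuum",
]

TWO_PI = 2.0 * np.pi


def _wrap(x: np.ndarray) -> np.ndarray:
    """Principal value of an angle array, in (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class LineModel:
    """A line between two gaits in phase space.

    Endpoints are given as normalized phase triples (cycles); internally the
    model works in radians.  ``k`` is the parameter count entering the AIC;
    both built-in models have fixed a-priori endpoints, hence ``k = 0``.
    """

    psi_a: tuple[float, float, float]
    psi_b: tuple[float, float, float]
    use_mirror: bool = False
    k: int = 0
    name: str = "line"

    def __post_init__(self) -> None:
        if np.allclose(self.psi_a, self.psi_b):
            raise ValueError("line endpoints must differ")

    @property
    def psi_a_rad(self) -> np.ndarray:
        return TWO_PI * np.asarray(self.psi_a, dtype=float)

    @property
    def psi_b_rad(self) -> np.ndarray:
        return TWO_PI * np.asarray(self.psi_b, dtype=float)

    @property
    def length(self) -> float:
        """||Psi_B - Psi_A|| in radians (unwrapped representatives)."""
        return float(np.linalg.norm(self.psi_b_rad - self.psi_a_rad))

    @property
    def u_hat(self) -> np.ndarray:
        """Unit direction from the unwrapped endpoint representatives."""
        d = self.psi_b_rad - self.psi_a_rad
        return d / np.linalg.norm(d)

    def point_at(self, lam: float | np.ndarray) -> np.ndarray:
        return self.psi_a_rad + np.multiply.outer(lam, self.u_hat)


#: average trot to average half-bound gallop (left lead) with its mirrored
#: right-lead counterpart; the continuum expressed by intact animals
TROT_HALFBOUND = LineModel(
    psi_a=(0.49, 0.47, 0.98),
    psi_b=(0.94, 0.60, 0.36),
    use_mirror=True,
    name="trot-halfbound",
)

#: idealized trot to idealized pace: the left-right-alternating continuum.
#: Trot's diagonal phase is 0 == 1 on the circle; the representative 1.0 is
#: used so that the segment to pace follows the family DIAG = HL + 0.5 --
#: the one remaining degree of freedom under left-right alternation of both
#: girdles -- and passes through the lateral- and diagonal-sequence walks
#: and ambles.  (The 0.0 representative would give a chord containing none
#: of those gaits.)  Both endpoints are left-right symmetric, so no mirror
#: branch is needed.
TROT_PACE = LineModel(
    psi_a=(0.5, 0.5, 1.0),
    psi_b=(0.5, 0.0, 0.5),
    use_mirror=False,
    name="trot-pace",
)


def _line_distance(phi_rad: np.ndarray, model: LineModel, lam: np.ndarray) -> np.ndarray:
    """Circular distance of points to the line at given lambdas.

    ``phi_rad``: (n, 3); ``lam``: (n,) or (n, m) candidate lambdas per point.
    """
    pts = model.psi_a_rad + lam[..., None] * model.u_hat
    if pts.ndim == 3:
        diff = phi_rad[:, None, :] - pts
    else:
        diff = phi_rad - pts
    return np.sqrt(np.sum(_wrap(diff) ** 2, axis=-1))


def _project_line(phi_rad: np.ndarray, model: LineModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact minimal-distance projections onto one line (no mirror).

    Returns (lambdas, residual distances), with |lambda| clamped to 2*pi.
    Candidate lambdas are the stationary points of all 27 per-component
    wrap branches (the plain projection and the +-2*pi-shifted reference
    positions among them), the branch-crossing kinks, and the bounds.
    """
    u = model.u_hat
    w0 = _wrap(phi_rad - model.psi_a_rad)  # (n, 3)
    n = w0.shape[0]

    shifts = TWO_PI * np.array(
        [[m0, m1, m2] for m0 in (-1, 0, 1) for m1 in (-1, 0, 1) for m2 in (-1, 0, 1)]
    )  # (27, 3)
    stationary = (w0[:, None, :] + shifts[None, :, :]) @ u  # (n, 27)

    kinks = []
    for i in range(3):
        if abs(u[i]) < 1e-12:
            continue
        for kk in (-2, -1, 0, 1):
            kinks.append((w0[:, i] - np.pi - TWO_PI * kk) / u[i])
    kink_arr = np.stack(kinks, axis=1) if kinks else np.empty((n, 0))

    bounds = np.broadcast_to([-TWO_PI, TWO_PI], (n, 2))
    cands = np.clip(
        np.concatenate([stationary, kink_arr, bounds], axis=1), -TWO_PI, TWO_PI
    )
    res = _line_distance(phi_rad, model, cands)
    # tie-break: minimal residual, then smallest |lambda|, then positive sign
    order = np.lexsort(
        (-np.sign(cands), np.abs(cands), np.round(res, 12)), axis=1
    )
    best = order[:, 0]
    rows = np.arange(n)
    return cands[rows, best], res[rows, best]


def project_phases(
    phases: np.ndarray | Sequence[Sequence[float]], model: LineModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project phase triples (cycles) onto a line model.

    Returns ``(lambdas, residuals, branches)`` where ``branches`` is an
    array of ``"primary"``/``"mirror"`` flags.  For a mirror-aware model
    each step is also projected with its left and right limbs relabelled and
    keeps the branch with the smaller residual.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    phi_rad = TWO_PI * phases
    lam_p, res_p = _project_line(phi_rad, model)
    branches = np.full(phases.shape[0], "primary", dtype=object)
    if not model.use_mirror:
        return lam_p, res_p, branches
    mirrored = np.array([mirror_point(p) for p in phases])
    lam_m, res_m = _project_line(TWO_PI * mirrored, model)
    use_m = res_m < res_p
    branches[use_m] = "mirror"
    return np.where(use_m, lam_m, lam_p), np.where(use_m, res_m, res_p), branches


def project_step(
    phi: Sequence[float], model: LineModel
) -> tuple[float, float, str]:
    """Projection of a single phase triple: (lambda, residual, branch)."""
    lam, res, branch = project_phases(np.asarray(phi, dtype=float)[None, :], model)
    return float(lam[0]), float(res[0]), str(branch[0])


def grand_circular_mean(
    points: np.ndarray | Sequence[Sequence[float]],
) -> tuple[float, float, float]:
    """Componentwise circular mean of phase triples, in cycles.

    Raises if any component's mean resultant vector has (numerically) zero
    length, in which case its circular mean is undefined.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("grand_circular_mean requires at least one point")
    z = np.exp(1j * TWO_PI * pts).mean(axis=0)
    if np.any(np.abs(z) < 1e-9):
        raise ValueError(
            "circular mean undefined: zero resultant length in component(s) "
            f"{np.nonzero(np.abs(z) < 1e-9)[0].tolist()}"
        )
    return tuple((np.angle(z) / TWO_PI) % 1.0)


def _mean_distances_sq(phases: np.ndarray, mu: Sequence[float]) -> np.ndarray:
    diff = _wrap(TWO_PI * (phases - np.asarray(mu)))
    return np.sum(diff**2, axis=1)


def line_r_squared(
    phases: np.ndarray,
    model: LineModel,
    residuals: np.ndarray | None = None,
    animal_ids: Sequence | None = None,
) -> tuple[float, dict]:
    """Coefficient of determination of a line model.

    ``R^2 = 1 - sum d_i^2 / sum d(Phi_i, mu_Phi)^2`` with mu_Phi the grand
    circular mean of the points.  When animal identities are given, R^2 is
    additionally computed per animal (each against its own grand mean).
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if phases.shape[0] < 2:
        raise ValueError("line_r_squared requires at least two points")
    if residuals is None:
        _, residuals, _ = project_phases(phases, model)
    denom = float(np.sum(_mean_distances_sq(phases, grand_circular_mean(phases))))
    if denom <= 0.0:
        raise ValueError("R^2 undefined: all points coincide with the grand mean")
    overall = 1.0 - float(np.sum(residuals**2)) / denom
    per_animal: dict = {}
    if animal_ids is not None:
        ids = np.asarray(animal_ids)
        for animal in pd.unique(ids):
            mask = ids == animal
            if mask.sum() < 2:
                continue
            sub = phases[mask]
            d = float(np.sum(_mean_distances_sq(sub, grand_circular_mean(sub))))
            if d <= 0.0:
                continue
            per_animal[animal] = 1.0 - float(np.sum(residuals[mask] ** 2)) / d
    return overall, per_animal


def line_aic(
    phases: np.ndarray,
    model: LineModel,
    residuals: np.ndarray | None = None,
) -> float:
    """AIC of a line model: ``2k + n * log(mean unsquared residual)``.

    If every residual is zero the criterion diverges to -inf; a warning is
    emitted and ``-inf`` returned.
    """
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    if residuals is None:
        _, residuals, _ = project_phases(phases, model)
    n = residuals.size
    if n == 0:
        raise ValueError("line_aic requires at least one point")
    mean_res = float(np.mean(residuals))
    if mean_res <= 0.0:
        warnings.warn("all residuals are zero; AIC is -inf", RuntimeWarning)
        return float("-inf")
    return 2.0 * model.k + n * float(np.log(mean_res))


def aic_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights: relative likelihood of each model among candidates."""
    arr = np.asarray(aics, dtype=float)
    delta = arr - np.min(arr)
    rel = np.exp(-0.5 * delta)
    return rel / np.sum(rel)


@dataclass
class ContinuumFit:
    """Per-model fit results: projections, residuals, R^2, AIC."""

    model: LineModel
    lambdas: np.ndarray
    residual_distances: np.ndarray
    branch: np.ndarray
    r2_overall: float
    r2_per_animal: dict
    aic: float
    n: int

    @property
    def r2_per_animal_summary(self) -> dict:
        """Median and quartiles of the per-animal R^2 values."""
        if not self.r2_per_animal:
            return {}
        vals = np.array(list(self.r2_per_animal.values()))
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3)}


class PhaseContinuum:
    """Model: a set of candidate phase-space lines evaluated on step phases.

    Parameters
    ----------
    phases
        (n, 3) normalized phase triples (cycles) of the steps.
    animal_ids
        optional per-step animal identifiers, enabling per-animal R^2.
    models
        candidate :class:`LineModel` objects; defaults to the
        trot-to-half-bound line (with mirror) and the trot-to-pace line.
    """

    def __init__(
        self,
        phases: np.ndarray | Sequence[Sequence[float]],
        animal_ids: Sequence | None = None,
        models: Sequence[LineModel] = (TROT_HALFBOUND, TROT_PACE),
    ) -> None:
        self.phases = np.atleast_2d(np.asarray(phases, dtype=float))
        if self.phases.shape[1] != 3:
            raise ValueError("phases must be (n, 3) phase triples")
        if animal_ids is not None and len(animal_ids) != self.phases.shape[0]:
            raise ValueError("animal_ids length must match the number of steps")
        self.animal_ids = None if animal_ids is None else np.asarray(animal_ids)
        if not models:
            raise ValueError("at least one line model is required")
        names = [m.name for m in models]
        if len(set(names)) != len(names):
            raise ValueError("model names must be unique")
        self.models = tuple(models)

    @classmethod
    def from_cycles(
        cls, cycles: Sequence, models: Sequence[LineModel] = (TROT_HALFBOUND, TROT_PACE)
    ) -> "PhaseContinuum":
        """Build the model from extracted :class:`~gaitspace.cycles.StepCycle`s."""
        phases = np.array([c.phase_point for c in cycles])
        animals = [c.animal_id for c in cycles]
        return cls(phases, animal_ids=animals, models=models)

    def fit(self) -> "PhaseContinuumResults":
        fits = {}
        for model in self.models:
            lam, res, branch = project_phases(self.phases, model)
            r2, r2_animals = line_r_squared(
                self.phases, model, residuals=res, animal_ids=self.animal_ids
            )
            fits[model.name] = ContinuumFit(
                model=model,
                lambdas=lam,
                residual_distances=res,
                branch=branch,
                r2_overall=r2,
                r2_per_animal=r2_animals,
                aic=line_aic(self.phases, model, residuals=res),
                n=self.phases.shape[0],
            )
        weights = aic_weights([f.aic for f in fits.values()])
        return PhaseContinuumResults(
            model=self,
            fits=fits,
            aic_weights=dict(zip(fits.keys(), (float(w) for w in weights))),
        )


@dataclass
class PhaseContinuumResults:
    """Fitted continuum models with goodness-of-fit and model weights."""

    model: PhaseContinuum
    fits: Mapping[str, ContinuumFit]
    aic_weights: dict

    def steps_frame(self) -> pd.DataFrame:
        """Per-step projections for every candidate model (tidy)."""
        rows = []
        for name, fit in self.fits.items():
            for i in range(fit.n):
                rows.append(
                    {
                        "model": name,
                        "step": i,
                        "lambda": float(fit.lambdas[i]),
                        "residual": float(fit.residual_distances[i]),
                        "branch": fit.branch[i],
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, fit in self.fits.items():
            s = fit.r2_per_animal_summary
            rows.append(
                {
                    "model": name,
                    "n": fit.n,
                    "r2_overall": fit.r2_overall,
                    "r2_animal_median": s.get("median", np.nan),
                    "r2_animal_q1": s.get("q1", np.nan),
                    "r2_animal_q3": s.get("q3", np.nan),
                    "aic": fit.aic,
                    "aic_weight": self.aic_weights[name],
                }
            )
        return pd.DataFrame(rows).set_index("model")

    def summary(self) -> str:
        """Plain-text summary table of the fitted line models."""
        frame = self.summary_frame()
        lines = ["Phase-space continuum model comparison", "=" * 54]
        with pd.option_context("display.float_format", "{:.4f}".format):
            lines.append(frame.to_string())
        return "\n".join(lines)


def fit_continuum(
    phases: np.ndarray | Sequence[Sequence[float]],
    animal_ids: Sequence | None = None,
    models: Sequence[LineModel] = (TROT_HALFBOUND, TROT_PACE),
) -> PhaseContinuumResults:
    """Convenience wrapper: build a :class:`PhaseContinuum` and fit it."""
    return PhaseContinuum(phases, animal_ids=animal_ids, models=models).fit()
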