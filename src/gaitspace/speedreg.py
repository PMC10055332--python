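"""Speed dependence of gait parameters: per-animal regressions, group
averages and delta-method confidence bands.

Stride length, duty factors and swing durations change linearly with
locomotor speed, f(beta, v) = beta0 + beta1 * v, whereas the step-cycle
period and the stance durations are inversely related to speed,
f(beta, v) = beta0 + beta1 / v.  Fits are performed per animal (pooling all
of an animal's cycles within a condition); the group estimate is the mean
of the per-animal coefficient vectors, and its 95% confidence band at speed
v is obtained by the delta method from the mean of the per-animal
coefficient covariance matrices:

    CI(v) = 1.96 * sqrt( grad f(mu_beta, v)^T  Cov_beta  grad f(mu_beta, v) )

The inverse form is estimated by ordinary least squares on the reciprocal
regressor 1/v, which shares its optimum with a nonlinear fit of the same
model under additive error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FORMS",
    "PARAMETER_FORMS",
    "RegressionFit",
    "GroupRegression",
    "SpeedRegression",
    "fit_speed_regression",
    "group_average",
    "delta_ci",
    "regression_report",
]

log = logging.getLogger(__name__)

FORMS = ("linear", "inverse")

#: the gait parameters regressed on speed and the functional form of each
PARAMETER_FORMS: dict[str, str] = {
    "stride_length_cm": "linear",
    "fore_duty_factor": "linear",
    "hind_duty_factor": "linear",
    "fore_swing_s": "linear",
    "hind_swing_s": "linear",
    "period_s": "inverse",
    "fore_stance_s": "inverse",
    "hind_stance_s": "inverse",
}


class SingularFitError(ValueError):
    """The regression design is degenerate (e.g. constant speed)."""


def _regressor(speed: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        return speed
    if form == "inverse":
        if np.any(speed <= 0):
            raise ValueError("inverse form requires strictly positive speeds")
        return 1.0 / speed
    raise ValueError(f"unknown regression form {form!r}")


@dataclass(frozen=True)
class RegressionFit:
    """Per-animal least-squares fit of one gait parameter against speed."""

    form: str
    beta: np.ndarray  #: (beta0, beta1)
    cov_beta: np.ndarray  #: 2x2 covariance of the estimates
    n: int
    animal_id: str | None = None
    parameter_name: str | None = None

    def predict(self, v: np.ndarray | float) -> np.ndarray | float:
        x = _regressor(np.asarray(v, dtype=float), self.form)
        return self.beta[0] + self.beta[1] * x


class SpeedRegression:
    """Model object for one animal's parameter-versus-speed regression."""

    def __init__(
        self,
        speed: Sequence[float],
        values: Sequence[float],
        form: str = "linear",
        animal_id: str | None = None,
        parameter_name: str | None = None,
    ) -> None:
        self.speed = np.asarray(speed, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.speed.shape != self.values.shape:
            raise ValueError("speed and values must have equal length")
        if self.speed.size < 3:
            raise ValueError("at least three points are required for a fit")
        if form not in FORMS:
            raise ValueError(f"unknown regression form {form!r}")
        self.form = form
        self.animal_id = animal_id
        self.parameter_name = parameter_name

    def fit(self) -> RegressionFit:
        x = _regressor(self.speed, self.form)
        design = sm.add_constant(x, has_constant="add")
        if np.linalg.matrix_rank(design) < 2:
            raise SingularFitError(
                f"degenerate design for {self.parameter_name or 'parameter'}: "
                "speeds carry no variation"
            )
        res = sm.OLS(self.values, design).fit()
        return RegressionFit(
            form=self.form,
            beta=np.asarray(res.params, dtype=float),
            cov_beta=np.asarray(res.cov_params(), dtype=float),
            n=int(res.nobs),
            animal_id=self.animal_id,
            parameter_name=self.parameter_name,
        )


def fit_speed_regression(
    speed: Sequence[float],
    values: Sequence[float],
    form: str = "linear",
    animal_id: str | None = None,
    parameter_name: str | None = None,
) -> RegressionFit:
    """Least-squares fit of one parameter against speed (one animal)."""
    return SpeedRegression(
        speed, values, form=form, animal_id=animal_id, parameter_name=parameter_name
    ).fit()


@dataclass(frozen=True)
class GroupRegression:
    """Group-averaged regression: mean coefficients and mean covariance."""

    form: str
    mu_beta: np.ndarray
    mean_cov: np.ndarray
    n_animals: int
    parameter_name: str | None = None
    condition: str | None = None

    def predict(self, v: np.ndarray | float) -> np.ndarray | float:
        x = _regressor(np.asarray(v, dtype=float), self.form)
        return self.mu_beta[0] + self.mu_beta[1] * x


def group_average(fits: Sequence[RegressionFit]) -> GroupRegression:
    """Average per-animal regressions: elementwise means of coefficients and
    of their covariance matrices."""
    fits = list(fits)
    if not fits:
        raise ValueError("group_average requires at least one fit")
    forms = {f.form for f in fits}
    if len(forms) > 1:
        raise ValueError(f"cannot average fits of mixed forms {sorted(forms)}")
    params = {f.parameter_name for f in fits}
    if len(params) > 1:
        raise ValueError(f"cannot average fits of different parameters {sorted(params)}")
    return GroupRegression(
        form=fits[0].form,
        mu_beta=np.mean([f.beta for f in fits], axis=0),
        mean_cov=np.mean([f.cov_beta for f in fits], axis=0),
        n_animals=len(fits),
        parameter_name=fits[0].parameter_name,
    )


def delta_ci(group: GroupRegression, v: np.ndarray | float) -> np.ndarray | float:
    """Half-width of the 95% confidence band at speed(s) v (delta method)."""
    v_arr = np.asarray(v, dtype=float)
    x = _regressor(v_arr, group.form)
    grad = np.stack([np.ones_like(x), x], axis=-1)
    quad = np.einsum("...i,ij,...j->...", grad, group.mean_cov, grad)
    out = 1.96 * np.sqrt(quad)
    return float(out) if np.isscalar(v) or v_arr.ndim == 0 else out


def regression_report(
    cycles: pd.DataFrame,
    parameters: Mapping[str, str] = PARAMETER_FORMS,
    n_band: int = 100,
    min_points: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group regressions and confidence bands for every condition.

    ``cycles`` is the table produced by
    :func:`gaitspace.cycles.cycles_to_frame`. For each condition and each
    parameter, per-animal fits are pooled across bouts, averaged, and the
    95% band is sampled at ``n_band`` evenly spaced speeds over the
    condition's observed speed range.  Conditions or animals with too few
    cycles are skipped with a log diagnostic.

    Returns ``(group_table, band_table)``.
    """
    group_rows = []
    band_rows = []
    for condition, sub in cycles.groupby("condition"):
        v_lo, v_hi = sub["speed_cm_s"].min(), sub["speed_cm_s"].max()
        grid = np.linspace(v_lo, v_hi, n_band)
        for parameter, form in parameters.items():
            fits = []
            for animal, chunk in sub.groupby("animal_id"):
                if len(chunk) < min_points:
                    log.info(
                        "skipping %s/%s for %s: only %d cycles",
                        condition, animal, parameter, len(chunk),
                    )
                    continue
                fits.append(
                    fit_speed_regression(
                        chunk["speed_cm_s"], chunk[parameter],
                        form=form, animal_id=str(animal), parameter_name=parameter,
                    )
                )
            if not fits:
                log.info("condition %s omitted for %s: no usable animals",
                         condition, parameter)
                continue
            group = group_average(fits)
            group_rows.append(
                {
                    "condition": condition,
                    "parameter": parameter,
                    "form": form,
                    "beta0": group.mu_beta[0],
                    "beta1": group.mu_beta[1],
                    "cov00": group.mean_cov[0, 0],
                    "cov01": group.mean_cov[0, 1],
                    "cov11": group.mean_cov[1, 1],
                    "n_animals": group.n_animals,
                }
            )
            pred = group.predict(grid)
            half = delta_ci(group, grid)
            for v, p, h in zip(grid, np.atleast_1d(pred), np.atleast_1d(half)):
                band_rows.append(
                    {
                        "condition": condition,
                        "parameter": parameter,
                        "speed_cm_s": v,
                        "estimate": p,
                        "ci_half_width": h,
                    }
                )
    return pd.DataFrame(group_rows), pd.DataFrame(band_rows)
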