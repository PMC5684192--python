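"""Constant-plus-variable model of CD4 TEMRA subset composition.

The model: every donor carries a roughly constant absolute frequency
``c`` of GPR56-Perforin- (double-negative) TEMRA cells among CD4
T cells, while the GPR56+/Perforin+ component varies between donors.
The proportion of double-negative cells *within* the TEMRA compartment
is then

    p_dn(f_temra) = min(1, c / f_temra)

which decays hyperbolically as the total TEMRA frequency ``f_temra``
rises — donors with few TEMRA cells have mostly double-negative TEMRA,
donors with expanded TEMRA have mostly GPR56+/Perforin+ cells.  (The
decay is often described loosely as "exponential"; the constant-fraction
model implies the hyperbolic c/f form, which is what is implemented.)

``c`` is fitted by bounded 1-D least squares on either the proportion
scale (what composition plots show; default) or the log-frequency scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import FitDegenerateError, ValidationError

_CLIP_TOL = 1e-12


@dataclass
class CompositionObservation:
    """One donor's flow-cytometry composition measurement.

    ``f_temra`` and ``f_dn`` are decimal fractions of total CD4 T cells
    (TEMRA overall, and GPR56-Perforin- TEMRA respectively).  The derived
    ``p_dn_within`` = f_dn / f_temra is the double-negative proportion
    within TEMRA; measurement noise can push f_dn above f_temra, in which
    case the proportion is clipped to 1 with a warning.
    """

    donor_id: str
    f_temra: float
    f_dn: float
    p_dn_within: float = field(init=False)
    clipped: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.f_temra <= 1.0):
            raise ValidationError(
                f"{self.donor_id}: f_temra must be in (0, 1], got {self.f_temra}"
            )
        if not (0.0 <= self.f_dn <= 1.0):
            raise ValidationError(
                f"{self.donor_id}: f_dn must be in [0, 1], got {self.f_dn}"
            )
        p = self.f_dn / self.f_temra
        if p > 1.0 + _CLIP_TOL:
            warnings.warn(
                f"{self.donor_id}: f_dn ({self.f_dn:.4g}) exceeds f_temra "
                f"({self.f_temra:.4g}); clipping within-TEMRA proportion to 1",
                stacklevel=2,
            )
            self.clipped = True
        self.p_dn_within = min(1.0, p)


@dataclass
class CompositionFit:
    """Fitted constant double-negative fraction and residual diagnostics."""

    c_hat: float
    n_donors: int
    residual_sum_of_squares: float
    fit_scale: str
    per_donor_residuals: np.ndarray

    def to_dict(self) -> dict:
        return {
            "c_hat": self.c_hat,
            "n_donors": self.n_donors,
            "residual_sum_of_squares": self.residual_sum_of_squares,
            "fit_scale": self.fit_scale,
            "per_donor_residuals": list(map(float, self.per_donor_residuals)),
        }


def predicted_dn_proportion(f_temra, c: float):
    """min(1, c / f_temra): double-negative proportion within TEMRA.

    Strictly decreasing in ``f_temra`` on the unclipped branch
    (f_temra > c); identically 1 below it.  Accepts scalars or arrays.
    """
    f = np.asarray(f_temra, dtype=float)
    if np.any(f <= 0):
        raise ValidationError("f_temra must be > 0")
    if c <= 0:
        raise ValidationError(f"c must be > 0, got {c}")
    pred = np.minimum(1.0, c / f)
    return float(pred) if np.isscalar(f_temra) else pred


def _residuals(obs_p: np.ndarray, f: np.ndarray, c: float,
               fit_scale: str) -> np.ndarray:
    pred = np.minimum(1.0, c / f)
    if fit_scale == "proportion":
        return obs_p - pred
    if fit_scale == "log_frequency":
        # compare implied absolute DN frequencies on the log scale
        return np.log(obs_p * f) - np.log(pred * f)
    raise ValidationError(
        f"fit_scale must be 'proportion' or 'log_frequency', got {fit_scale!r}"
    )


def fit_constant_fraction(
    observations: list[CompositionObservation],
    fit_scale: str = "proportion",
) -> CompositionFit:
    """Least-squares estimate of the constant fraction ``c``.

    Bounded one-dimensional minimization of the squared residuals between
    observed and predicted within-TEMRA double-negative proportions, over
    c in (1e-5, max observed f_temra).  Deterministic for fixed inputs.

    Raises
    ------
    FitDegenerateError
        If every observation is clipped (p_dn_within == 1 for all
        donors): any c >= max(f_temra) then fits equally well and the
        constant fraction is unidentifiable.
    """
    if len(observations) < 2:
        raise FitDegenerateError("need >= 2 observations to fit c")
    f = np.array([o.f_temra for o in observations])
    p = np.array([o.p_dn_within for o in observations])
    if len(np.unique(f)) < 2:
        raise FitDegenerateError("need >= 2 distinct f_temra values")
    if np.all(p >= 1.0 - _CLIP_TOL):
        raise FitDegenerateError(
            "every donor sits on the clipped branch (p_dn_within = 1); "
            "the constant fraction is unidentifiable"
        )
    if fit_scale == "log_frequency" and np.any(p <= 0):
        raise ValidationError(
            "log_frequency scale requires strictly positive proportions"
        )

    def sse(c: float) -> float:
        return float(np.sum(_residuals(p, f, c, fit_scale) ** 2))

    res = minimize_scalar(sse, bounds=(1e-5, float(f.max())),
                          method="bounded",
                          options={"xatol": 1e-10})
    c_hat = float(res.x)
    resid = _residuals(p, f, c_hat, fit_scale)
    return CompositionFit(
        c_hat=c_hat,
        n_donors=len(observations),
        residual_sum_of_squares=float(np.sum(resid ** 2)),
        fit_scale=fit_scale,
        per_donor_residuals=resid,
    )


def composition_report(
    observations: list[CompositionObservation],
    fit: CompositionFit,
    n_curve: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor observed-vs-predicted table plus a sampled model curve.

    The curve spans the observed f_temra range on a geometric grid
    (frequencies span more than an order of magnitude).
    """
    f = np.array([o.f_temra for o in observations])
    donors = pd.DataFrame(
        {
            "donor_id": [o.donor_id for o in observations],
            "f_temra": f,
            "f_dn": [o.f_dn for o in observations],
            "p_dn_within": [o.p_dn_within for o in observations],
            "p_dn_predicted": predicted_dn_proportion(f, fit.c_hat),
            "residual": fit.per_donor_residuals,
            "clipped": [o.clipped for o in observations],
        }
    )
    grid = np.geomspace(f.min(), f.max(), n_curve)
    curve = pd.DataFrame(
        {
            "f_temra": grid,
            "p_dn_predicted": predicted_dn_proportion(grid, fit.c_hat),
        }
    )
    return donors, curve


def read_composition_table(path: str | Path) -> list[CompositionObservation]:
    """Read a donor composition TSV (donor_id, f_temra, f_dn as decimal
    fractions of total CD4 T cells)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("donor_id", "f_temra", "f_dn"):
        if col not in df.columns:
            raise ValidationError(
                f"{path}: composition table missing column {col!r}"
            )
    return [
        CompositionObservation(donor_id=str(r.donor_id),
                               f_temra=float(r.f_temra),
                               f_dn=float(r.f_dn))
        for r in df.itertuples()
    ]
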