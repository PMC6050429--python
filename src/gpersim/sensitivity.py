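"""Local sensitivity analysis of observables to inputs and parameters.

Normalized (relative) sensitivity coefficients

    S(t) = (∂y(t)/∂p) · (p / y(t))

are estimated by central finite differences, perturbing the quantity p —
either a species initial concentration (e.g. the clamped tamoxifen input)
or a rate constant — by ±delta_rel·p and re-integrating.  Normalized
coefficients make observables of different magnitudes comparable, which is
what a ranking over {Raf1_active, PI3K_active, ppMEK, ppERK} needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reaction_network import Model, StructuralError
from .simulate import DEFAULT_ATOL, DEFAULT_N_POINTS, DEFAULT_T_END, Observable, integrate, observable_timecourse

__all__ = [
    "SensitivityResult",
    "UndefinedSensitivityError",
    "StepSizeWarning",
    "DegenerateRankingWarning",
    "local_sensitivity",
    "rank_sensitivities",
]


class UndefinedSensitivityError(Exception):
    """Baseline observable below the floor everywhere: S is undefined."""


class StepSizeWarning(UserWarning):
    """Finite-difference summaries changed too much when delta was halved."""


class DegenerateRankingWarning(UserWarning):
    """All sensitivity summaries are zero; ranking fell back to name order."""


@dataclass
class SensitivityResult:
    """Normalized sensitivity of one observable to one perturbed quantity."""

    observable: str
    perturbed: str
    times: np.ndarray
    coefficients: np.ndarray  # S(t), masked to NaN where y below floor
    max_abs: float
    mean_abs: float
    delta_rel: float


def _perturbed_model(model: Model, quantity: str, factor: float) -> Model:
    m = model.copy()
    try:
        sp = m.get_species(quantity)
    except StructuralError:
        sp = None
    if sp is not None:
        sp.initial_concentration *= factor
        return m
    m.find_rate_constant(quantity).value *= factor
    return m


def _baseline_value(model: Model, quantity: str) -> float:
    try:
        return model.get_species(quantity).initial_concentration
    except StructuralError:
        return model.find_rate_constant(quantity).value


def local_sensitivity(
    model: Model,
    obs: Observable,
    perturb: str,
    delta_rel: float = 0.01,
    t_end: float = DEFAULT_T_END,
    n_points: int = DEFAULT_N_POINTS,
    y_floor: float = DEFAULT_ATOL,
    scheme: str = "central",
) -> SensitivityResult:
    """Central-difference normalized sensitivity coefficient time series.

    S(t) = [y(t; (1+δ)p) − y(t; (1−δ)p)] / (2δ·y(t; p)); points where the
    baseline y(t) falls below ``y_floor`` are masked (NaN) and excluded from
    the scalar summaries.  ``scheme="forward"`` uses the one-sided estimate
    [y((1+δ)p) − y(p)] / (δ·y(p)), mainly for step-size diagnostics.
    """
    if delta_rel <= 0 or delta_rel >= 1:
        raise ValueError(f"delta_rel must be in (0, 1), got {delta_rel}")
    p0 = _baseline_value(model, perturb)
    base = integrate(model, t_end, n_points)
    y0 = observable_timecourse(base, obs)
    ok = y0 > y_floor
    if not ok.any():
        raise UndefinedSensitivityError(
            f"observable {obs.name!r} never exceeds floor {y_floor}; "
            f"sensitivity to {perturb!r} is undefined"
        )
    if p0 == 0.0:
        # relative perturbation of a zero quantity is a no-op; S ≡ 0
        s = np.zeros_like(y0)
    else:
        up = integrate(_perturbed_model(model, perturb, 1.0 + delta_rel), t_end, n_points)
        y_up = observable_timecourse(up, obs)
        if scheme == "central":
            down = integrate(
                _perturbed_model(model, perturb, 1.0 - delta_rel), t_end, n_points
            )
            y_dn = observable_timecourse(down, obs)
            s = np.where(ok, (y_up - y_dn) / (2.0 * delta_rel * np.where(ok, y0, 1.0)), np.nan)
        elif scheme == "forward":
            s = np.where(ok, (y_up - y0) / (delta_rel * np.where(ok, y0, 1.0)), np.nan)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    valid = s[ok] if p0 != 0.0 else s
    return SensitivityResult(
        observable=obs.name,
        perturbed=perturb,
        times=base.times,
        coefficients=np.where(ok, s, np.nan) if p0 != 0.0 else s,
        max_abs=float(np.max(np.abs(valid))) if valid.size else 0.0,
        mean_abs=float(np.mean(np.abs(valid))) if valid.size else 0.0,
        delta_rel=delta_rel,
    )


def rank_sensitivities(
    model: Model,
    observables: list,
    perturb: str,
    delta_rel: float = 0.01,
    t_end: float = DEFAULT_T_END,
    n_points: int = DEFAULT_N_POINTS,
    check_step: bool = False,
) -> list:
    """Rank observables by sensitivity to one perturbed quantity.

    Descending by time-averaged |S|; ties broken by max |S| over time, then
    observable name.  The time average is the primary key because the
    pointwise maximum of a *normalized* coefficient is taken where the
    baseline trajectory is barely above the floor — typically the start-up
    transient — which makes it depend on the output grid and the floor
    rather than on the biology; the time average is stable under both.
    Returns ``[(name, SensitivityResult), ...]`` in rank order.  With
    ``check_step=True`` the analysis is repeated at delta/2 and a
    :class:`StepSizeWarning` is raised if any summary moves by >5%.
    """
    results = [
        local_sensitivity(model, obs, perturb, delta_rel, t_end, n_points)
        for obs in observables
    ]
    if check_step:
        halved = [
            local_sensitivity(model, obs, perturb, delta_rel / 2.0, t_end, n_points)
            for obs in observables
        ]
        for r, h in zip(results, halved):
            ref = max(abs(r.mean_abs), 1e-12)
            if abs(r.mean_abs - h.mean_abs) / ref > 0.05:
                warnings.warn(
                    f"sensitivity summary for {r.observable} changed by "
                    f">5% when halving delta_rel — consider a smaller step",
                    StepSizeWarning,
                )
    if all(r.mean_abs == 0.0 and r.max_abs == 0.0 for r in results):
        warnings.warn(
            "all sensitivity summaries are zero; ranking by name only",
            DegenerateRankingWarning,
        )
        ordered = sorted(results, key=lambda r: r.observable)
    else:
        ordered = sorted(results, key=lambda r: (-r.mean_abs, -r.max_abs, r.observable))
    return [(r.observable, r) for r in ordered]
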