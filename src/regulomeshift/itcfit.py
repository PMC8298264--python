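"""Single-binding-site isothermal titration calorimetry (ITC).

The Wiseman single-site model relates the cumulative heat after injection i
to the bound fraction Theta of the macromolecule:

    Q_i = n * Theta_i * M_i * V0 * dH

where Theta_i is the root in [0, 1] of

    Theta^2 - Theta * (1 + X/(n*M) + 1/(n*Ka*M)) + X/(n*M) = 0

with M and X the displacement-corrected cell concentrations of macromolecule
and titrant after i injections.  Per-injection heats subtract the previous
cumulative heat and add the standard displaced-volume correction

    q_i = Q_i - Q_{i-1} + (v_inj/V0) * (Q_i + Q_{i-1}) / 2 .

Units: molar concentrations, microlitre volumes, kcal/mol enthalpy; heats
come out in microcalories.  Parameters (Ka, dH, n) are estimated from
integrated heats by multi-start nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
from scipy.optimize import least_squares

KCAL_PER_MOL_TIMES_M_UL_TO_UCAL = 1.0e3  # (mol/L * uL) * kcal/mol -> ucal


@dataclass(frozen=True)
class ITCProtocol:
    """Titration geometry and concentrations.

    Defaults follow a 19 x 2 uL titration of 200 uM titrant into 200 uM
    macromolecule in a 200 uL perfusion cell (a typical volume for the
    instrument class; configurable).
    """

    v0: float = 200.0  # cell volume, uL
    n_inj: int = 19
    v_inj: float = 2.0  # per-injection volume, uL
    syringe_conc: float = 200e-6  # titrant (ligand), M
    cell_conc: float = 200e-6  # macromolecule, M

    def __post_init__(self) -> None:
        if min(self.v0, self.n_inj, self.v_inj, self.syringe_conc,
               self.cell_conc) <= 0:
            raise ValueError("all protocol parameters must be positive")
        if self.n_inj * self.v_inj >= self.v0:
            warnings.warn("cumulative injected volume reaches the cell "
                          "volume; displacement correction is inaccurate",
                          stacklevel=2)


@dataclass
class ITCFitResult:
    ka: float  # association constant, 1/M
    dh: float  # enthalpy, kcal/mol
    n: float  # stoichiometry (fraction of active protein)
    residual_sse: float
    converged: bool

    @property
    def kd(self) -> float:
        return 1.0 / self.ka


def injection_state(p: ITCProtocol, i: int) -> tuple[float, float, float]:
    """Cell concentrations after injection ``i`` (1-based).

    Returns (M_t, X_t, dilution factor) using the standard perfusion-cell
    displacement correction for a total injected volume dV = i * v_inj:

        M_t = M_0 * (1 - dV/(2*V0)) / (1 + dV/(2*V0))
        X_t = X_syr * (dV/V0) / (1 + dV/(2*V0))

    ``i = 0`` is accepted and returns the pre-titration state.
    """
    if not 0 <= i <= p.n_inj:
        raise ValueError(f"injection index {i} outside [0, {p.n_inj}]")
    dv = i * p.v_inj
    half = dv / (2.0 * p.v0)
    dilution = (1.0 - half) / (1.0 + half)
    m_t = p.cell_conc * dilution
    x_t = p.syringe_conc * (dv / p.v0) / (1.0 + half)
    return m_t, x_t, dilution


def bound_fraction(ka: float, n: float, m_t: float, x_t: float) -> float:
    """Root in [0, 1] of the single-site quadratic for Theta."""
    if ka <= 0 or n <= 0 or m_t <= 0:
        raise ValueError("ka, n and M_t must be positive")
    b = 1.0 + x_t / (n * m_t) + 1.0 / (n * ka * m_t)
    c = x_t / (n * m_t)
    disc = b * b - 4.0 * c
    if disc < 0:
        raise ArithmeticError("negative discriminant in binding quadratic")
    theta = (b - np.sqrt(disc)) / 2.0
    return float(min(max(theta, 0.0), 1.0))


def cumulative_heat(ka: float, dh: float, n: float, p: ITCProtocol,
                    i: int) -> float:
    """Cumulative heat Q_i in microcalories."""
    if i == 0:
        return 0.0
    m_t, x_t, _ = injection_state(p, i)
    theta = bound_fraction(ka, n, m_t, x_t)
    return n * theta * m_t * p.v0 * dh * KCAL_PER_MOL_TIMES_M_UL_TO_UCAL


def simulate_isotherm(ka: float, dh: float, n: float,
                      p: ITCProtocol) -> np.ndarray:
    """Per-injection heats (ucal) under the single-site model."""
    q = np.empty(p.n_inj)
    prev = 0.0
    for i in range(1, p.n_inj + 1):
        cur = cumulative_heat(ka, dh, n, p, i)
        q[i - 1] = cur - prev + (p.v_inj / p.v0) * (cur + prev) / 2.0
        prev = cur
    return q


def molar_ratio(p: ITCProtocol) -> np.ndarray:
    """Titrant-to-macromolecule molar ratio X_t/M_t after each injection."""
    out = np.empty(p.n_inj)
    for i in range(1, p.n_inj + 1):
        m_t, x_t, _ = injection_state(p, i)
        out[i - 1] = x_t / m_t
    return out


def integrate_thermogram(
    times: Sequence[float],
    power: Sequence[float],
    injection_times: Sequence[float],
    window: float,
) -> np.ndarray:
    """Per-injection heats from a power trace (ucal from ucal/s input).

    The baseline is the median power outside all injection windows; each
    injection's heat is the trapezoidal integral of baseline-subtracted
    power over [t_inj, t_inj + window).  Windows must not overlap.
    """
    t = np.asarray(times, dtype=float)
    pw = np.asarray(power, dtype=float)
    if t.ndim != 1 or t.shape != pw.shape:
        raise ValueError("times and power must be 1-D and equally long")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    starts = np.asarray(sorted(injection_times), dtype=float)
    if np.any(np.diff(starts) < window):
        raise ValueError("injection windows overlap")
    in_window = np.zeros_like(t, dtype=bool)
    for s in starts:
        in_window |= (t >= s) & (t < s + window)
    baseline = float(np.median(pw[~in_window])) if (~in_window).any() else 0.0
    heats = np.empty(len(starts))
    for k, s in enumerate(starts):
        mask = (t >= s) & (t < s + window)
        heats[k] = np.trapezoid(pw[mask] - baseline, t[mask]) \
            if mask.sum() >= 2 else 0.0
    return heats


_DEFAULT_KA_STARTS = (1e3, 1e4, 1e5, 1e6, 1e7, 1e8)
_DEFAULT_N_STARTS = (0.5, 1.0, 2.0)


def fit_single_site(
    heats: Sequence[float],
    p: ITCProtocol,
    init: tuple[float, float, float] | None = None,
    drop_first: bool = False,
) -> ITCFitResult:
    """Estimate (Ka, dH, n) from integrated injection heats.

    Nonlinear least squares in (log10 Ka, dH, n) space.  Without ``init`` a
    grid of starting points covers Ka over 1e3..1e8 /M and n in
    {0.5, 1, 2}, with dH initialized from the early-injection heat scale.
    ``drop_first`` excludes the (often anomalous) first injection from the
    residuals.  All-flat heats are unidentifiable and reported with
    ``converged=False``.
    """
    heats = np.asarray(heats, dtype=float)
    if heats.size != p.n_inj:
        raise ValueError(f"expected {p.n_inj} heats, got {heats.size}")
    if heats.size < 5:
        raise ValueError("need at least 5 injections to fit")
    weight = np.ones_like(heats)
    if drop_first:
        weight[0] = 0.0

    scale = np.abs(heats).max()
    if scale == 0.0 or not np.isfinite(scale):
        return ITCFitResult(ka=1.0, dh=0.0, n=1.0, residual_sse=0.0,
                            converged=False)

    def residuals(params: np.ndarray) -> np.ndarray:
        log_ka, dh, n = params
        model = simulate_isotherm(10.0 ** log_ka, dh, n, p)
        return (model - heats) * weight

    # dH guess: heat of an early injection divided by the moles it delivers
    moles_per_inj = p.syringe_conc * p.v_inj * \
        KCAL_PER_MOL_TIMES_M_UL_TO_UCAL
    dh0 = float(heats[:3].mean() / moles_per_inj)
    if dh0 == 0.0:
        dh0 = float(heats.sum() / (p.n_inj * moles_per_inj))

    if init is not None:
        starts = [(np.log10(init[0]), init[1], init[2])]
    else:
        starts = [(np.log10(ka0), dh0, n0)
                  for ka0 in _DEFAULT_KA_STARTS
                  for n0 in _DEFAULT_N_STARTS]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, x0=np.asarray(x0, dtype=float),
                bounds=([-1.0, -1e4, 1e-3], [12.0, 1e4, 1e2]),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:  # a bad start may push the model out of range
            continue
        sse = float(np.sum(sol.fun ** 2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        return ITCFitResult(ka=1.0, dh=dh0, n=1.0,
                            residual_sse=float("inf"), converged=False)
    sse, sol = best
    log_ka, dh, n = sol.x
    identifiable = sse < (scale * heats.size) ** 2  # any fit at all
    return ITCFitResult(
        ka=float(10.0 ** log_ka), dh=float(dh), n=float(n),
        residual_sse=sse, converged=bool(sol.success and identifiable),
    )
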