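"""Hill-equation analysis of binding titrations.

A microscale-thermophoresis (MST) titration reports a signal S_obs as a
function of ligand concentration C at fixed labeled-partner
concentration.  The cooperative binding isotherm is the Hill equation

    S_obs = S_U + (S_B - S_U) * C^n / (K_D + C^n)

where S_U and S_B are the unbound and bound signals, n the Hill
coefficient, and K_D the dissociation constant in the printed form of the
equation, which carries units of concentration^n.  To make affinities
comparable across different n the fit is parameterized by the apparent
dissociation constant K_d,app = K_D^(1/n) — the ligand concentration at
half saturation — and both forms are reported.

The titration design generator reproduces the serial-dilution layout used
in practice: 16 two-fold dilutions from a 100 uM top concentration reach
100/2^15 uM ~ 3 nM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .errors import DegenerateDataError, FitConvergenceError

__all__ = ["Titration", "HillFit", "hill_signal", "fit_hill", "simulate_titration"]


@dataclass(frozen=True)
class Titration:
    """Ligand concentrations (molar) vs observed signal at fixed partner."""

    ligand_concentration: np.ndarray
    signal: np.ndarray
    fixed_partner_concentration: float = 100e-9

    def __post_init__(self):
        c = np.asarray(self.ligand_concentration, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "ligand_concentration", c)
        object.__setattr__(self, "signal", s)
        if c.shape != s.shape or c.ndim != 1:
            raise DegenerateDataError("concentration and signal must match 1-D arrays")
        if np.any(c < 0):
            raise DegenerateDataError("concentrations must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.ligand_concentration.size)


@dataclass(frozen=True)
class HillFit:
    """Hill-equation parameters with uncertainties and fit diagnostics.

    ``kd_app`` is the half-saturation concentration K_D^(1/n) in molar;
    ``kd_raw`` is K_D as it appears in the equation, in molar^n.
    """

    s_unbound: float
    s_bound: float
    kd_app: float
    hill_n: float
    kd_raw: float = None  # type: ignore[assignment]
    stderr: dict = field(default_factory=dict)
    residual_sum_squares: float = float("nan")
    n_points: int = 0
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kd_app <= 0:
            raise DegenerateDataError("K_d must be positive")
        if self.hill_n <= 0:
            raise DegenerateDataError("Hill coefficient must be positive")
        if self.kd_raw is None:
            object.__setattr__(self, "kd_raw", self.kd_app ** self.hill_n)

    @classmethod
    def from_parameters(cls, s_unbound: float, s_bound: float,
                        kd_app: float, hill_n: float) -> "HillFit":
        """Construct generating parameters (e.g. for simulation) without a fit."""
        return cls(s_unbound=s_unbound, s_bound=s_bound,
                   kd_app=kd_app, hill_n=hill_n)

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        return hill_signal(np.asarray(concentration, dtype=float),
                           self.s_unbound, self.s_bound, self.kd_app, self.hill_n)


def hill_signal(concentration, s_unbound, s_bound, kd_app, hill_n):
    """Hill isotherm, numerically safe at zero concentration."""
    c = np.asarray(concentration, dtype=float)
    frac = np.zeros_like(c)
    pos = c > 0
    ratio = (kd_app / c[pos]) ** hill_n
    frac[pos] = 1.0 / (1.0 + ratio)
    return s_unbound + (s_bound - s_unbound) * frac


def fit_hill(titration: Titration,
             fix_hill_n: float | None = None) -> HillFit:
    """Least-squares Hill fit of a titration.

    S_U / S_B are initialized from the signals at the lowest and highest
    concentrations, K_d,app from the concentration nearest half signal
    range, and n from 1.  Pass ``fix_hill_n`` to constrain the Hill
    coefficient (e.g. 1 for non-cooperative binding); the residual sum of
    squares lets free-n and constrained fits be compared.

    A ``"saturation-not-approached"`` warning is attached when the fitted
    bound-state signal lies outside the observed range by more than half
    the dynamic range.
    """
    c, s = titration.ligand_concentration, titration.signal
    if titration.n_points < 6:
        raise DegenerateDataError("need >= 6 titration points")
    pos = c[c > 0]
    if pos.size < 2 or pos.max() / pos.min() < 10:
        raise DegenerateDataError("titration must span at least one decade")

    order = np.argsort(c)
    s_u0 = float(s[order[0]])
    s_b0 = float(s[order[-1]])
    half = 0.5 * (s_u0 + s_b0)
    kd0 = float(pos[np.argmin(np.abs(s[c > 0] - half))])

    model = Model(hill_signal)
    params = model.make_params(s_unbound=s_u0, s_bound=s_b0, kd_app=kd0, hill_n=1.0)
    params["kd_app"].set(min=pos.min() / 1e4, max=pos.max() * 1e4)
    params["hill_n"].set(min=0.05, max=10.0)
    if fix_hill_n is not None:
        params["hill_n"].set(value=float(fix_hill_n), vary=False)

    result = model.fit(s, params, concentration=c)
    if not result.success:
        raise FitConvergenceError(f"Hill fit did not converge: {result.message}")

    vals = result.params
    warnings = []
    span = float(s.max() - s.min())
    if span > 0 and not (s.min() - 0.5 * span
                         <= vals["s_bound"].value <= s.max() + 0.5 * span):
        warnings.append("saturation-not-approached")

    stderr = {name: (p.stderr if p.stderr is not None else float("nan"))
              for name, p in vals.items()}
    return HillFit(
        s_unbound=float(vals["s_unbound"].value),
        s_bound=float(vals["s_bound"].value),
        kd_app=float(vals["kd_app"].value),
        hill_n=float(vals["hill_n"].value),
        stderr=stderr,
        residual_sum_squares=float(np.sum(result.residual ** 2)),
        n_points=titration.n_points,
        warnings=tuple(warnings),
    )


def simulate_titration(params: HillFit,
                       top_concentration: float = 100e-6,
                       n_points: int = 16,
                       dilution_factor: float = 2.0,
                       noise_sd: float = 0.0,
                       seed: int | None = None,
                       fixed_partner_concentration: float = 100e-9) -> Titration:
    """Simulate a serial-dilution titration from Hill parameters.

    The concentration ladder is ``top / factor^i`` for i = 0..n_points-1
    (descending); Gaussian noise of standard deviation ``noise_sd`` (in
    signal units) is added with the given seed.  Defaults reproduce the
    16-point two-fold design from a 100 uM top concentration.
    """
    if n_points < 2:
        raise DegenerateDataError("need at least 2 points")
    if dilution_factor <= 1:
        raise DegenerateDataError("dilution_factor must be > 1")
    if noise_sd < 0:
        raise DegenerateDataError("noise_sd must be >= 0")
    conc = top_concentration / dilution_factor ** np.arange(n_points)
    signal = params.predict(conc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=conc.shape)
    return Titration(ligand_concentration=conc, signal=signal,
                     fixed_partner_concentration=fixed_partner_concentration)
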