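"""1:1 SPR kinetics, sigmoidal dose-response fits, and competition capacity.

Three small models support the mechanistic story:

* the Langmuir 1:1 interaction — association R(t) = R_eq(1 − e^{−(k_a C + k_d)t})
  with R_eq = R_max C/(C + K_D), first-order dissociation, and K_D = k_d/k_a;
  sensorgrams across a concentration series are fit globally for (k_a, k_d,
  R_max);
* the four-parameter logistic ("sigmoidal dose response, variable slope")
  used for EC50/IC50 extraction;
* a mass-action competition model in which an inhibitor with n independent
  antigen-binding "trap" sites depletes free antigen before it can reach an
  immobilised receptor — in the tight-binding (stoichiometric) regime the
  molar IC50 scales inversely with n, which is the capacity advantage of a
  molecule that traps two antigen dimers instead of one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "KineticParams",
    "Sensorgram",
    "DoseResponseFit",
    "CompetitionSetup",
    "BindingModelError",
    "FitConvergenceError",
    "kd_from_rates",
    "simulate_sensorgram",
    "fit_one_to_one",
    "fourpl_fit",
    "fourpl_curve",
    "equilibrium_competition",
    "capacity_curve",
]


class BindingModelError(ValueError):
    """Invalid kinetic/dose-response input."""


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the final residual."""


@dataclass
class KineticParams:
    ka: float  # 1/(M·s)
    kd: float  # 1/s
    rmax: float = 100.0  # response units
    ka_stderr: Optional[float] = None
    kd_stderr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ka <= 0 or self.kd <= 0:
            raise BindingModelError("rate constants must be positive")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant in M."""
        return self.kd / self.ka


@dataclass
class Sensorgram:
    time: np.ndarray  # s
    response: np.ndarray  # RU
    analyte_conc: float  # M
    t_assoc_end: float  # s, boundary between association and dissociation

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.response = np.asarray(self.response, float)
        if len(self.time) != len(self.response):
            raise BindingModelError("time and response must have equal length")
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise BindingModelError("time must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise BindingModelError("response contains non-finite values")


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ec50: float  # M; the inflection dose (IC50 for inhibition curves)
    hill: float
    residual_norm: float
    inverted: bool = False  # True for decreasing (inhibition) curves

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise BindingModelError("EC50 must be positive")


def kd_from_rates(ka: float, kd: float) -> float:
    """K_D = k_d / k_a expressed in picomolar.

    E.g. k_a = 81.3×10⁵ M⁻¹s⁻¹ with k_d = 8.08×10⁻⁵ s⁻¹ gives 9.94 pM.
    """
    if ka <= 0 or kd <= 0:
        raise BindingModelError("rate constants must be positive")
    return kd / ka * 1e12


def _langmuir_response(
    t: np.ndarray, ka: float, kd: float, rmax: float, conc: float, t_assoc_end: float
) -> np.ndarray:
    """Closed-form 1:1 response over association and dissociation phases."""
    t = np.asarray(t, float)
    r = np.zeros_like(t)
    if conc > 0:
        kobs = ka * conc + kd
        req = rmax * conc / (conc + kd / ka)
        assoc = t <= t_assoc_end
        r[assoc] = req * (1.0 - np.exp(-kobs * t[assoc]))
        r_end = req * (1.0 - math.exp(-kobs * t_assoc_end))
        r[~assoc] = r_end * np.exp(-kd * (t[~assoc] - t_assoc_end))
    return r


def simulate_sensorgram(
    params: KineticParams,
    conc: float,
    t_assoc: float,
    t_diss: float,
    *,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> Sensorgram:
    """Simulate a 1:1 sensorgram (association then dissociation phase)."""
    if t_assoc <= 0 or t_diss < 0:
        raise BindingModelError("phase durations must be positive")
    if conc < 0:
        raise BindingModelError("analyte concentration must be >= 0")
    time = np.arange(0.0, t_assoc + t_diss + dt / 2, dt)
    resp = _langmuir_response(time, params.ka, params.kd, params.rmax, conc, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(0.0, noise_sd, time.shape)
    return Sensorgram(time=time, response=resp, analyte_conc=conc, t_assoc_end=t_assoc)


_MULTISTART_SEEDS = (0, 1, 2, 3, 4)  # fixed multi-start offsets: reproducible fits


def fit_one_to_one(
    sensorgrams: Sequence[Sensorgram],
    *,
    drop_top_concentration: bool = False,
) -> KineticParams:
    """Global 1:1 fit of (k_a, k_d, R_max) across a concentration series.

    Nonlinear least squares on log-parameters, multi-started from a fixed
    grid of perturbed initial guesses; the best run wins. Standard errors come
    from the Jacobian at the optimum. ``drop_top_concentration`` discards the
    highest-concentration curve before fitting, mirroring the common practice
    of removing top curves distorted by nonspecific binding.

    A single-concentration input cannot identify k_a and k_d separately; this
    raises a conditioning error rather than returning an unstable fit.
    """
    curves = sorted(sensorgrams, key=lambda s: s.analyte_conc)
    if drop_top_concentration and len(curves) > 1:
        curves = curves[:-1]
    concs = {c.analyte_conc for c in curves if c.analyte_conc > 0}
    if len(concs) < 2:
        raise BindingModelError(
            "ill-conditioned: need >=2 distinct positive analyte concentrations "
            "to separate ka from kd"
        )

    rmax0 = max(float(np.max(c.response)) for c in curves) or 1.0
    cmid = float(np.median(sorted(concs)))
    # crude initial rates: assume KD near the mid concentration, kobs ~ 1/span
    span = max(c.t_assoc_end for c in curves)
    ka0 = 1.0 / (cmid * span)
    kd0 = ka0 * cmid

    def residuals(log_params: np.ndarray) -> np.ndarray:
        ka, kd, rmax = np.exp(np.clip(log_params, -200.0, 200.0))
        out = [
            c.response - _langmuir_response(c.time, ka, kd, rmax, c.analyte_conc, c.t_assoc_end)
            for c in curves
        ]
        return np.concatenate(out)

    best = None
    for i in _MULTISTART_SEEDS:
        jitter = 10.0 ** (i - len(_MULTISTART_SEEDS) // 2)
        x0 = np.log([ka0 * jitter, kd0 * jitter, rmax0])
        try:
            sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=20_000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError("1:1 fit did not converge from any start")

    ka, kd, rmax = np.exp(best.x)
    # covariance of log-params from J^T J; delta-method back to linear scale
    stderr = (None, None)
    try:
        jtj = best.jac.T @ best.jac
        dof = max(1, best.fun.size - 3)
        cov = np.linalg.inv(jtj) * 2.0 * best.cost / dof
        log_sd = np.sqrt(np.diag(cov))
        stderr = (ka * log_sd[0], kd * log_sd[1])
    except np.linalg.LinAlgError:
        pass
    return KineticParams(ka=ka, kd=kd, rmax=rmax, ka_stderr=stderr[0], kd_stderr=stderr[1])


def fourpl_curve(dose: np.ndarray, bottom: float, top: float, ec50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic: bottom + (top − bottom)/(1 + (EC50/dose)^hill)."""
    dose = np.asarray(dose, float)
    return bottom + (top - bottom) / (1.0 + (ec50 / dose) ** hill)


def fourpl_fit(dose: Sequence[float], response: Sequence[float]) -> DoseResponseFit:
    """Fit a sigmoidal dose-response (variable slope) model.

    Doses must be positive; at least 5 doses are required. Decreasing
    (inhibition) curves are detected and flagged ``inverted``; the reported
    ``ec50`` is then the IC50. A flat response cannot define an inflection
    dose and raises a degenerate-fit error.
    """
    dose = np.asarray(dose, float)
    resp = np.asarray(response, float)
    if len(dose) != len(resp):
        raise BindingModelError("dose and response must have equal length")
    if len(dose) < 5:
        raise BindingModelError("need at least 5 doses for a 4PL fit")
    if np.any(dose <= 0):
        raise BindingModelError("doses must be positive")
    spread = float(np.max(resp) - np.min(resp))
    scale = max(abs(float(np.max(resp))), abs(float(np.min(resp))), 1e-300)
    if spread <= 1e-9 * scale:
        raise BindingModelError("degenerate fit: response is flat across doses")

    order = np.argsort(dose)
    increasing = resp[order][-1] >= resp[order][0]
    b0, t0 = float(np.min(resp)), float(np.max(resp))
    ec0 = float(np.exp(np.mean(np.log(dose))))
    h0 = 1.0 if increasing else -1.0

    def residuals(p: np.ndarray) -> np.ndarray:
        bottom, top, log_ec50, hill = p
        return fourpl_curve(dose, bottom, top, np.exp(log_ec50), hill) - resp

    best = None
    for h_start in (h0, 2.0 * h0, 0.5 * h0):
        try:
            sol = optimize.least_squares(
                residuals, np.array([b0, t0, math.log(ec0), h_start]), max_nfev=20_000
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError("4PL fit did not converge")
    bottom, top, log_ec50, hill = best.x
    # (b, t, ec50, h) and (t, b, ec50, -h) describe the same curve; normalise to
    # top >= bottom, after which a negative slope marks an inhibition curve
    if top < bottom:
        bottom, top, hill = top, bottom, -hill
    inverted = hill < 0
    hill = abs(hill)
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        ec50=float(np.exp(log_ec50)),
        hill=float(hill),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        inverted=bool(inverted),
    )


# --------------------------------------------------------------------------
# equilibrium competition / capacity
# --------------------------------------------------------------------------

@dataclass
class CompetitionSetup:
    """Receptor-binding-inhibition assay at mass-action equilibrium.

    ``dimers_trapped_at_saturation`` is the number of independent antigen
    "trap" sites per inhibitor molecule that enter the equilibrium solve (the
    capacity); ``sites_per_inhibitor`` records the nominal paratope count for
    bookkeeping. ``vegf_total`` is the fixed antigen concentration in M (a
    10 ng/mL assay input converts via the antigen's dimer mass, e.g.
    10 ng/mL / 48 kDa ≈ 208 pM).
    """

    inhibitor_concs: np.ndarray  # M
    vegf_total: float  # M
    kd_inhibitor_site: float  # M, per-site
    kd_receptor_vegf: float = 1e-10  # M
    receptor_density: float = 1.0  # arbitrary signal units at full occupancy
    sites_per_inhibitor: int = 2
    dimers_trapped_at_saturation: int = 2

    def __post_init__(self) -> None:
        self.inhibitor_concs = np.asarray(self.inhibitor_concs, float)
        if np.any(self.inhibitor_concs < 0) or self.vegf_total < 0:
            raise BindingModelError("concentrations must be >= 0")
        if self.sites_per_inhibitor < 1 or self.dimers_trapped_at_saturation < 1:
            raise BindingModelError("site counts must be >= 1")
        if self.kd_inhibitor_site < 0 or self.kd_receptor_vegf <= 0:
            raise BindingModelError("dissociation constants must be positive")


def _free_vegf(v_tot: float, site_tot: float, kd: float) -> float:
    """Solve V_tot = V_f + S_tot·V_f/(K_d + V_f) for free antigen V_f.

    Quadratic in V_f: V_f² + (K_d + S_tot − V_tot)·V_f − K_d·V_tot = 0;
    the positive root is the physical one. ``kd = 0`` is the infinitely tight
    (purely stoichiometric) limit.
    """
    if v_tot == 0:
        return 0.0
    if kd == 0:
        return max(v_tot - site_tot, 0.0)
    b = kd + site_tot - v_tot
    v_f = 0.5 * (-b + math.sqrt(b * b + 4.0 * kd * v_tot))
    return max(v_f, 0.0)


def equilibrium_competition(setup: CompetitionSetup) -> tuple[pd.DataFrame, DoseResponseFit]:
    """Solve the competition equilibrium over an inhibitor titration.

    For each inhibitor concentration I, the free antigen V_f satisfies mass
    conservation against n·I independent trap sites with per-site K_d; the
    receptor-bound signal is proportional to receptor occupancy by free
    antigen, V_f/(K_d,R + V_f), normalised to the no-inhibitor control. The
    IC50 comes from a 4PL fit of signal versus inhibitor concentration.
    """
    n = setup.dimers_trapped_at_saturation
    v0 = _free_vegf(setup.vegf_total, 0.0, setup.kd_inhibitor_site)
    control = setup.receptor_density * v0 / (setup.kd_receptor_vegf + v0)
    if control <= 0:
        raise BindingModelError("no receptor signal without inhibitor; check vegf_total")
    rows = []
    for conc in setup.inhibitor_concs:
        site_tot = n * conc
        v_f = _free_vegf(setup.vegf_total, site_tot, setup.kd_inhibitor_site)
        if setup.kd_inhibitor_site == 0:
            bound = min(site_tot, setup.vegf_total)
            occupied_sites = bound
        else:
            bound = site_tot * v_f / (setup.kd_inhibitor_site + v_f)
            occupied_sites = bound
        signal = setup.receptor_density * v_f / (setup.kd_receptor_vegf + v_f) / control
        rows.append(
            {
                "inhibitor_conc": float(conc),
                "free_vegf": v_f,
                "free_vegf_fraction": v_f / setup.vegf_total if setup.vegf_total else 0.0,
                "inhibitor_bound_vegf": float(bound),
                "free_sites": float(site_tot - occupied_sites),
                "bound_signal": float(signal),
            }
        )
    table = pd.DataFrame(rows)
    positive = table[table.inhibitor_conc > 0]
    fit = fourpl_fit(positive.inhibitor_conc.to_numpy(), positive.bound_signal.to_numpy())
    return table, fit


def capacity_curve(
    architectures: Sequence[tuple],
    vegf_total: float,
    ratios: Sequence[float],
    kd_site: float = 1e-12,
) -> pd.DataFrame:
    """Antigen dimers sequestered per inhibitor molecule across a titration.

    ``architectures`` is a list of ``(name, dimers_trapped_at_saturation)``.
    For each inhibitor:antigen molar ratio the equilibrium is solved and the
    bound antigen per mole of inhibitor reported; at antigen excess the value
    approaches the per-molecule capacity (2 for the dual-dAb layout, 1 for a
    1:1 trap).
    """
    if vegf_total < 0:
        raise BindingModelError("vegf_total must be >= 0")
    rows = []
    for name, n_trap in architectures:
        for ratio in ratios:
            inhibitor = ratio * vegf_total
            if inhibitor == 0 or vegf_total == 0:
                per_molecule = 0.0
            else:
                v_f = _free_vegf(vegf_total, n_trap * inhibitor, kd_site)
                per_molecule = (vegf_total - v_f) / inhibitor
            rows.append(
                {
                    "architecture": name,
                    "inhibitor_to_vegf_ratio": float(ratio),
                    "dimers_per_molecule": float(per_molecule),
                    "capacity_asymptote": float(n_trap),
                }
            )
    return pd.DataFrame(rows)
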