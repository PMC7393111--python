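"""Force-dependent unfolding kinetics under a Kramers-like rate law.

The Dudko-Hummer-Szabo (DHS) family of escape-rate laws describes the
unfolding rate of a folded domain under force F as

    k(F) = (1/tau0) * u**(1/nu - 1) * exp{ dG * [1 - u**(1/nu)] },
    u(F) = 1 - nu * F * dx / (dG * kBT),

with intrinsic folded-state lifetime tau0 (s), transition-state distance dx
(nm), barrier height dG (kBT units) and shape exponent nu (1/2 linear-cubic
cusp, 2/3 linear-cubic, 1 the Bell limit, where dG drops out). The raw
formula is valid below the critical force F_c = dG*kBT/(nu*dx), at which the
barrier vanishes.

Under a constant loading rate r (pN/s) the cumulative hazard along the ramp
has the closed form

    Lambda(F) = (kBT / (tau0 * dx * r)) * [exp(E(F)) - 1],
    E(F) = dG * [1 - u**(1/nu)],

which yields the rupture-force survival S(F) = exp(-Lambda), density
p(F|r) = k(F)/r * S(F), and an exact inverse-CDF sampler.

Capped-hazard policy: for nu < 1 the raw k(F) rises, peaks, and drops to zero
at F_c. The hazard used in likelihoods and lifetimes here is the running
maximum of k over [0, F] — i.e. k is evaluated at min(F, F*) where F* is the
analytic maximizer — and is held constant beyond F*. This keeps the
likelihood finite for rips observed at or above the fitted model's critical
force instead of silently extrapolating the raw formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polymer import KBT_ROOM

NU_DEFAULT = 2.0 / 3.0


@dataclass(frozen=True)
class BarrierParams:
    """DHS landscape parameters.

    ``log10_tau0`` is log10 of the intrinsic folded-state lifetime in
    seconds; ``dx_ddagger`` in nm; ``dG_ddagger`` in kBT units; ``nu`` the
    shape exponent; ``thermal_energy`` kBT in pN*nm.
    """

    log10_tau0: float
    dx_ddagger: float
    dG_ddagger: float
    nu: float = NU_DEFAULT
    thermal_energy: float = KBT_ROOM

    def __post_init__(self) -> None:
        if self.dx_ddagger <= 0:
            raise ValueError("dx_ddagger must be positive")
        if self.dG_ddagger <= 0:
            raise ValueError("dG_ddagger must be positive")
        if self.thermal_energy <= 0:
            raise ValueError("thermal_energy must be positive")
        if not 0 < self.nu <= 1:
            raise ValueError("nu must lie in (0, 1]")

    @property
    def tau0(self) -> float:
        """Intrinsic folded-state lifetime, s."""
        return 10.0 ** self.log10_tau0

    @property
    def k0(self) -> float:
        """Zero-force unfolding rate, 1/s."""
        return 10.0 ** (-self.log10_tau0)

    @property
    def critical_force(self) -> float:
        """Force at which the model barrier vanishes, pN (inf in the Bell limit)."""
        if self.nu == 1.0:
            return np.inf
        return self.dG_ddagger * self.thermal_energy / (self.nu * self.dx_ddagger)

    @property
    def peak_force(self) -> float:
        """Force maximizing the raw rate: u* = ((1-nu)/dG)**nu (inf for nu=1)."""
        if self.nu == 1.0:
            return np.inf
        u_star = ((1.0 - self.nu) / self.dG_ddagger) ** self.nu
        return (1.0 - u_star) * self.critical_force


def _raw_log_rate(force, p: BarrierParams):
    """log k(F) of the raw DHS formula; force must satisfy u(F) > 0."""
    f = np.asarray(force, dtype=float)
    log_k0 = -p.log10_tau0 * np.log(10.0)
    if p.nu == 1.0:  # Bell limit: barrier height cancels, valid for all F
        return log_k0 + f * p.dx_ddagger / p.thermal_energy
    u = 1.0 - p.nu * f * p.dx_ddagger / (p.dG_ddagger * p.thermal_energy)
    inv_nu = 1.0 / p.nu
    return log_k0 + (inv_nu - 1.0) * np.log(u) + p.dG_ddagger * (1.0 - u**inv_nu)


def unfolding_rate(force, params: BarrierParams):
    """Unfolding rate k(F) in 1/s under the capped-hazard policy.

    Equals the raw DHS rate for F <= F* (the rate maximizer) and k(F*) for
    larger forces, so it is defined and positive for every F >= 0.
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    f_eff = np.minimum(f, params.peak_force)
    k = np.exp(_raw_log_rate(f_eff, params))
    return k if k.ndim else float(k)


def folded_lifetime(force, params: BarrierParams):
    """Folded-state lifetime tau(F) = 1/k(F), s."""
    k = unfolding_rate(force, params)
    return 1.0 / k


def _exp_E(force, p: BarrierParams):
    """exp(E(F)) with E = dG*[1 - u**(1/nu)], valid up to the peak force."""
    f = np.asarray(force, dtype=float)
    u = 1.0 - p.nu * f * p.dx_ddagger / (p.dG_ddagger * p.thermal_energy)
    return np.exp(p.dG_ddagger * (1.0 - u ** (1.0 / p.nu)))


def cumulative_hazard(force, loading_rate, params: BarrierParams):
    """Integrated hazard Lambda(F) = int_0^F k(f)/r df along a constant ramp.

    Closed form below the rate maximizer; linear continuation (constant
    hazard) above it, matching the capped-hazard policy. Dimensionless,
    Lambda(0) = 0, strictly increasing.
    """
    f = np.asarray(force, dtype=float)
    r = np.asarray(loading_rate, dtype=float)
    if np.any(r <= 0):
        raise ValueError("loading_rate must be positive")
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    pref = params.thermal_energy / (params.tau0 * params.dx_ddagger)
    f_star = params.peak_force
    f_eff = np.minimum(f, f_star)
    lam = pref * (_exp_E(f_eff, params) - 1.0) / r
    if np.isfinite(f_star):
        over = f > f_star
        if np.any(over):
            k_star = float(np.exp(_raw_log_rate(f_star, params)))
            lam = lam + np.where(over, k_star * (f - f_eff) / r, 0.0)
    return lam if lam.ndim else float(lam)


def survival(force, loading_rate, params: BarrierParams):
    """Probability that the domain is still folded at force F on the ramp."""
    return np.exp(-cumulative_hazard(force, loading_rate, params))


def rip_force_pdf(force, loading_rate, params: BarrierParams):
    """Rupture-force density p(F|r) = k(F)/r * exp(-Lambda(F)), per pN."""
    k = unfolding_rate(force, params)
    lam = cumulative_hazard(force, loading_rate, params)
    return k / np.asarray(loading_rate, dtype=float) * np.exp(-lam)


def rip_force_cdf(force, loading_rate, params: BarrierParams):
    """Rupture-force CDF 1 - exp(-Lambda(F))."""
    return 1.0 - survival(force, loading_rate, params)


def sample_rip_forces(n, loading_rate, params: BarrierParams, seed=None):
    """Exact inverse-transform sampling of rupture forces on a constant ramp.

    Inverts the capped cumulative hazard, Lambda(F) = -ln U. Below the rate
    maximizer this is the closed form

        E* = ln(1 + (r * tau0 * dx / kBT) * (-ln U)),
        F  = (dG * kBT / (nu * dx)) * [1 - (1 - E*/dG)**nu];

    beyond it the hazard is constant, so the continuation is linear in F.
    Draws that would rupture only at or past the vanishing barrier are
    recorded as censored at the critical force. ``loading_rate`` may be a
    scalar or an array of per-event rates of length ``n``; ``seed`` may be an
    int or a Generator.

    Returns
    -------
    forces : ndarray shape (n,)
    censored : ndarray of bool, shape (n,)
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r = np.broadcast_to(np.asarray(loading_rate, dtype=float), (n,))
    if np.any(r <= 0):
        raise ValueError("loading_rate must be positive")
    u_draw = rng.uniform(size=n)
    lam_target = -np.log(u_draw)
    kbt, dx, dg, nu = params.thermal_energy, params.dx_ddagger, params.dG_ddagger, params.nu
    e_star = np.log1p(r * params.tau0 * dx / kbt * lam_target)
    if nu == 1.0:
        forces = e_star * kbt / dx
        return forces, np.zeros(n, dtype=bool)
    f_peak = params.peak_force
    e_peak = dg * (1.0 - (1.0 - f_peak * nu * dx / (dg * kbt)) ** (1.0 / nu))
    below = e_star <= e_peak
    e_clip = np.minimum(e_star, e_peak)
    forces = (dg * kbt / (nu * dx)) * (1.0 - (1.0 - e_clip / dg) ** nu)
    if not np.all(below):
        k_peak = float(np.exp(_raw_log_rate(f_peak, params)))
        lam_peak = kbt / (params.tau0 * dx) * (np.exp(e_peak) - 1.0) / r
        forces = np.where(below, forces, f_peak + (lam_target - lam_peak) * r / k_peak)
    censored = forces >= params.critical_force
    forces = np.where(censored, params.critical_force, forces)
    return forces, censored


# ---------------------------------------------------------------------------
# rip events and histogram-based lifetime transform


@dataclass(frozen=True)
class RipEvent:
    """One rupture observation from a force-ramp experiment."""

    molecule_id: str
    condition: str
    rip_force: float  # pN
    loading_rate: float  # pN/s
    delta_extension: float | None = None  # nm
    trap_velocity: float | None = None  # nm/s
    censored: bool = False

    def __post_init__(self) -> None:
        if self.rip_force <= 0:
            raise ValueError("rip_force must be positive")
        if self.loading_rate <= 0:
            raise ValueError("loading_rate must be positive")


def events_to_frame(events) -> pd.DataFrame:
    """Tabulate a sequence of RipEvent as a DataFrame (CSV dialect columns)."""
    return pd.DataFrame(
        {
            "molecule_id": [e.molecule_id for e in events],
            "condition": [e.condition for e in events],
            "rip_force_pN": [e.rip_force for e in events],
            "loading_rate_pN_s": [e.loading_rate for e in events],
            "delta_extension_nm": [e.delta_extension for e in events],
            "trap_velocity_nm_s": [e.trap_velocity for e in events],
            "censored": [e.censored for e in events],
        }
    )


def binned_lifetime_transform(events, bin_width: float) -> pd.DataFrame:
    """Histogram transform of rupture forces into force-dependent lifetimes.

    For bin i with midpoint F_i, counts h_i out of N total events and mean
    loading rate <r>_i within the bin,

        tau(F_i) = S(F_i) / (p(F_i) * <r>_i),
        S(F_i) = (h_i/2 + sum_{k>i} h_k) / N,   p(F_i) = h_i / (N * dF).

    Empty bins are skipped. A single occupied bin still yields an estimate
    but is flagged with a warning (no force dependence can be resolved).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    forces = np.array([e.rip_force for e in events], dtype=float)
    rates = np.array([e.loading_rate for e in events], dtype=float)
    if forces.size == 0:
        raise ValueError("no events")
    lo = bin_width * np.floor(forces.min() / bin_width)
    hi = bin_width * np.ceil(forces.max() / bin_width)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    h, _ = np.histogram(forces, bins=edges)
    n = forces.size
    occupied = np.nonzero(h)[0]
    if occupied.size == 1:
        warnings.warn("all events fall in a single force bin; lifetime-force dependence unresolved")
    rows = []
    for i in occupied:
        mid = 0.5 * (edges[i] + edges[i + 1])
        surv = (h[i] / 2.0 + h[i + 1 :].sum()) / n
        dens = h[i] / (n * bin_width)
        in_bin = (forces >= edges[i]) & (forces < edges[i + 1])
        if i == len(h) - 1:  # right edge inclusive in np.histogram
            in_bin |= forces == edges[-1]
        r_mean = rates[in_bin].mean()
        rows.append({"force_pN": mid, "lifetime_s": surv / (dens * r_mean), "count": int(h[i])})
    return pd.DataFrame(rows)


def barrier_shape_diagnostic(events, nu: float = NU_DEFAULT, thermal_energy: float = KBT_ROOM,
                             max_components: int = 2, seed: int = 0) -> dict:
    """Single-barrier vs two-component-mixture model comparison on rip forces.

    Fits a one-population DHS model and a two-component mixture (mixing
    weight plus two parameter triples sharing nu and kBT) by maximum
    likelihood and reports log-likelihoods, AIC, BIC and the BIC-preferred
    model. A broad, multimodal or heavy-tailed rupture-force distribution —
    the signature of unfolding from more than one native state — favors the
    mixture.
    """
    from . import mle  # deferred: mle imports this module

    if len(events) < 20:
        raise ValueError("need at least 20 events for a shape diagnostic")
    if max_components != 2:
        raise NotImplementedError("only a two-component mixture is implemented")

    single = mle.fit_global(events, nu=nu, thermal_energy=thermal_energy, n_bootstrap=0, seed=seed)
    n = len(events)
    ll1 = single.loglik

    forces = np.array([e.rip_force for e in events])
    rates = np.array([e.loading_rate for e in events])
    censored = np.array([e.censored for e in events])

    def mix_nll(x):
        w = 1.0 / (1.0 + np.exp(-x[0]))
        try:
            p1 = BarrierParams(x[1], x[2], x[3], nu=nu, thermal_energy=thermal_energy)
            p2 = BarrierParams(x[4], x[5], x[6], nu=nu, thermal_energy=thermal_energy)
        except ValueError:
            return 1e12
        d1 = np.where(censored, survival(forces, rates, p1), rip_force_pdf(forces, rates, p1))
        d2 = np.where(censored, survival(forces, rates, p2), rip_force_pdf(forces, rates, p2))
        dens = w * d1 + (1.0 - w) * d2
        if not np.all(np.isfinite(dens)):
            return 1e12
        return -float(np.sum(np.log(np.maximum(dens, 1e-300))))

    from scipy.optimize import minimize

    t = single.params
    lo_f, hi_f = np.quantile(forces, [0.3, 0.7])
    low = mle.fit_global([e for e in events if e.rip_force <= lo_f] or events[: n // 2],
                         nu=nu, thermal_energy=thermal_energy, n_bootstrap=0, seed=seed)
    high = mle.fit_global([e for e in events if e.rip_force >= hi_f] or events[n // 2 :],
                          nu=nu, thermal_energy=thermal_energy, n_bootstrap=0, seed=seed)
    starts = [
        np.array([0.0, low.params.log10_tau0, low.params.dx_ddagger, low.params.dG_ddagger,
                  high.params.log10_tau0, high.params.dx_ddagger, high.params.dG_ddagger]),
        np.array([0.0, t.log10_tau0 - 1.5, t.dx_ddagger, t.dG_ddagger,
                  t.log10_tau0 + 1.5, t.dx_ddagger, t.dG_ddagger]),
        np.array([0.0, t.log10_tau0, max(0.1, t.dx_ddagger - 0.7), t.dG_ddagger,
                  t.log10_tau0, t.dx_ddagger + 0.7, t.dG_ddagger]),
    ]
    bounds = [(-6, 6)] + list(mle.DEFAULT_BOUNDS) * 2
    best = None
    for x0 in starts:
        res = minimize(mix_nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success) and best.fun < 1e11
    ll2 = -best.fun
    k1, k2 = 3, 7
    report = {
        "n_events": n,
        "loglik_single": ll1,
        "loglik_mixture": ll2,
        "aic_single": 2 * k1 - 2 * ll1,
        "aic_mixture": 2 * k2 - 2 * ll2,
        "bic_single": k1 * np.log(n) - 2 * ll1,
        "bic_mixture": k2 * np.log(n) - 2 * ll2,
        "mixture_converged": converged,
        "mixture_weight": float(1.0 / (1.0 + np.exp(-best.x[0]))),
        "single_params": single.params,
        "mixture_params": (
            BarrierParams(*best.x[1:4], nu=nu, thermal_energy=thermal_energy),
            BarrierParams(*best.x[4:7], nu=nu, thermal_energy=thermal_energy),
        ),
    }
    if not converged:
        report["preferred"] = "inconclusive"
    else:
        report["preferred"] = "single" if report["bic_single"] <= report["bic_mixture"] else "mixture"
    return report
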