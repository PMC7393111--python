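"""Motor-force inference by lifetime matching.

During translocation the motor holds the folded roadblock under load while
it is stalled; the measured unfolding rate k_unfold (1/min) therefore
corresponds to a folded-state lifetime of 60/k_unfold seconds. The
equivalent constant force is the unique F at which the force-spectroscopy
lifetime law tau(F) equals that value — unique because tau is strictly
decreasing up to the rate maximizer. No duty-cycle correction is applied:
if the motor loads the substrate only intermittently, the true peak force is
higher than the equivalent constant force reported here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import BarrierParams, folded_lifetime
from .mle import BarrierFit

#: rates arrive in 1/min, lifetimes in s
SECONDS_PER_MINUTE = 60.0


@dataclass
class TransloconForceEstimate:
    """Matched motor force with Monte-Carlo propagated uncertainty."""

    force: float  # pN
    sd_force: float  # pN
    k_unfold_used: float  # 1/min
    sd_k_unfold: float  # 1/min
    n_mc: int
    seed: int | None
    n_unsolvable: int = 0
    flagged: bool = False

    def to_dict(self) -> dict:
        return {
            "force_pN": self.force,
            "sd_force_pN": self.sd_force,
            "k_unfold_per_min": self.k_unfold_used,
            "sd_k_unfold_per_min": self.sd_k_unfold,
            "n_mc": self.n_mc,
            "seed": self.seed,
            "n_unsolvable": self.n_unsolvable,
            "flagged": self.flagged,
        }


def solve_translocon_force(k_unfold: float, params: BarrierParams, tol: float = 1e-4) -> float:
    """Force at which the folded-state lifetime equals 60/k_unfold seconds.

    ``k_unfold`` is in 1/min. Returns 0 (with a warning) when the observed
    lifetime is not shorter than the intrinsic lifetime tau0, i.e. no
    positive force is needed to explain the observed unfolding.
    """
    if k_unfold <= 0:
        raise ValueError("k_unfold must be positive")
    target = SECONDS_PER_MINUTE / k_unfold  # s
    if target >= params.tau0:
        warnings.warn("observed lifetime exceeds the intrinsic lifetime; force pinned at 0")
        return 0.0
    f_star = params.peak_force
    hi = f_star if np.isfinite(f_star) else params.thermal_energy / params.dx_ddagger * 500.0
    tau_min = folded_lifetime(hi * (1 - 1e-12), params)
    if target <= tau_min:
        raise ValueError("observed lifetime below the model's minimum lifetime; no solution")
    return brentq(lambda f: np.log(folded_lifetime(f, params)) - np.log(target),
                  0.0, hi, xtol=tol)


def propagate_force_uncertainty(k_unfold: float, sd_k_unfold: float, fit: BarrierFit,
                                n_mc: int = 1000, seed: int | None = 0) -> TransloconForceEstimate:
    """Monte-Carlo propagation of rate and barrier-parameter uncertainty.

    Barrier parameters are drawn from the fit's bootstrap replicates when
    available (otherwise a Gaussian with the fit covariance); k_unfold from
    Normal(mean, SD) truncated to positive values. Each draw is solved for
    the matching force; draws with no positive-force solution are counted,
    and the estimate is flagged if they exceed 20%.
    """
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    rng = np.random.default_rng(seed)
    point = solve_translocon_force(k_unfold, fit.params)

    if fit.bootstrap_replicates is not None and len(fit.bootstrap_replicates) >= 10:
        idx = rng.integers(0, len(fit.bootstrap_replicates), size=n_mc)
        param_draws = fit.bootstrap_replicates[idx]
    elif np.any(fit.covariance):
        param_draws = rng.multivariate_normal(
            [fit.params.log10_tau0, fit.params.dx_ddagger, fit.params.dG_ddagger],
            fit.covariance, size=n_mc)
    else:
        param_draws = np.tile(
            [fit.params.log10_tau0, fit.params.dx_ddagger, fit.params.dG_ddagger], (n_mc, 1))

    k_draws = rng.normal(k_unfold, sd_k_unfold, size=n_mc)
    forces = []
    n_bad = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for (lt, dx, dg), k in zip(param_draws, k_draws):
            if k <= 0 or dx <= 0 or dg <= 0:
                n_bad += 1
                continue
            try:
                p = BarrierParams(lt, dx, dg, nu=fit.params.nu,
                                  thermal_energy=fit.params.thermal_energy)
                forces.append(solve_translocon_force(k, p))
            except (ValueError, RuntimeError):
                n_bad += 1
    forces = np.asarray(forces)
    flagged = n_bad > 0.2 * n_mc
    if flagged:
        warnings.warn(f"{n_bad}/{n_mc} Monte-Carlo draws had no force solution; estimate flagged")
    sd = float(forces.std(ddof=1)) if forces.size > 1 else 0.0
    return TransloconForceEstimate(
        force=float(point), sd_force=sd, k_unfold_used=k_unfold, sd_k_unfold=sd_k_unfold,
        n_mc=n_mc, seed=seed, n_unsolvable=n_bad, flagged=flagged)


def lifetime_overlay_table(fit: BarrierFit, k_unfold_points, force_grid,
                           n_draws: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Plot-ready table: lifetime curve with SD band plus matched-force markers.

    One row per grid force with the curve (lifetime_s, sd_s) and, for each
    supplied k_unfold (1/min), constant columns carrying the horizontal
    lifetime level 60/k (s) and the intersection force (pN).
    """
    from .mle import lifetime_band

    tab = lifetime_band(fit, force_grid, n_draws=n_draws, seed=seed)
    for i, k in enumerate(k_unfold_points):
        tab[f"level_s_{i}"] = SECONDS_PER_MINUTE / k
        tab[f"intersection_pN_{i}"] = solve_translocon_force(k, fit.params)
    return tab
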