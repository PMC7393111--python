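"""Kinetic model of real-time split-luciferase translocation traces.

A stalled translocation intermediate is released at t = 0 (reduction of the
disulfide loop by DTT); the substrate then advances to the folded roadblock
domain, which must unfold before import can complete. The post-release state
scheme is

    S --k_unfold-->  U --k_transloc-->  T        (productive path)
    S --k_incap--->  X                           (dead end)

with S the roadblocked fraction (initially 1), U unfolded-and-translocating,
T fully imported (the luminescent species) and X incapacitated. Unfolding
competes with first-order incapacitation, so the asymptotic imported
fraction is T(inf) = k_unfold / (k_unfold + k_incap): slower unfolding at
constant incapacitation means smaller final amplitude, which is exactly what
breaks the usual two-exponential rate-swap degeneracy.

With a = k_unfold + k_incap the closed-form fractions are

    S(t) = exp(-a t)
    U(t) = k_unfold * (exp(-a t) - exp(-k_transloc t)) / (k_transloc - a)
    T(t) = (k_unfold/a) * [1 - (k_transloc exp(-a t) - a exp(-k_transloc t))
                               / (k_transloc - a)]
    X(t) = (k_incap/a) * (1 - exp(-a t))

and the observed signal is

    RLU(t) = exp(-k_deplete t) * A * (T(t) + T0) + baseline,

where A converts imported fraction to luminescence, k_deplete models
luciferase-substrate depletion as a multiplicative roll-off, T0 is the
pre-imported (loop-free) fraction already luminescent at t = 0, and baseline
is instrument background. Rates are in 1/min throughout this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

_DEGEN_EPS = 1e-9  # 1/min; switch to the analytic k_transloc -> a limit


@dataclass(frozen=True)
class TranslocationRates:
    """Per-condition kinetic rates, 1/min."""

    k_unfold: float
    k_transloc: float
    k_incap: float

    def __post_init__(self) -> None:
        if min(self.k_unfold, self.k_transloc, self.k_incap) < 0:
            raise ValueError("rates must be non-negative")


@dataclass(frozen=True)
class TraceNuisance:
    """Signal-model nuisance parameters of one trace."""

    amplitude: float  # RLU per unit imported fraction
    k_deplete: float = 0.0  # 1/min
    baseline: float = 0.0  # RLU
    pre_translocated: float = 0.0  # imported loop-free fraction at t = 0
    s0: float = 1.0  # initial roadblocked fraction (conventionally 1)

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.k_deplete < 0 or self.pre_translocated < 0:
            raise ValueError("k_deplete and pre_translocated must be non-negative")


@dataclass(frozen=True)
class LuminescenceTrace:
    """Time-stamped luminescence series with the reduction (t = 0) marker."""

    time: np.ndarray  # s
    rlu: np.ndarray  # relative light units
    t_dtt: float  # s; DTT addition defines the kinetic origin
    condition: str = ""
    replicate_id: str = ""
    sampling_rate: float = 0.2  # Hz

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.rlu, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "rlu", y)
        if t.ndim != 1 or t.size != y.size:
            raise ValueError("time and rlu must be 1-D and equally long")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("rlu must be finite")
        if not (t[0] <= self.t_dtt <= t[-1]):
            raise ValueError("t_dtt must lie within the recorded window")

    def post_dtt(self):
        """(t_min, rlu) with t = 0 at DTT addition, minutes."""
        sel = self.time >= self.t_dtt
        return (self.time[sel] - self.t_dtt) / 60.0, self.rlu[sel]


@dataclass
class TranslocationFit:
    """Fitted rates plus nuisance parameters for one trace."""

    rates: TranslocationRates | None
    nuisance: TraceNuisance | None
    sd: dict
    rss: float
    n_points: int
    degenerate: bool = False
    residuals: np.ndarray | None = field(default=None, repr=False)
    fitted: np.ndarray | None = field(default=None, repr=False)


def state_fractions(t_min, rates: TranslocationRates):
    """Closed-form (S, U, T, X) occupancies at times ``t_min`` (minutes)."""
    t = np.asarray(t_min, dtype=float)
    ku, kt, ki = rates.k_unfold, rates.k_transloc, rates.k_incap
    a = ku + ki
    if a == 0.0:
        s = np.ones_like(t)
        z = np.zeros_like(t)
        return s, z.copy(), z.copy(), z.copy()
    e_a = np.exp(-a * t)
    s = e_a
    x = (ki / a) * (1.0 - e_a)
    if abs(kt - a) < _DEGEN_EPS:
        u = ku * t * e_a
        trans = (ku / a) * (1.0 - e_a * (1.0 + a * t))
    else:
        e_k = np.exp(-kt * t)
        u = ku * (e_a - e_k) / (kt - a)
        trans = (ku / a) * (1.0 - (kt * e_a - a * e_k) / (kt - a))
    return s, u, trans, x


def model_signal(t_min, rates: TranslocationRates, nuisance: TraceNuisance):
    """Predicted luminescence (RLU) on the post-DTT time grid (minutes)."""
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("model is defined on the post-DTT window t >= 0")
    _, _, trans, _ = state_fractions(t, rates)
    sig = np.exp(-nuisance.k_deplete * t) * nuisance.amplitude * (
        nuisance.s0 * trans + nuisance.pre_translocated
    ) + nuisance.baseline
    return sig if sig.ndim else float(sig)


_PARAM_NAMES = ("k_unfold", "k_transloc", "k_incap", "amplitude", "k_deplete",
                "pre_translocated", "baseline")


def _unpack(x, fixed):
    vals = dict(fixed)
    free = [n for n in _PARAM_NAMES if n not in fixed]
    vals.update(zip(free, x))
    rates = TranslocationRates(vals["k_unfold"], vals["k_transloc"], vals["k_incap"])
    nuis = TraceNuisance(vals["amplitude"], vals["k_deplete"], vals["baseline"],
                         vals["pre_translocated"])
    return rates, nuis


def fit_trace(trace: LuminescenceTrace, init: dict | None = None,
              fixed: dict | None = None, weights=None) -> TranslocationFit:
    """Least-squares fit of the signal model to one post-DTT trace.

    Homoscedastic by default (``weights`` accepts a per-point array). Uses a
    small deterministic multi-start over rate initializations — including a
    swapped (k_unfold, k_transloc) start — and reports parameter SDs from the
    Jacobian-based covariance. Traces indistinguishable from flat noise are
    returned with ``degenerate=True`` and no rate estimates.

    Two structural ambiguities of the two-exponential signal are resolved
    explicitly:

    * The amplitude A is a calibration constant of the luminescence assay,
      not estimable from a single post-DTT trace (the trace pins only
      A*k_unfold/(k_unfold+k_incap) and A*T0). Pass
      ``fixed={"amplitude": <calibrated RLU per imported fraction>}`` for a
      well-posed k_unfold/k_incap split; a warning is raised otherwise.
    * The signal is exactly invariant under exchanging the two decay rates
      a = k_unfold + k_incap and k_transloc (rescaling k_unfold to preserve
      k_unfold/a). The branch with k_transloc > a is reported: clearing the
      folded roadblock, not moving the unfolded chain, is the slow step,
      consistent with independently measured translocation rates for
      unstructured substrates.
    """
    fixed = dict(fixed or {})
    if "amplitude" not in fixed:
        warnings.warn(
            "amplitude left free: the k_unfold/k_incap split is unidentifiable "
            "from a single trace without an amplitude calibration"
        )
    t, y = trace.post_dtt()
    n = t.size
    if n < 50:
        raise ValueError("need at least 50 post-DTT samples")

    # flat-trace guard: range of the smoothed trace against what pure noise of
    # the locally estimated amplitude would produce
    noise = np.median(np.abs(np.diff(y))) / 0.6745 / np.sqrt(2.0) + 1e-12
    w = min(25, n // 4)
    smooth = np.convolve(y, np.ones(w) / w, mode="valid")
    if (smooth.max() - smooth.min()) < 10.0 * noise / np.sqrt(w) or np.ptp(y) == 0.0:
        return TranslocationFit(rates=None, nuisance=None, sd={}, rss=float(np.var(y) * n),
                                n_points=n, degenerate=True)

    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    free = [nme for nme in _PARAM_NAMES if nme not in fixed]

    def residual(x):
        try:
            rates, nuis = _unpack(x, fixed)
        except ValueError:
            return np.full(n, 1e6)
        return (model_signal(t, rates, nuis) - y) * w

    bg0 = float(np.percentile(y, 2))
    amp0 = fixed.get("amplitude", max(float(y.max() - bg0) * 2.0, noise * 10.0))

    # rank candidate rate/depletion combinations by profiling the two linear
    # parameters (A*T0 and baseline) out with ordinary least squares
    def profiled_start(ku, kt, ki, kd):
        rates = TranslocationRates(ku, kt, ki)
        _, _, trans, _ = state_fractions(t, rates)
        decay = np.exp(-kd * t)
        design = np.column_stack([decay, np.ones(n)])
        target = y - decay * amp0 * trans
        coef, *_ = np.linalg.lstsq(design, target, rcond=None)
        t0_lin = max(coef[0] / amp0, 0.0)
        bg_lin = coef[1]
        pred = decay * amp0 * (trans + t0_lin) + bg_lin
        rss0 = float(np.sum((pred - y) ** 2))
        return rss0, {"k_unfold": ku, "k_transloc": kt, "k_incap": ki, "amplitude": amp0,
                      "k_deplete": kd, "pre_translocated": max(t0_lin, 1e-6), "baseline": bg_lin}

    candidates = []
    for ku in (0.002, 0.01, 0.05, 0.2):
        for kt in (0.05, 0.25):
            for ki in (0.02, 0.07):
                for kd in (0.0, 0.005, 0.02):
                    candidates.append(profiled_start(ku, kt, ki, kd))
    candidates.sort(key=lambda c: c[0])
    starts = []
    if init is not None:
        full = {**candidates[0][1], **init}
        starts.append([full[nme] for nme in free])
    starts += [[c[1][nme] for nme in free] for c in candidates[:4]]
    # swapped-rate start to probe the labeling explicitly
    swap = dict(candidates[0][1])
    swap["k_unfold"], swap["k_transloc"] = swap["k_transloc"], swap["k_unfold"]
    starts.append([swap[nme] for nme in free])

    lower = {"k_unfold": 0.0, "k_transloc": 0.0, "k_incap": 0.0, "amplitude": 1e-12,
             "k_deplete": 0.0, "pre_translocated": 0.0, "baseline": -np.inf}
    lo = [lower[nme] for nme in free]
    hi = [np.inf] * len(free)

    best = None
    for x0 in starts:
        x0 = np.maximum(np.asarray(x0, dtype=float), np.asarray(lo) + 1e-12 * np.isfinite(lo))
        try:
            res = least_squares(residual, x0, bounds=(lo, hi), method="trf", max_nfev=4000)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("trace fit failed to converge from every start")

    rates, nuis = _unpack(best.x, fixed)
    # exact swap symmetry: pick the branch where roadblock clearance is slow
    a = rates.k_unfold + rates.k_incap
    if 0 < rates.k_transloc < a and {"k_unfold", "k_transloc", "k_incap"} <= set(free):
        c = rates.k_unfold / a
        swapped = {"k_unfold": c * rates.k_transloc,
                   "k_incap": (1.0 - c) * rates.k_transloc,
                   "k_transloc": a}
        x_sw = np.array([swapped.get(nme, v) for nme, v in zip(free, best.x)])
        res = least_squares(residual, x_sw, bounds=(lo, hi), method="trf", max_nfev=4000)
        if res.cost <= best.cost * (1 + 1e-9):
            best = res
            rates, nuis = _unpack(best.x, fixed)
    resid = residual(best.x)
    rss = float(np.sum(resid**2))
    dof = max(n - len(free), 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.pinv(jtj) * rss / dof
        sd_vals = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sd_vals = np.full(len(free), np.nan)
    sd = dict(zip(free, map(float, sd_vals)))

    fitted = model_signal(t, rates, nuis)
    return TranslocationFit(rates=rates, nuisance=nuis, sd=sd, rss=rss, n_points=n,
                            degenerate=False, residuals=y - fitted, fitted=fitted)


def aggregate_replicates(fits) -> pd.DataFrame:
    """Mean and sample SD of each rate across replicate fits.

    Returns a DataFrame indexed by rate name with columns mean, sd, n. For a
    single fit the SD is NaN (undefined) and a warning is raised.
    """
    fits = [f for f in fits if f.rates is not None]
    if len(fits) == 0:
        raise ValueError("no non-degenerate fits to aggregate")
    if len(fits) == 1:
        warnings.warn("single fit: SD undefined")
    rows = {}
    for name in ("k_unfold", "k_transloc", "k_incap"):
        vals = np.array([getattr(f.rates, name) for f in fits])
        rows[name] = {"mean": vals.mean(),
                      "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                      "n": len(vals)}
    return pd.DataFrame(rows).T


def rate_ratio_report(table: dict) -> dict:
    """Derived rate comparisons across conditions.

    ``table`` maps condition label to an aggregate DataFrame (as produced by
    :func:`aggregate_replicates`) or to a TranslocationRates. Reports the
    translocation-to-unfolding ratio per condition (how much longer the
    roadblock stalls translocation than the translocation step itself takes)
    and all pairwise unfolding-rate ratios, unrounded and rounded to one
    significant figure.
    """

    def get(cond, name):
        entry = table[cond]
        if isinstance(entry, TranslocationRates):
            return getattr(entry, name)
        return float(entry.loc[name, "mean"])

    def round1sig(x):
        if x == 0:
            return 0.0
        mag = 10.0 ** np.floor(np.log10(abs(x)))
        return float(round(x / mag) * mag)

    report = {"per_condition": {}, "k_unfold_ratios": {}}
    for cond in table:
        ratio = get(cond, "k_transloc") / get(cond, "k_unfold")
        report["per_condition"][cond] = {
            "k_transloc_over_k_unfold": ratio,
            "rounded": round1sig(ratio),
        }
    conds = list(table)
    for i, c1 in enumerate(conds):
        for c2 in conds[i + 1:]:
            ratio = get(c1, "k_unfold") / get(c2, "k_unfold")
            report["k_unfold_ratios"][f"{c1}/{c2}"] = {
                "ratio": ratio, "rounded": round1sig(ratio)}
    return report
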