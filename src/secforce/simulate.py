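"""Synthetic rip-event tables and luminescence traces.

Generators reproduce the statistical structure the analyses assume so the
whole pipeline can be exercised closed-loop against known ground truth:

* Rupture forces are drawn exactly from the Kramers-like rupture
  distribution at the study's two pulling speeds (20 and 150 nm/s, trap
  stiffness ~0.1 pN/nm), with per-molecule log-normal loading-rate scatter
  emulating tether-to-tether stiffness variation.
* Luminescence traces follow the closed-form kinetic signal model sampled at
  0.2 Hz over 30 min, with Gaussian noise whose SD grows with the square
  root of the signal (shot-noise-like photon counting).

Module-level ``REFERENCE_RATES`` and ``REFERENCE_BARRIERS`` hold the
published per-condition kinetic rates and barrier parameters of the
mDHFR/SecA system; they are the generator defaults and the ground truth for
round-trip tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import BarrierParams, RipEvent, sample_rip_forces
from .polymer import PolymerModel, expected_contour_change, wlc_relative_extension
from .translocation import LuminescenceTrace, TraceNuisance, TranslocationRates, model_signal

#: Published kinetic rates (1/min) per condition of the mDHFR roadblock assay.
REFERENCE_RATES = {
    "apo": TranslocationRates(k_unfold=0.0251, k_transloc=0.245, k_incap=0.0658),
    "MTX": TranslocationRates(k_unfold=0.0115, k_transloc=0.239, k_incap=0.0729),
    "M+N": TranslocationRates(k_unfold=0.00130, k_transloc=0.230, k_incap=0.0547),
}

#: Replicate SDs of k_unfold (1/min) accompanying REFERENCE_RATES.
REFERENCE_RATE_SDS = {"apo": 0.00173, "MTX": 0.000500, "M+N": 0.000194}

#: Published barrier parameters (log10 tau0/s, dx nm, dG kBT) per ligand condition.
REFERENCE_BARRIERS = {
    "MTX": BarrierParams(log10_tau0=5.46, dx_ddagger=1.67, dG_ddagger=15.3),
    "M+N": BarrierParams(log10_tau0=7.28, dx_ddagger=2.29, dG_ddagger=18.0),
}

#: mDHFR chain length (residues) used for the expected unfolding length change.
MDHFR_RESIDUES = 186

#: Recording length (min) per condition: until the signal plateaus, i.e. a few
#: times 1/(k_unfold + k_incap). The slowest-unfolding condition needs longest.
PLATEAU_DURATIONS = {"apo": 30.0, "MTX": 60.0, "M+N": 90.0}


@dataclass(frozen=True)
class RipSimConfig:
    """Configuration of a synthetic force-ramp experiment."""

    params: BarrierParams
    trap_velocities: tuple = (20.0, 150.0)  # nm/s
    stiffness: float = 0.1  # pN/nm
    n_per_speed: tuple = (100, 100)
    loading_rate_cv: float = 0.3  # log-normal per-molecule scatter
    censor_at: float | None = None  # pN, overstretching plateau
    condition: str = "synthetic"
    seed: int = 0
    polymer: PolymerModel = field(default_factory=PolymerModel)
    n_residues: int = MDHFR_RESIDUES

    def __post_init__(self) -> None:
        if self.stiffness <= 0 or any(v <= 0 for v in self.trap_velocities):
            raise ValueError("stiffness and velocities must be positive")
        if len(self.n_per_speed) != len(self.trap_velocities):
            raise ValueError("n_per_speed must match trap_velocities")
        if any(n < 0 for n in self.n_per_speed):
            raise ValueError("n_per_speed must be non-negative")


@dataclass(frozen=True)
class TraceSimConfig:
    """Configuration of a synthetic real-time translocation trace."""

    rates: TranslocationRates
    nuisance: TraceNuisance = field(
        default_factory=lambda: TraceNuisance(
            amplitude=1.0e4, k_deplete=0.005, baseline=200.0, pre_translocated=0.05
        )
    )
    duration: float = 30.0  # min
    sampling_rate: float = 0.2  # Hz
    noise_floor: float = 3.0  # RLU
    noise_scale: float = 0.25  # RLU**0.5
    condition: str = "synthetic"
    replicate_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")


def simulate_rip_dataset(config: RipSimConfig) -> list[RipEvent]:
    """Draw a synthetic rip-event table.

    Per event: loading rate r = stiffness x velocity x L with L log-normal
    (median 1, coefficient of variation ``loading_rate_cv``); rupture force
    from the exact inverse-CDF sampler at that r; extension change
    back-computed through the WLC from the expected full-unfolding
    contour-length change; events above ``censor_at`` marked censored.
    """
    rng = np.random.default_rng(config.seed)
    sigma = np.sqrt(np.log1p(config.loading_rate_cv**2))
    dl = expected_contour_change(config.n_residues, config.polymer)
    events: list[RipEvent] = []
    for v, n in zip(config.trap_velocities, config.n_per_speed):
        if n == 0:
            continue
        scatter = rng.lognormal(mean=0.0, sigma=sigma, size=n)
        rates = config.stiffness * v * scatter
        forces, censored = sample_rip_forces(n, rates, config.params, seed=rng)
        if config.censor_at is not None:
            over = forces >= config.censor_at
            forces = np.where(over, config.censor_at, forces)
            censored = censored | over
        z = wlc_relative_extension(forces, config.polymer, config.params.thermal_energy)
        dx = np.asarray(z) * dl
        for i in range(n):
            events.append(
                RipEvent(
                    molecule_id=f"v{v:g}_m{i:04d}",
                    condition=config.condition,
                    rip_force=float(forces[i]),
                    loading_rate=float(rates[i]),
                    delta_extension=float(dx[i]),
                    trap_velocity=float(v),
                    censored=bool(censored[i]),
                )
            )
    return events


def simulate_trace(config: TraceSimConfig) -> LuminescenceTrace:
    """Draw one synthetic luminescence trace on a uniform post-DTT grid."""
    rng = np.random.default_rng(config.seed)
    dt = 1.0 / config.sampling_rate  # s
    t_s = np.arange(0.0, config.duration * 60.0 + dt / 2, dt)
    clean = model_signal(t_s / 60.0, config.rates, config.nuisance)
    sd = config.noise_floor + config.noise_scale * np.sqrt(np.maximum(clean, 0.0))
    rlu = clean + rng.normal(0.0, 1.0, size=t_s.size) * sd
    return LuminescenceTrace(
        time=t_s, rlu=rlu, t_dtt=0.0, condition=config.condition,
        replicate_id=config.replicate_id, sampling_rate=config.sampling_rate,
    )


def make_demo_suite(out_dir, seed: int = 0, n_per_speed: tuple = (100, 100)) -> dict:
    """Write a self-contained demo dataset and its ground-truth manifest.

    One rip CSV per ligand condition (plus an apo-like 60/40 two-component
    mixture for the barrier-shape diagnostic) and one trace CSV per
    condition, all deterministic in ``seed``. Returns the manifest, which is
    also written as JSON alongside the data.
    """
    from .io import write_rip_csv, write_trace_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}, "ground_truth": {}}

    for i, (cond, params) in enumerate(REFERENCE_BARRIERS.items()):
        cfg = RipSimConfig(params=params, condition=cond, seed=seed + i, n_per_speed=n_per_speed)
        path = out / f"rips_{cond.replace('+', '')}.csv"
        write_rip_csv(simulate_rip_dataset(cfg), path)
        manifest["files"][f"rips_{cond}"] = path.name
        manifest["ground_truth"][f"rips_{cond}"] = {
            "log10_tau0": params.log10_tau0, "dx_ddagger_nm": params.dx_ddagger,
            "dG_ddagger_kBT": params.dG_ddagger, "nu": params.nu,
            "thermal_energy_pN_nm": params.thermal_energy,
            "n_per_speed": list(n_per_speed),
        }

    # apo-like two-population mixture: a mechanically labile and a stable state
    mix_components = (
        BarrierParams(log10_tau0=2.5, dx_ddagger=3.0, dG_ddagger=12.0),
        BarrierParams(log10_tau0=6.0, dx_ddagger=2.0, dG_ddagger=17.0),
    )
    weights = (0.6, 0.4)
    mix_events = []
    for j, (p, w) in enumerate(zip(mix_components, weights)):
        n = (int(round(n_per_speed[0] * w)), int(round(n_per_speed[1] * w)))
        cfg = RipSimConfig(params=p, condition="apo-mixture", seed=seed + 10 + j, n_per_speed=n)
        mix_events.extend(simulate_rip_dataset(cfg))
    path = out / "rips_apo_mixture.csv"
    write_rip_csv(mix_events, path)
    manifest["files"]["rips_apo-mixture"] = path.name
    manifest["ground_truth"]["rips_apo-mixture"] = {
        "weights": list(weights),
        "components": [
            {"log10_tau0": p.log10_tau0, "dx_ddagger_nm": p.dx_ddagger,
             "dG_ddagger_kBT": p.dG_ddagger} for p in mix_components
        ],
    }

    for i, (cond, rates) in enumerate(REFERENCE_RATES.items()):
        cfg = TraceSimConfig(rates=rates, condition=cond, replicate_id=f"demo{i}",
                             duration=PLATEAU_DURATIONS[cond], seed=seed + 20 + i)
        path = out / f"trace_{cond.replace('+', '')}.csv"
        write_trace_csv(simulate_trace(cfg), path)
        manifest["files"][f"trace_{cond}"] = path.name
        manifest["ground_truth"][f"trace_{cond}"] = {
            "k_unfold_per_min": rates.k_unfold, "k_transloc_per_min": rates.k_transloc,
            "k_incap_per_min": rates.k_incap, "amplitude_RLU": cfg.nuisance.amplitude,
            "duration_min": cfg.duration,
            "noise_floor_RLU": cfg.noise_floor, "noise_scale": cfg.noise_scale,
        }

    blob = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["manifest_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
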