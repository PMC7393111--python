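"""Worm-like chain elasticity and contour-length bookkeeping.

Force-extension curves of protein tethers are analysed with the Marko-Siggia
interpolation formula

    F(z) = (kBT / p) * [ 1 / (4 (1 - z)^2) - 1/4 + z ],   z = x / L,

where ``p`` is the persistence length and ``z`` the fractional extension.
Observed extension changes at rupture are converted into contour-length
changes by dividing by the fractional extension at the rupture force, and the
expected contour-length gain on unfolding an ``n``-residue domain is
``n * contour_per_residue - native_end_to_end``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Thermal energy at room temperature (~24.5 degC), pN*nm.
KBT_ROOM = 4.11


@dataclass(frozen=True)
class PolymerModel:
    """Polymer constants for the unfolded protein chain.

    Parameters
    ----------
    persistence_length : float
        WLC persistence length of the unfolded polypeptide, nm.
    contour_per_residue : float
        Contour-length increment per amino acid, nm.
    native_end_to_end : float
        End-to-end distance of the folded domain (subtracted from the
        unfolded contour length), nm.
    """

    persistence_length: float = 0.65
    contour_per_residue: float = 0.36
    native_end_to_end: float = 1.6

    def __post_init__(self) -> None:
        for name in ("persistence_length", "contour_per_residue", "native_end_to_end"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def wlc_force(relative_extension, model: PolymerModel | None = None, thermal_energy: float = KBT_ROOM):
    """Marko-Siggia force at fractional extension ``z`` in [0, 1), pN.

    Strictly increasing in ``z`` and divergent as ``z -> 1``. Accepts scalars
    or arrays.
    """
    model = model or PolymerModel()
    z = np.asarray(relative_extension, dtype=float)
    if np.any(z < 0) or np.any(z >= 1):
        raise ValueError("relative_extension must lie in [0, 1)")
    f = (thermal_energy / model.persistence_length) * (0.25 / (1.0 - z) ** 2 - 0.25 + z)
    return f if f.ndim else float(f)


def wlc_relative_extension(force, model: PolymerModel | None = None, thermal_energy: float = KBT_ROOM):
    """Invert the Marko-Siggia relation: fractional extension at ``force`` (pN).

    Bracketed bisection on the monotone forward map, tolerance 1e-10 in z.
    """
    model = model or PolymerModel()
    forces = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(forces < 0):
        raise ValueError("force must be non-negative")

    out = np.empty_like(forces)
    for i, f in enumerate(forces):
        if f == 0.0:
            out[i] = 0.0
            continue
        lo, hi = 0.0, 1.0 - 1e-15
        while hi - lo > 1e-10:
            mid = 0.5 * (lo + hi)
            if wlc_force(mid, model, thermal_energy) < f:
                lo = mid
            else:
                hi = mid
        out[i] = 0.5 * (lo + hi)
    return out if np.asarray(force).ndim else float(out[0])


def extension_to_contour_change(
    delta_extension: float,
    rip_force: float,
    model: PolymerModel | None = None,
    thermal_energy: float = KBT_ROOM,
):
    """Contour-length change from an observed extension change at rupture.

    ``dL = dx / z(F)``; always larger than ``dx`` since ``z < 1``.
    """
    if not np.all(np.asarray(delta_extension) > 0):
        raise ValueError("delta_extension must be positive")
    if not np.all(np.asarray(rip_force) > 0):
        raise ValueError("rip_force must be positive")
    z = wlc_relative_extension(rip_force, model, thermal_energy)
    return delta_extension / z


def expected_contour_change(n_residues: int, model: PolymerModel | None = None) -> float:
    """Expected contour-length gain on fully unfolding an ``n``-residue domain, nm."""
    model = model or PolymerModel()
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    dl = n_residues * model.contour_per_residue - model.native_end_to_end
    if dl <= 0:
        raise ValueError("domain too short for the stated native end-to-end distance")
    return dl
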