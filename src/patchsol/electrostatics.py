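"""Screened-Coulomb (Debye-Hückel) electrostatics.

A uniform-dielectric screened Coulomb model: the potential of a point charge
q at distance d is

    phi(d) = q * exp(-kappa d) / (4 pi eps0 eps_r d)

with the inverse Debye length kappa set by the ionic strength.  Potentials
are reported in mV, site-site interaction energies in kJ/mol.  This is the
whole electrostatic model of the package — there is no grid Poisson-
Boltzmann solver; the uniform-dielectric form keeps every quantity
closed-form and exactly superposable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._constants import (
    AVOGADRO,
    BOLTZMANN,
    COULOMB_KJ_A,
    COULOMB_MV_A,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
)

MIN_CHARGE_POINT_DIST = 0.1  # Å
MIN_SITE_DIST = 0.5  # Å


@dataclass(frozen=True)
class ElectrostaticParams:
    """Solvent model: relative dielectric, ionic strength (mol/L), T (K)."""

    eps_r: float = 78.4
    ionic_strength: float = 0.15
    temperature: float = 298.15

    @property
    def kappa(self) -> float:
        """Inverse Debye length in 1/Å."""
        return debye_kappa(self)


def debye_kappa(params: ElectrostaticParams) -> float:
    """kappa = sqrt(2 N_A e^2 I*1000 / (eps0 eps_r kB T)), in 1/Å.

    Zero ionic strength gives kappa = 0 (pure Coulomb); kappa scales with
    the square root of ionic strength.
    """
    if params.ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if params.ionic_strength == 0:
        return 0.0
    kappa_m = math.sqrt(
        2.0
        * AVOGADRO
        * ELEMENTARY_CHARGE**2
        * (params.ionic_strength * 1000.0)
        / (VACUUM_PERMITTIVITY * params.eps_r * BOLTZMANN * params.temperature)
    )
    return kappa_m * 1e-10


def potential_at_points(
    charges: list[tuple[np.ndarray, float]] | tuple[np.ndarray, np.ndarray],
    points: np.ndarray,
    params: ElectrostaticParams | None = None,
) -> np.ndarray:
    """Potential (mV) at each point from a set of point charges.

    ``charges`` is either a list of (position, charge_e) pairs or a tuple of
    (positions (n,3), charges (n,)) arrays.  Superposition holds exactly.
    A point within 0.1 Å of a charge raises: surface dots never coincide
    with buried charge centers, so this is always a usage error.
    """
    params = params or ElectrostaticParams()
    if isinstance(charges, tuple) and len(charges) == 2:
        qpos, qval = np.asarray(charges[0], float), np.asarray(charges[1], float)
    else:
        qpos = np.array([np.asarray(p, float) for p, _ in charges])
        qval = np.array([q for _, q in charges], dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if len(qpos) == 0:
        return np.zeros(len(points))
    qpos = np.atleast_2d(qpos)

    kappa = debye_kappa(params)
    out = np.zeros(len(points))
    # chunk over points to bound memory on large dot surfaces
    chunk = max(1, int(4e7 // max(1, len(qpos))))
    for lo in range(0, len(points), chunk):
        d = cdist(points[lo : lo + chunk], qpos)
        if d.min(initial=np.inf) <= MIN_CHARGE_POINT_DIST:
            raise ValueError(
                f"evaluation point within {MIN_CHARGE_POINT_DIST} Å of a charge"
            )
        out[lo : lo + chunk] = (
            COULOMB_MV_A / params.eps_r * (np.exp(-kappa * d) / d) @ qval
        )
    return out


def interaction_matrix(
    positions: np.ndarray, params: ElectrostaticParams | None = None
) -> np.ndarray:
    """Pairwise screened-Coulomb energies for unit charges, kJ/mol.

    W[i, j] is the interaction energy of +1/+1 charges at sites i and j;
    actual pair energies downstream are W[i, j] * q_i * q_j.  The diagonal
    is zero (no self energy).
    """
    params = params or ElectrostaticParams()
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    if n == 0:
        raise ValueError("need at least one site")
    d = cdist(positions, positions)
    off = ~np.eye(n, dtype=bool)
    if n > 1 and d[off].min() <= MIN_SITE_DIST:
        raise ValueError(f"sites closer than {MIN_SITE_DIST} Å (coincident?)")
    kappa = debye_kappa(params)
    W = np.zeros((n, n))
    W[off] = COULOMB_KJ_A / params.eps_r * np.exp(-kappa * d[off]) / d[off]
    return W
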