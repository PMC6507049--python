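"""Protonation-state thermodynamics of ionisable groups.

Sites (Asp, Glu, His, Lys, Arg, Tyr, free Cys and the chain termini) carry
model pKa values and interact through the screened-Coulomb pair matrix W.
The energy of a protonation microstate x (1 = proton bound) at a given pH is

    E(x, pH) = sum_i x_i ln(10) RT (pH - pKa_i)
             + sum_{i<j} W_ij q_i(x_i) q_j(x_j)

with q = x - 1 for acids and q = x for bases, so every site is neutral in
the fully "model" protonation sense when acids are protonated and bases
deprotonated.  Small systems are enumerated exactly (2^N states); larger
ones are sampled with single-flip Metropolis Monte Carlo.  Free energies are
-RT ln Z with a common zero of energy, so the folded-minus-unfolded
difference (the interacting model minus the same sites with W = 0) is the
ionisable-group contribution to folded-state stability: negative values are
stabilising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import logsumexp

from ._constants import (
    ACID_SITES,
    BACKBONE_ATOMS,
    GAS_CONSTANT_KJ,
    LN10,
    MODEL_PKA,
    SITE_CENTER_ATOMS,
)
from .electrostatics import ElectrostaticParams, interaction_matrix
from .structure_io import Structure, find_disulfides

MAX_EXACT_SITES = 20
DEFAULT_PH_GRID = np.arange(0.0, 14.0 + 1e-9, 0.25)


@dataclass(frozen=True)
class TitratableSite:
    chain_id: str
    residue_seq: int
    site_type: str          # ASP/GLU/HIS/LYS/ARG/TYR/CYS/NTERM/CTERM
    position: np.ndarray    # charge-center, Å
    model_pka: float

    @property
    def is_acid(self) -> bool:
        return self.site_type in ACID_SITES

    @property
    def q_deprotonated(self) -> float:
        return -1.0 if self.is_acid else 0.0


@dataclass
class TitrationResult:
    pH: np.ndarray                    # grid
    fractions: np.ndarray             # (n_pH, n_sites) mean protonation
    mean_charge: np.ndarray           # (n_pH,)
    G: np.ndarray                     # (n_pH,) kJ/mol, -RT ln Z
    method: str                       # "exact" | "mc" | "ideal"
    seed: int | None = None
    sites: list[TitratableSite] = field(default_factory=list, repr=False)

    def G_at(self, pH: float) -> float:
        return float(np.interp(pH, self.pH, self.G))


@dataclass(frozen=True)
class PHStability:
    pH: float
    phstab: float  # kJ/mol; negative = favourable (stabilising)


# ---------------------------------------------------------------------------
# site model
# ---------------------------------------------------------------------------

def build_site_model(
    s: Structure, params: ElectrostaticParams | None = None
) -> tuple[list[TitratableSite], np.ndarray]:
    """Titratable sites of a structure plus their interaction matrix.

    Disulphide-bonded cysteines are excluded.  Each site's charge sits at
    the centroid of its canonical charge-center atoms (falling back to the
    sidechain centroid when those atoms are missing).
    """
    params = params or ElectrostaticParams()
    bridged = {r for pair in find_disulfides(s) for r in pair}
    sites: list[TitratableSite] = []
    residues = s.residues()
    chain_first: dict[str, int] = {}
    chain_last: dict[str, int] = {}
    for cid, seq, _name, _idx in residues:
        chain_first.setdefault(cid, seq)
        chain_last[cid] = seq

    def center(idxs: list[int], names: tuple[str, ...]) -> np.ndarray | None:
        atom_map = {s.atoms[i].name: i for i in idxs}
        picked = [atom_map[n] for n in names if n in atom_map]
        if not picked:
            picked = [i for i in idxs if s.atoms[i].name not in BACKBONE_ATOMS]
        if not picked:
            picked = idxs
        return np.mean([s.atoms[i].position for i in picked], axis=0)

    for cid, seq, name, idxs in residues:
        if name in ("ASP", "GLU", "HIS", "LYS", "ARG", "TYR") or (
            name == "CYS" and (cid, seq) not in bridged
        ):
            pos = center(idxs, SITE_CENTER_ATOMS[name])
            sites.append(TitratableSite(cid, seq, name, pos, MODEL_PKA[name]))
        if seq == chain_first[cid]:
            pos = center(idxs, SITE_CENTER_ATOMS["NTERM"])
            sites.append(TitratableSite(cid, seq, "NTERM", pos, MODEL_PKA["NTERM"]))
        if seq == chain_last[cid]:
            pos = center(idxs, SITE_CENTER_ATOMS["CTERM"])
            sites.append(TitratableSite(cid, seq, "CTERM", pos, MODEL_PKA["CTERM"]))

    if not sites:
        return [], np.zeros((0, 0))
    W = interaction_matrix(np.array([st.position for st in sites]), params)
    return sites, W


def _site_arrays(sites: list[TitratableSite]) -> tuple[np.ndarray, np.ndarray]:
    pka = np.array([st.model_pka for st in sites], dtype=float)
    qdep = np.array([st.q_deprotonated for st in sites], dtype=float)
    return pka, qdep


# ---------------------------------------------------------------------------
# exact enumeration
# ---------------------------------------------------------------------------

def titrate_exact(
    sites: list[TitratableSite],
    W: np.ndarray,
    pH_grid: np.ndarray | None = None,
    temperature: float = 298.15,
) -> TitrationResult:
    """Exact partition function over all 2^N protonation states (N <= 20)."""
    pH_grid = DEFAULT_PH_GRID if pH_grid is None else np.asarray(pH_grid, float)
    n = len(sites)
    if n > MAX_EXACT_SITES:
        raise ValueError(
            f"{n} sites exceeds the exact-enumeration limit "
            f"({MAX_EXACT_SITES}); use titrate_mc"
        )
    RT = GAS_CONSTANT_KJ * temperature
    if n == 0:
        z = np.zeros(len(pH_grid))
        return TitrationResult(pH_grid, np.zeros((len(pH_grid), 0)), z, z.copy(), "exact")

    pka, qdep = _site_arrays(sites)
    states = ((np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1).astype(float)
    Q = states + qdep
    Epair = 0.5 * np.einsum("si,ij,sj->s", Q, W, Q)

    fracs = np.empty((len(pH_grid), n))
    meanQ = np.empty(len(pH_grid))
    G = np.empty(len(pH_grid))
    for k, pH in enumerate(pH_grid):
        E = Epair + states @ (LN10 * RT * (pH - pka))
        logw = -E / RT
        lz = logsumexp(logw)
        w = np.exp(logw - lz)
        fracs[k] = w @ states
        meanQ[k] = w @ Q.sum(axis=1)
        G[k] = -RT * lz
    return TitrationResult(pH_grid, fracs, meanQ, G, "exact", sites=list(sites))


def titrate_ideal(
    sites: list[TitratableSite],
    pH_grid: np.ndarray | None = None,
    temperature: float = 298.15,
) -> TitrationResult:
    """Non-interacting (W = 0) reference: Henderson-Hasselbalch per site.

    This is the unfolded-state model: same sites and model pKas, no
    charge-charge coupling.
    """
    pH_grid = DEFAULT_PH_GRID if pH_grid is None else np.asarray(pH_grid, float)
    RT = GAS_CONSTANT_KJ * temperature
    n = len(sites)
    if n == 0:
        z = np.zeros(len(pH_grid))
        return TitrationResult(pH_grid, np.zeros((len(pH_grid), 0)), z, z.copy(), "ideal")
    pka, qdep = _site_arrays(sites)
    frac = 1.0 / (1.0 + 10.0 ** (pH_grid[:, None] - pka[None, :]))
    meanQ = (frac + qdep).sum(axis=1)
    # G_i = -RT ln(1 + 10^(pKa - pH)) per site
    G = (-RT * np.log1p(10.0 ** (pka[None, :] - pH_grid[:, None]))).sum(axis=1)
    return TitrationResult(pH_grid, frac, meanQ, G, "ideal", sites=list(sites))


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

@njit(cache=False)
def _mc_chain(x, dE_pH, Wdyn, Wmeas, qdep, RT, sweeps, burn_in, seed):  # pragma: no cover
    np.random.seed(seed)
    n = x.shape[0]
    q = x.astype(np.float64) + qdep
    acc_x = np.zeros(n)
    acc_q = 0.0
    acc_ew = 0.0
    n_acc = 0
    for sweep in range(sweeps + burn_in):
        for _ in range(n):
            i = np.random.randint(n)
            dq = 1.0 - 2.0 * x[i]
            h = 0.0
            for j in range(n):
                if j != i:
                    h += Wdyn[i, j] * q[j]
            dE = dq * dE_pH[i] + dq * h
            if dE <= 0.0 or np.random.random() < np.exp(-dE / RT):
                x[i] = 1 - x[i]
                q[i] += dq
        if sweep >= burn_in:
            n_acc += 1
            # Rao-Blackwellised (heat-bath) estimator: accumulate each
            # site's exact conditional protonation probability given the
            # rest of the chain, not its binary state
            for i in range(n):
                h = 0.0
                for j in range(n):
                    if j != i:
                        h += Wdyn[i, j] * q[j]
                arg = (dE_pH[i] + h) / RT
                if arg > 500.0:
                    p = 0.0
                elif arg < -500.0:
                    p = 1.0
                else:
                    p = 1.0 / (1.0 + np.exp(arg))
                acc_x[i] += p
                acc_q += p + qdep[i]
            ew = 0.0
            for i in range(n):
                for j in range(i + 1, n):
                    ew += Wmeas[i, j] * q[i] * q[j]
            acc_ew += ew
    return acc_x / n_acc, acc_q / n_acc, acc_ew / n_acc


def titrate_mc(
    sites: list[TitratableSite],
    W: np.ndarray,
    pH_grid: np.ndarray | None = None,
    sweeps: int = 10_000,
    burn_in: int = 1_000,
    seed: int = 0,
    temperature: float = 298.15,
) -> TitrationResult:
    """Metropolis single-site-flip titration.

    Chains run per pH value (warm-started from the previous pH).  The free
    energy is anchored at the first grid point — exactly when the system is
    small enough to enumerate, otherwise by thermodynamic integration over a
    coupling parameter scaling W from zero — and extended across the grid by
    integrating the mean number of bound protons:
    dG/dpH = ln(10) RT <n_H>.
    """
    if sweeps < 1:
        raise ValueError("sweeps must be >= 1")
    pH_grid = DEFAULT_PH_GRID if pH_grid is None else np.asarray(pH_grid, float)
    n = len(sites)
    RT = GAS_CONSTANT_KJ * temperature
    if n == 0:
        z = np.zeros(len(pH_grid))
        return TitrationResult(pH_grid, np.zeros((len(pH_grid), 0)), z, z.copy(), "mc", seed)

    pka, qdep = _site_arrays(sites)
    W = np.asarray(W, dtype=float)
    rng = np.random.default_rng(seed)

    # start fully "model-protonated": acids protonated, bases protonated at
    # acidic end of the grid
    x = np.ones(n, dtype=np.int8)
    fracs = np.empty((len(pH_grid), n))
    meanQ = np.empty(len(pH_grid))
    nprot = np.empty(len(pH_grid))
    for k, pH in enumerate(pH_grid):
        dE_pH = LN10 * RT * (pH - pka)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fx, mq, _ = _mc_chain(
            x, dE_pH, W, W, qdep, RT, int(sweeps), int(burn_in), sub_seed
        )
        fracs[k] = fx
        meanQ[k] = mq
        nprot[k] = fx.sum()

    # anchor the free energy at the first grid point
    if n <= MAX_EXACT_SITES:
        G0 = titrate_exact(sites, W, np.array([pH_grid[0]]), temperature).G[0]
    else:
        G0 = _anchor_by_coupling_ti(
            sites, W, pH_grid[0], sweeps, burn_in, rng, temperature
        )
    dG = np.concatenate(
        [[0.0], np.cumsum(LN10 * RT * 0.5 * (nprot[1:] + nprot[:-1]) * np.diff(pH_grid))]
    )
    return TitrationResult(pH_grid, fracs, meanQ, G0 + dG, "mc", seed, list(sites))


def _anchor_by_coupling_ti(
    sites, W, pH, sweeps, burn_in, rng, temperature, n_lambda: int = 11
) -> float:
    """G(pH) by integrating <E_W> over a coupling constant scaling W.

    G(lambda=0) is the analytic non-interacting free energy; the integral of
    the mean unscaled pair energy over lambda in [0, 1] (trapezoidal) adds
    the interaction contribution.
    """
    RT = GAS_CONSTANT_KJ * temperature
    pka, qdep = _site_arrays(sites)
    n = len(sites)
    G_ideal = float(-RT * np.log1p(10.0 ** (pka - pH)).sum())
    lambdas = np.linspace(0.0, 1.0, n_lambda)
    dE_pH = LN10 * RT * (pH - pka)
    x = np.ones(n, dtype=np.int8)
    means = np.empty(n_lambda)
    for k, lam in enumerate(lambdas):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        _, _, ew = _mc_chain(
            x, dE_pH, lam * W, W, qdep, RT, int(sweeps), int(burn_in), sub_seed
        )
        means[k] = ew
    return G_ideal + float(np.trapezoid(means, lambdas))


# ---------------------------------------------------------------------------
# pH-dependent stability
# ---------------------------------------------------------------------------

def ph_stability(
    folded: TitrationResult, unfolded: TitrationResult, pH: float = 7.0
) -> PHStability:
    """Folded-minus-unfolded ionisable-group free energy at a pH.

    Both results must share the pH grid and site count.  Negative values
    mean the charge-charge interactions of the folded state are net
    stabilising at that pH.
    """
    if len(folded.pH) != len(unfolded.pH) or not np.allclose(folded.pH, unfolded.pH):
        raise ValueError("folded and unfolded results use different pH grids")
    if folded.fractions.shape[1] != unfolded.fractions.shape[1]:
        raise ValueError("folded and unfolded results have different site lists")
    return PHStability(pH, folded.G_at(pH) - unfolded.G_at(pH))


def ph_stability_for_structure(
    s: Structure,
    params: ElectrostaticParams | None = None,
    pH: float = 7.0,
    pH_grid: np.ndarray | None = None,
    sweeps: int = 10_000,
    burn_in: int = 1_000,
    seed: int = 0,
) -> tuple[PHStability, TitrationResult, TitrationResult]:
    """Convenience wrapper: site model -> folded titration -> pHstab.

    The folded state is enumerated exactly when it has few enough sites,
    otherwise sampled by Monte Carlo; the unfolded state is always the
    analytic non-interacting model.
    """
    params = params or ElectrostaticParams()
    sites, W = build_site_model(s, params)
    grid = DEFAULT_PH_GRID if pH_grid is None else np.asarray(pH_grid, float)
    if len(sites) <= MAX_EXACT_SITES:
        folded = titrate_exact(sites, W, grid, params.temperature)
    else:
        folded = titrate_mc(sites, W, grid, sweeps, burn_in, seed, params.temperature)
    unfolded = titrate_ideal(sites, grid, params.temperature)
    return ph_stability(folded, unfolded, pH), folded, unfolded
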