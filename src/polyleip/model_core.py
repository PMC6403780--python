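"""Domain types and the exact reduced free energy of roto-microstates.

The model is a linear weak polyelectrolyte carrying ``n_sites`` identical
ionizable sites placed every ``spacing`` chain nodes.  Each inter-site
segment contains one rotatable bond with three rotational isomeric states
(trans, gauche+, gauche-); the remaining bonds are frozen trans.  A joint
ionization vector ``s`` (0/1 per site) and conformation vector ``c``
(0=t, 1=g+, 2=g-) define a roto-microstate.

All energies are *reduced* and expressed in decimal-log units: the
statistical weight of a state with reduced free energy F is 10**(-F).
The temperature is fixed implicitly at 298 K through the default Bjerrum
length; there is no explicit temperature parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrostatics import (
    ConfigurationError,
    ScreenedPotential,
    debye_kappa,
    dh_pair,
)

__all__ = [
    "ChainSpec",
    "EnergyParams",
    "SolutionConditions",
    "RotoMicrostate",
    "build_chain",
    "reduced_free_energy",
]

TRANS, GAUCHE_PLUS, GAUCHE_MINUS = 0, 1, 2


@dataclass(frozen=True)
class ChainSpec:
    """Geometry and topology of the minimal polyelectrolyte chain.

    ``spacing`` is the number of bonds between consecutive ionizable
    sites (3 in the minimal model); sites sit on nodes 0, spacing,
    2*spacing, ...  For ``spacing >= 2`` each inter-site segment has one
    rotatable bond at offset ``rotatable_index`` (the middle bond by
    default); ``spacing == 1`` is the degenerate rigid chain with no
    rotatable bonds, whose sites are treated as collinear with separation
    ``bond_length``.
    """

    n_sites: int
    spacing: int = 3
    bond_length: float = 0.2
    bond_angle: float = 120.0
    rotatable_index: int = 1

    @property
    def n_nodes(self) -> int:
        return self.spacing * (self.n_sites - 1) + 1

    @property
    def n_bonds(self) -> int:
        return self.n_nodes - 1

    @property
    def n_rotatable(self) -> int:
        return self.n_sites - 1 if self.spacing >= 2 else 0

    @property
    def site_nodes(self) -> np.ndarray:
        return np.arange(self.n_sites) * self.spacing

    @property
    def rotatable_bonds(self) -> np.ndarray:
        """Global bond indices of the rotatable bonds."""
        if self.spacing < 2:
            return np.empty(0, dtype=int)
        return np.arange(self.n_sites - 1) * self.spacing + self.rotatable_index

    @property
    def is_rigid(self) -> bool:
        return self.n_rotatable == 0


def build_chain(
    n_sites: int,
    spacing: int = 3,
    bond_length: float = 0.2,
    bond_angle: float = 120.0,
    rotatable_index: int | None = None,
) -> ChainSpec:
    """Construct a validated :class:`ChainSpec`.

    The paper's minimal model is ``build_chain(50, 3, 0.2, 120)``:
    148 nodes, 147 bonds, 49 rotatable bonds.
    """
    if n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    if spacing < 1:
        raise ConfigurationError("spacing must be >= 1")
    if bond_length <= 0:
        raise ConfigurationError("bond_length must be positive")
    if not 0.0 < bond_angle < 180.0:
        raise ConfigurationError("bond_angle must lie strictly between 0 and 180")
    if rotatable_index is None:
        rotatable_index = spacing // 2 if spacing >= 2 else 0
    if spacing >= 2 and not 1 <= rotatable_index <= spacing - 1:
        raise ConfigurationError(
            "rotatable_index must lie in [1, spacing-1] so the bond torsion "
            "is geometrically defined"
        )
    return ChainSpec(n_sites, spacing, bond_length, bond_angle, rotatable_index)


@dataclass(frozen=True)
class EnergyParams:
    """Short-range reduced energies and protonation constant.

    Weights are Boltzmann factors; the corresponding decimal-log energies
    are ``p_sigma = -log10(sigma)``, ``eps_t = -log10(u_t)`` and
    ``eps_g = -log10(u_g)``.  ``u_g = 0`` encodes a forbidden gauche
    state between two protonated sites (eps_g -> infinity).  ``epsilon``
    is the nearest-neighbour interaction of the rigid chain.  Triplet
    terms are carried for completeness but fixed to zero in all solver
    paths.
    """

    pK: float
    sigma: float = 1.0
    psi: float = 1.0
    omega: float = 1.0
    u_t: float = 1.0
    u_g: float = 1.0
    epsilon: float = 0.0
    tau: float = field(default=0.0)

    def __post_init__(self) -> None:
        for name in ("sigma", "psi", "omega", "u_t", "u_g"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be a non-negative weight")
        if self.tau != 0.0:
            raise ConfigurationError("triplet terms are not supported (tau must be 0)")

    # Decimal-log energies (may be +inf for zero weights).
    @property
    def p_sigma(self) -> float:
        return -np.log10(self.sigma) if self.sigma > 0 else np.inf

    @property
    def p_psi(self) -> float:
        return -np.log10(self.psi) if self.psi > 0 else np.inf

    @property
    def p_omega(self) -> float:
        return -np.log10(self.omega) if self.omega > 0 else np.inf

    @property
    def eps_t(self) -> float:
        return -np.log10(self.u_t) if self.u_t > 0 else np.inf

    @property
    def eps_g(self) -> float:
        return -np.log10(self.u_g) if self.u_g > 0 else np.inf

    @classmethod
    def from_energies(
        cls,
        pK: float,
        p_sigma: float = 0.0,
        eps_t: float = 0.0,
        eps_g: float = 0.0,
        p_psi: float = 0.0,
        p_omega: float = 0.0,
        epsilon: float = 0.0,
    ) -> "EnergyParams":
        """Build from decimal-log energies instead of Boltzmann weights."""

        def w(e: float) -> float:
            return 0.0 if np.isinf(e) else float(10.0 ** (-e))

        return cls(
            pK=pK,
            sigma=w(p_sigma),
            psi=w(p_psi),
            omega=w(p_omega),
            u_t=w(eps_t),
            u_g=w(eps_g),
            epsilon=epsilon,
        )


@dataclass(frozen=True)
class SolutionConditions:
    """Solution state: pH, ionic strength (mol/L) and Bjerrum length (nm)."""

    pH: float
    ionic_strength: float = 0.1
    bjerrum_length: float = 0.7
    lr_enabled: bool = True

    def __post_init__(self) -> None:
        if self.ionic_strength <= 0:
            raise ConfigurationError("ionic_strength must be positive")
        if self.bjerrum_length <= 0:
            raise ConfigurationError("bjerrum_length must be positive")

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength)

    @property
    def potential(self) -> ScreenedPotential:
        return ScreenedPotential(self.bjerrum_length, self.kappa)


@dataclass
class RotoMicrostate:
    """A joint ionization vector s and conformation vector c."""

    s: np.ndarray
    c: np.ndarray
    reduced_free_energy: float | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=np.int8)
        self.c = np.asarray(self.c, dtype=np.int8)

    def validate(self, chain: ChainSpec) -> None:
        if self.s.shape != (chain.n_sites,):
            raise ValueError("ionization vector length does not match chain")
        if self.c.shape != (chain.n_rotatable,):
            raise ValueError("conformation vector length does not match chain")
        if not np.all((self.s == 0) | (self.s == 1)):
            raise ValueError("ionization states must be 0/1")
        if self.c.size and not np.all((self.c >= 0) & (self.c <= 2)):
            raise ValueError("bond states must be 0 (t), 1 (g+) or 2 (g-)")


def _site_distances(state: RotoMicrostate, chain: ChainSpec) -> np.ndarray:
    """Full site-site distance matrix for the given conformation (nm)."""
    if chain.is_rigid:
        idx = np.arange(chain.n_sites)
        return np.abs(idx[:, None] - idx[None, :]) * chain.bond_length
    from .geometry_moments import site_positions  # local import: avoids a cycle

    pos = site_positions(state.c, chain)[chain.site_nodes]
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def rotational_free_energy(
    c: np.ndarray, params: EnergyParams
) -> float:
    """F_rot(c): gauche energies plus consecutive-gauche pair terms."""
    c = np.asarray(c)
    F = 0.0
    n_gauche = int(np.count_nonzero(c))
    if n_gauche:
        if params.sigma == 0.0:
            return np.inf
        F += n_gauche * params.p_sigma
    # Pair terms couple consecutive rotatable bonds: same-orientation
    # gauche pairs weigh psi, opposite-orientation pairs weigh omega.
    for a, b in zip(c[:-1], c[1:]):
        if a and b:
            w = params.psi if a == b else params.omega
            if w == 0.0:
                return np.inf
            F += -np.log10(w)
    return F


def protonation_free_energy(
    state: RotoMicrostate,
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
    distances: np.ndarray | None = None,
) -> float:
    """F_p(s, c): site chemical potentials, adjacent SR pairs and, when
    long-range interactions are enabled, the Debye-Huckel sum over site
    pairs separated by at least two sites."""
    s = state.s
    F = float((cond.pH - params.pK) * int(s.sum()))
    # Adjacent-site SR term, mediated by the connecting rotatable bond
    # (or by the rigid-chain epsilon when there is none).
    for i in range(chain.n_sites - 1):
        if s[i] and s[i + 1]:
            if chain.is_rigid:
                F += params.epsilon
            else:
                e = params.eps_t if state.c[i] == TRANS else params.eps_g
                if np.isinf(e):
                    return np.inf
                F += e
    if cond.lr_enabled:
        charged = np.flatnonzero(s)
        if charged.size >= 2:
            d = distances if distances is not None else _site_distances(state, chain)
            pot = cond.potential
            for a in range(charged.size):
                for b in range(a + 1, charged.size):
                    i, j = charged[a], charged[b]
                    if j - i >= 2:
                        F += dh_pair(d[i, j], pot)
    return F


def reduced_free_energy(
    state: RotoMicrostate,
    chain: ChainSpec,
    params: EnergyParams,
    cond: SolutionConditions,
) -> float:
    """Exact reduced free energy F(s, c) of a roto-microstate.

    F = F_rot(c) + F_p(s, c), with the long-range Debye-Huckel term
    included in F_p when ``cond.lr_enabled``.  Forbidden configurations
    (zero statistical weight) return +inf.
    """
    state.validate(chain)
    F = rotational_free_energy(state.c, params)
    if np.isinf(F):
        return np.inf
    return F + protonation_free_energy(state, chain, params, cond)
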