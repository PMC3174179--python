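"""Mass-action reaction networks for doxorubicin bioactivation.

A :class:`ReactionNetwork` holds an ordered species list and a list of
:class:`Reaction` objects, each with one of the three rate-law kinds the
bioactivation models use:

``bimolecular``
    elementary mass action, ``rate = k * [A] * [B]`` (``A`` may equal ``B``,
    as in superoxide self-dismutation);
``saturable_supply``
    Michaelis-type zero-order supply, ``rate = vmax * [S] / (km + [S])``
    (the G6PD NADPH-regeneration step);
``permeation``
    first-order membrane transport, ``rate = k * A_surf * [S]`` (doxorubicin
    uptake across the plasma membrane).

A reaction may additionally carry a saturating *modifier*
``[M] / ([M] + K)`` — used to make the NOX-catalysed NADPH/O2 reaction
depend on intracellular quinone doxorubicin.

Internally time is in seconds and concentrations in molar.  Negative
concentrations produced by integrator overshoot are clamped to zero during
rate evaluation only (tolerance 1e-12 M); the state itself is never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "Reaction",
    "ReactionNetwork",
    "NEGATIVE_CLAMP_TOL",
]

#: integrator-overshoot tolerance (M): values above -tol are treated as 0
NEGATIVE_CLAMP_TOL = 1e-12

RATE_KINDS = ("bimolecular", "saturable_supply", "permeation")


class ConfigurationError(ValueError):
    """A network references a species or constant that is not defined."""


@dataclass(frozen=True)
class Reaction:
    """One reaction: rate-law kind, constants, reactants and stoichiometry.

    Parameters
    ----------
    rid : str
        Reaction identifier (``"R1"`` ... ``"R8"``, ``"Rsod"``).
    kind : str
        One of :data:`RATE_KINDS`.
    reactants : tuple of str
        Species entering the rate law.  ``bimolecular`` takes exactly two
        (repeat a species for a second-order self-reaction);
        ``saturable_supply`` and ``permeation`` take exactly one.
    stoichiometry : mapping of str to float
        Net stoichiometric coefficients (negative = consumed).
    constants : mapping of str to float
        ``bimolecular``/``permeation``: ``k`` (permeation also ``area``);
        ``saturable_supply``: ``vmax`` and ``km``.
    modifier : tuple (species, K) or None
        Optional saturating multiplier ``[M]/([M]+K)``.
    """

    rid: str
    kind: str
    reactants: tuple[str, ...]
    stoichiometry: Mapping[str, float]
    constants: Mapping[str, float]
    modifier: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in RATE_KINDS:
            raise ConfigurationError(
                f"reaction {self.rid}: unknown rate-law kind {self.kind!r}"
            )
        n_expected = 2 if self.kind == "bimolecular" else 1
        if len(self.reactants) != n_expected:
            raise ConfigurationError(
                f"reaction {self.rid}: kind {self.kind!r} takes "
                f"{n_expected} reactant(s), got {len(self.reactants)}"
            )
        needed = {
            "bimolecular": ("k",),
            "permeation": ("k", "area"),
            "saturable_supply": ("vmax", "km"),
        }[self.kind]
        for name in needed:
            if name not in self.constants:
                raise ConfigurationError(
                    f"reaction {self.rid}: missing constant {name!r}"
                )

    def rate(self, conc: Mapping[str, float]) -> float:
        """Evaluate the reaction rate (M s^-1) at the given concentrations.

        Concentrations within :data:`NEGATIVE_CLAMP_TOL` below zero are
        treated as zero, so rates are non-negative on the (numerically)
        non-negative orthant.
        """
        try:
            values = [max(0.0, conc[s]) for s in self.reactants]
        except KeyError as exc:  # pragma: no cover - guarded by network checks
            raise ConfigurationError(
                f"reaction {self.rid}: species {exc.args[0]!r} missing from state"
            ) from None
        if self.kind == "bimolecular":
            r = self.constants["k"] * values[0] * values[1]
        elif self.kind == "permeation":
            r = self.constants["k"] * self.constants["area"] * values[0]
        else:  # saturable_supply
            s = values[0]
            r = self.constants["vmax"] * s / (self.constants["km"] + s)
        if self.modifier is not None:
            m_species, m_k = self.modifier
            m = max(0.0, conc[m_species])
            r *= m / (m + m_k)
        return r


@dataclass
class ReactionNetwork:
    """Ordered species plus reactions; evaluates rates, RHS and stoichiometry.

    ``clamped`` species are held constant by the right-hand side (their
    derivative row is zeroed) — used for the optional oxygen clamp.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    clamped: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.reactions = tuple(self.reactions)
        self.clamped = frozenset(self.clamped)
        if len(set(self.species)) != len(self.species):
            raise ConfigurationError("duplicate species identifiers")
        known = set(self.species)
        for rxn in self.reactions:
            for s in (*rxn.reactants, *rxn.stoichiometry):
                if s not in known:
                    raise ConfigurationError(
                        f"reaction {rxn.rid}: unknown species {s!r}"
                    )
            if rxn.modifier is not None and rxn.modifier[0] not in known:
                raise ConfigurationError(
                    f"reaction {rxn.rid}: unknown modifier species "
                    f"{rxn.modifier[0]!r}"
                )
        for s in self.clamped:
            if s not in known:
                raise ConfigurationError(f"clamped species {s!r} not in network")
        self._index = {s: i for i, s in enumerate(self.species)}

    # -- evaluation ---------------------------------------------------------

    def evaluate_rates(self, state: Mapping[str, float]) -> dict[str, float]:
        """Per-reaction rate map (M s^-1) at a concentration state."""
        return {rxn.rid: rxn.rate(state) for rxn in self.reactions}

    def evaluate_rhs(self, state: Mapping[str, float]) -> dict[str, float]:
        """Species time-derivative map (M s^-1): stoichiometry-weighted rates."""
        deriv = dict.fromkeys(self.species, 0.0)
        for rxn in self.reactions:
            r = rxn.rate(state)
            for s, nu in rxn.stoichiometry.items():
                deriv[s] += nu * r
        for s in self.clamped:
            deriv[s] = 0.0
        return deriv

    def rhs_vector(self, y: np.ndarray) -> np.ndarray:
        """Vectorised RHS for the integrator; ``y`` ordered like ``species``."""
        conc = {s: y[i] for s, i in self._index.items()}
        d = self.evaluate_rhs(conc)
        return np.array([d[s] for s in self.species])

    def stoichiometry_matrix(self) -> np.ndarray:
        """(|species| x |reactions|) matrix N with RHS = N @ rate vector.

        Rows of clamped species are zeroed so the identity with
        :meth:`evaluate_rhs` holds exactly.
        """
        n = np.zeros((len(self.species), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for s, nu in rxn.stoichiometry.items():
                n[self._index[s], j] = nu
        for s in self.clamped:
            n[self._index[s], :] = 0.0
        return n

    # -- conversions --------------------------------------------------------

    def state_vector(self, state: Mapping[str, float]) -> np.ndarray:
        missing = [s for s in self.species if s not in state]
        if missing:
            raise ConfigurationError(f"state missing species {missing}")
        return np.array([state[s] for s in self.species], dtype=float)

    def state_dict(self, y: Sequence[float]) -> dict[str, float]:
        return {s: float(y[i]) for s, i in self._index.items()}
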