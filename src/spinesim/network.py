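"""Reaction network of the dopamine -> cAMP -> PKA -> DARPP-32/GluA1 cascade.

The network is defined in a line-oriented text table (``data/reactions.txt``)
mirroring the published kinetic scheme: reversible binding rows, irreversible
conversion rows, and enzyme rows of the form ``E + S <-> ES -> E + P`` carrying
(kf, kb, kcat). Loading expands every row into irreversible, mass-action
*elementary* reactions — the uniform currency of both simulation engines:

* reversible row  -> forward + backward reaction,
* enzyme row      -> bind + unbind + catalyze,
* irreversible row -> itself.

Rate-law conventions
--------------------
Reactions are at most second order. A reactant printed with coefficient 2
(``PKA + 2 cAMP``) binds a pre-paired ligand couple: the rate law stays
bimolecular (kf*[A]*[L]) but each event consumes/releases two ligands. A
self-reaction (``A + A -> ...``) has deterministic flux kf*[A]^2 and stochastic
propensity c*n*(n-1)/2 with c chosen to match it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .units import stochastic_rate  # noqa: F401  (re-exported: part of the module surface)

__all__ = [
    "RateConstants",
    "SpeciesSpec",
    "ReactionSpec",
    "ElementaryReaction",
    "ReactionNetwork",
    "load_network",
    "load_default_network",
    "expand_enzyme_steps",
    "conserved_moieties",
    "stochastic_rate",
]


class NetworkError(ValueError):
    """Malformed reaction-table row or species registry entry."""


@dataclass(frozen=True)
class RateConstants:
    """kf (nM^-1 s^-1 bimolecular / s^-1 unimolecular), kb (s^-1), kcat (s^-1)."""

    kf: float
    kb: float | None = None
    kcat: float | None = None

    def __post_init__(self):
        for name in ("kf", "kb", "kcat"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise NetworkError(f"negative rate constant {name}={v}")
        if self.kcat is not None and self.kb is None:
            raise NetworkError("kcat requires kb (enzyme triple)")


@dataclass(frozen=True)
class SpeciesSpec:
    """A model species: diffusion constant and conserved-moiety composition."""

    name: str
    D: float = 0.0  # um^2/s; 0 = anchored / non-diffusing
    composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.D < 0:
            raise NetworkError(f"negative diffusion constant for {self.name}")


@dataclass(frozen=True)
class ReactionSpec:
    """One row of the reaction table, prior to elementary expansion."""

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rates: RateConstants
    reversible: bool
    complex_species: str | None = None  # ES species of an enzyme row
    complex_products: tuple[tuple[str, int], ...] = ()
    pmr: bool = False
    tag: str = ""

    @property
    def is_enzyme(self) -> bool:
        return self.rates.kcat is not None


@dataclass(frozen=True)
class ElementaryReaction:
    """Irreversible mass-action reaction (the unit both engines consume).

    Reactant patterns and their rate laws:

    ===================  =======================  ==========================
    reactants            deterministic flux       stochastic propensity
    ===================  =======================  ==========================
    (A,1)                k*[A]                    k*nA
    (A,2)  self          k*[A]^2                  (2k/fV)*nA*(nA-1)/2
    (A,1),(B,1)          k*[A]*[B]                (k/fV)*nA*nB
    (A,1),(L,2) paired   k*[A]*[L]                (k/fV)*nA*nL  (2 L consumed)
    ===================  =======================  ==========================

    where fV converts nM*um^3 to molecules. The paired-ligand form is the
    table's "X + 2 L" convention (pre-paired calcium/cAMP site pairs).
    """

    reactants: tuple[tuple[str, int], ...]  # 1-2 distinct species
    products: tuple[tuple[str, int], ...]
    k: float  # nM^-1 s^-1 if order 2, s^-1 if order 1
    tag: str = ""

    @property
    def identical(self) -> bool:
        """True for a self-reaction A + A -> products."""
        return len(self.reactants) == 1 and self.reactants[0][1] == 2

    @property
    def order(self) -> int:
        """Rate-law order (decides the units of k)."""
        if len(self.reactants) == 2 or self.identical:
            return 2
        return 1


_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z0-9_]+)$")


def _parse_side(text: str, row: str) -> tuple[tuple[str, int], ...]:
    terms = []
    for raw in text.split("+"):
        raw = raw.strip()
        if not raw:
            raise NetworkError(f"empty species term in row: {row}")
        m = _TERM_RE.match(raw)
        if not m:
            raise NetworkError(f"cannot parse species term {raw!r} in row: {row}")
        coeff = int(m.group(1) or 1)
        if coeff not in (1, 2):
            raise NetworkError(f"stoichiometry {coeff} unsupported in row: {row}")
        terms.append((m.group(2), coeff))
    # merge "A + A" into a single (A, 2) term
    merged: dict[str, int] = {}
    for name, coeff in terms:
        merged[name] = merged.get(name, 0) + coeff
    return tuple(merged.items())


def parse_row(line: str) -> ReactionSpec:
    """Parse one ';'-separated table row into a ReactionSpec."""
    fields = [f.strip() for f in line.split(";")]
    equation = fields[0]
    kf = kb = kcat = None
    tag = ""
    pmr = False
    for f in fields[1:]:
        if not f:
            continue
        if f == "pmr":
            pmr = True
            continue
        if "=" not in f:
            raise NetworkError(f"cannot parse field {f!r} in row: {line}")
        key, val = (s.strip() for s in f.split("=", 1))
        if key == "kf":
            kf = float(val)
        elif key == "kb":
            kb = float(val)
        elif key == "kcat":
            kcat = float(val)
        elif key == "tag":
            tag = val
        else:
            raise NetworkError(f"unknown field {key!r} in row: {line}")
    if kf is None:
        raise NetworkError(f"row has no kf: {line}")

    complex_species = None
    complex_products: tuple[tuple[str, int], ...] = ()
    if "<->" in equation:
        lhs, rest = equation.split("<->", 1)
        if "->" in rest:
            mid, prod = rest.split("->", 1)
            mid_terms = _parse_side(mid, line)
            if len(mid_terms) != 1 or mid_terms[0][1] != 1:
                raise NetworkError(f"enzyme row must form a single complex: {line}")
            if kcat is None:
                raise NetworkError(f"enzyme-form row lacks kcat: {line}")
            complex_species = mid_terms[0][0]
            complex_products = _parse_side(prod, line)
            reactants = _parse_side(lhs, line)
            products = (mid_terms[0],)
            reversible = True
        else:
            reactants = _parse_side(lhs, line)
            products = _parse_side(rest, line)
            reversible = True
        if kb is None:
            # printed as reversible but with a single rate: treated as
            # irreversible (constitutive decay rows of the source table)
            reversible = False
    elif "->" in equation:
        lhs, rhs = equation.split("->", 1)
        reactants = _parse_side(lhs, line)
        products = _parse_side(rhs, line)
        reversible = False
        if kcat is not None:
            raise NetworkError(f"kcat on a row with no complex product: {line}")
    else:
        raise NetworkError(f"row has no reaction arrow: {line}")

    if kcat is not None and complex_species is None:
        raise NetworkError(f"kcat on a row with no complex product: {line}")
    coeffs = sorted(c for _, c in reactants)
    if coeffs not in ([1], [2], [1, 1], [1, 2]):
        # allowed: A; A+A; A+B; A + 2 L (paired ligand). Anything else exceeds
        # second order.
        raise NetworkError(f"reaction above second order: {line}")
    return ReactionSpec(
        reactants=reactants,
        products=products,
        rates=RateConstants(kf=kf, kb=kb, kcat=kcat),
        reversible=reversible,
        complex_species=complex_species,
        complex_products=complex_products,
        pmr=pmr,
        tag=tag,
    )


def expand_enzyme_steps(row: ReactionSpec) -> list[ElementaryReaction]:
    """Expand a table row into its elementary reactions.

    Enzyme rows produce [bind, unbind, catalyze]; reversible rows produce
    [forward, backward]; irreversible rows pass through unchanged.
    """
    tag = row.tag
    out = [
        ElementaryReaction(row.reactants, row.products, row.rates.kf, tag=f"{tag}.f")
    ]
    if row.reversible:
        out.append(
            ElementaryReaction(row.products, row.reactants, row.rates.kb, tag=f"{tag}.b")
        )
    if row.rates.kcat is not None:
        if row.complex_species is None:
            raise NetworkError(f"kcat without complex in row {tag}")
        out.append(
            ElementaryReaction(
                ((row.complex_species, 1),), row.complex_products, row.rates.kcat,
                tag=f"{tag}.cat",
            )
        )
    return out


class ReactionNetwork:
    """Species registry + elementary reaction list + stoichiometric matrix."""

    def __init__(self, species: list[SpeciesSpec], rows: list[ReactionSpec],
                 source_text: str = ""):
        self.species = list(species)
        self.rows = list(rows)
        self.source_text = source_text
        self.index = {s.name: i for i, s in enumerate(self.species)}
        if len(self.index) != len(self.species):
            raise NetworkError("duplicate species names")

        elementary: list[ElementaryReaction] = []
        seen: dict[tuple, int] = {}
        for row in rows:
            for e in expand_enzyme_steps(row):
                key = (e.reactants, e.products, e.k)
                if key in seen:
                    # identical elementary step printed on two rows (shared
                    # ES complex): the step happens once
                    continue
                seen[key] = len(elementary)
                elementary.append(e)
        self.elementary = elementary

        n_r, n_s = len(elementary), len(self.species)
        S = np.zeros((n_r, n_s), dtype=np.int64)
        for j, e in enumerate(elementary):
            for name, coeff in e.reactants:
                S[j, self._idx(name, e.tag)] -= coeff
            for name, coeff in e.products:
                S[j, self._idx(name, e.tag)] += coeff
        self.stoichiometry = S

    def _idx(self, name: str, tag: str) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise NetworkError(f"unknown species {name!r} in reaction {tag!r}") from None

    # -- convenience -------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.elementary)

    def species_index(self, name: str) -> int:
        return self.index[name]

    def diffusion_constants(self) -> np.ndarray:
        return np.array([s.D for s in self.species])

    def serialize(self) -> str:
        """The definition-table text this network was loaded from."""
        return self.source_text

    # -- conservation ------------------------------------------------------
    def moiety_vector(self, moiety: str) -> np.ndarray:
        """Integer weights of a conserved moiety across all species."""
        return np.array([s.composition.get(moiety, 0) for s in self.species],
                        dtype=np.int64)

    def conserved_moieties(self) -> dict[str, np.ndarray]:
        """All declared moieties that are invariant under every reaction.

        Each returned weight vector w satisfies S @ w == 0, i.e. it lies in the
        left null space of the stoichiometric matrix. Moieties whose total is
        changed by some reaction (none, for a correct composition table) are
        reported by raising, so composition errors surface immediately.
        """
        names = sorted({m for s in self.species for m in s.composition})
        out = {}
        bad = []
        for m in names:
            w = self.moiety_vector(m)
            if np.any(self.stoichiometry @ w != 0):
                bad.append(m)
            else:
                out[m] = w
        if bad:
            raise NetworkError(f"moieties not conserved by the reaction set: {bad}")
        return out


def _read_species_table(path: Path) -> list[SpeciesSpec]:
    species = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # column header
                continue
            name, d_str, comp_str = line.split("\t")
            comp: dict[str, int] = {}
            if comp_str.strip() != "-":
                for item in comp_str.split(","):
                    m, w = item.split(":")
                    comp[m.strip()] = int(w)
            species.append(SpeciesSpec(name=name, D=float(d_str), composition=comp))
    return species


def load_network(definition_file: str | Path,
                 species_file: str | Path | None = None) -> ReactionNetwork:
    """Load a reaction table (and species registry) into a ReactionNetwork."""
    definition_file = Path(definition_file)
    text = definition_file.read_text()
    rows = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        rows.append(parse_row(stripped))

    if species_file is not None:
        species = _read_species_table(Path(species_file))
    else:
        # bare network: register every species mentioned, D = 0, no composition
        names: list[str] = []
        for row in rows:
            for group in (row.reactants, row.products, row.complex_products):
                for name, _ in group:
                    if name not in names:
                        names.append(name)
            if row.complex_species and row.complex_species not in names:
                names.append(row.complex_species)
        species = [SpeciesSpec(name=n) for n in names]
    return ReactionNetwork(species, rows, source_text=text)


def _data_path(name: str) -> Path:
    return Path(resources.files("spinesim").joinpath("data", name))


def load_default_network() -> ReactionNetwork:
    """The full striatal signaling network shipped with the package."""
    return load_network(_data_path("reactions.txt"), _data_path("species.tsv"))


def conserved_moieties(network: ReactionNetwork) -> dict[str, np.ndarray]:
    """Module-level alias for :meth:`ReactionNetwork.conserved_moieties`."""
    return network.conserved_moieties()
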