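"""Nearest-neighbour loop energy model and Boltzmann transition weights.

The grammar engine only ever sees Boltzmann *log-weights* ``-dG/RT`` for
whole loops; this module owns the translation from free energies (kcal/mol)
to those weights.  The parameter set is deliberately compact — stacking
energies for the 36 ordered canonical pair combinations, length-dependent
hairpin/bulge/internal-loop penalties with Jacobson–Stockmayer extrapolation,
and an affine multiloop score ``a + b·branches + c·unpaired`` — because every
consumer of the engine (including the exhaustive enumeration oracle) shares
the same model, so algorithmic exactness does not depend on parameter
richness.

Conventions:

* canonical pairs are exactly {AU, UA, CG, GC, GU, UG}; anything involving
  ``N`` does not pair;
* a hairpin needs at least ``min_hairpin_unpaired`` (default 3) unpaired
  bases, i.e. paired residues ``(k, l)`` satisfy ``5 <= l - k + 1``;
* weights are ``exp(-dG/RT)`` with negative dG stabilising;
* internal/bulge loops larger than ``max_internal_loop`` bases are excluded
  from the ensemble (weight 0), in the engine and the oracle alike.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .sequence import CODES

#: canonical pair types, 1-based; 0 means "no pair"
PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_INDEX = {p: k + 1 for k, p in enumerate(PAIR_TYPES)}

#: 5x5 residue-code table -> pair-type index (0 = not canonical)
PAIR_TABLE = np.zeros((5, 5), dtype=np.int8)
for _p, _k in PAIR_INDEX.items():
    PAIR_TABLE[CODES[_p[0]], CODES[_p[1]]] = _k

GAS_CONSTANT_KCAL = 1.98720425864083e-3  # kcal/(mol K)


class EnergyModelError(ValueError):
    pass


def pair_type(a: str, b: str) -> str | None:
    """Canonical pair type of residues ``a``/``b`` or None.

    Raises for symbols outside {A,C,G,U,N}; any pairing involving N is None.
    """
    for c in (a, b):
        if c not in CODES:
            raise EnergyModelError(f"invalid residue symbol {c!r}")
    k = PAIR_TABLE[CODES[a], CODES[b]]
    return PAIR_TYPES[k - 1] if k else None


@dataclass(frozen=True)
class EnergyModel:
    """Loop free energies (kcal/mol) plus the thermodynamic constants.

    ``dangle_mode`` is either ``"none"`` (default) or ``"simplified"``; the
    simplified mode charges ``terminal_au`` to every exterior-loop closing
    pair that is not CG/GC (a terminal-AU-style penalty hook).
    """

    temperature: float = 310.15
    gas_constant: float = GAS_CONSTANT_KCAL
    stack_energies: Mapping[tuple[str, str], float] = field(default_factory=dict)
    hairpin_by_length: Mapping[int, float] = field(default_factory=lambda: {3: 0.0})
    bulge_by_length: Mapping[int, float] = field(default_factory=lambda: {1: 0.0})
    internal_by_length: Mapping[int, float] = field(default_factory=lambda: {2: 0.0})
    multiloop_affine: tuple[float, float, float] = (0.0, 0.0, 0.0)
    dangle_mode: str = "none"
    min_hairpin_unpaired: int = 3
    max_internal_loop: int = 30
    terminal_au: float = 0.0
    jacobson: float = 0.0  # loop-length extrapolation coefficient

    def __post_init__(self) -> None:
        if self.min_hairpin_unpaired < 3:
            raise EnergyModelError("min_hairpin_unpaired must be >= 3")
        if self.dangle_mode not in ("none", "simplified"):
            raise EnergyModelError(f"unknown dangle_mode {self.dangle_mode!r}")
        if self.temperature <= 0:
            raise EnergyModelError("temperature must be positive")

    # -- thermodynamics -----------------------------------------------------

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def weight(self, dg: float) -> float:
        """Boltzmann weight exp(-dG/RT); dG=inf maps to 0."""
        return 0.0 if math.isinf(dg) else math.exp(-dg / self.rt)

    # -- loop free energies -------------------------------------------------

    def _tabulated(self, table: Mapping[int, float], size: int) -> float:
        if not table:
            return 0.0
        mx = max(table)
        if size <= mx:
            return table.get(size, math.inf)
        return table[mx] + self.jacobson * math.log(size / mx)

    def hairpin_energy(self, size: int) -> float:
        if size < self.min_hairpin_unpaired:
            return math.inf
        return self._tabulated(self.hairpin_by_length, size)

    def stack_energy(self, outer: str, inner: str) -> float:
        return self.stack_energies.get((outer, inner), 0.0)

    def internal_energy(self, left: int, right: int) -> float:
        """Two-branch loop with ``left``/``right`` unpaired bases (not both 0)."""
        size = left + right
        if size == 0:
            raise EnergyModelError("size-0 internal loop is a stack")
        if size > self.max_internal_loop:
            return math.inf
        if left == 0 or right == 0:
            return self._tabulated(self.bulge_by_length, size)
        return self._tabulated(self.internal_by_length, size)

    def multiloop_energy(self, branches: int, unpaired: int) -> float:
        a, b, c = self.multiloop_affine
        return a + b * branches + c * unpaired

    def exterior_pair_energy(self, ptype: str) -> float:
        if self.dangle_mode == "simplified" and ptype not in ("CG", "GC"):
            return self.terminal_au
        return 0.0

    # -- constructors -------------------------------------------------------

    @classmethod
    def default(cls, **overrides) -> "EnergyModel":
        model = load_parameters(
            importlib.resources.files("spanfold.data").joinpath("default_params.tsv").read_text()
        )
        return replace(model, **overrides) if overrides else model

    @classmethod
    def zero(cls, **overrides) -> "EnergyModel":
        """All-zero energies: the partition function counts structures."""
        return cls(**overrides)

    @classmethod
    def from_file(cls, path) -> "EnergyModel":
        with open(path) as fh:
            return load_parameters(fh.read())

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(dump_parameters(self))

    def digest(self) -> str:
        return hashlib.sha1(dump_parameters(self).encode()).hexdigest()[:12]

    # -- kernel tables ------------------------------------------------------

    def log_weight_tables(self, w: int) -> "CompiledTables":
        """Log Boltzmann weights as flat arrays for the banded DP kernels.

        Loop-size tables are materialised up to size ``w`` (a loop inside a
        window of span ``<= w`` can never be larger).
        """
        rt = self.rt
        # entries absent from the parameter set mean dG = 0
        stack_lw = np.zeros((7, 7))
        for (p, q), e in self.stack_energies.items():
            stack_lw[PAIR_INDEX[p], PAIR_INDEX[q]] = -e / rt

        def table_lw(fn, lo):
            arr = np.full(w + 2, -np.inf)
            for s in range(lo, w + 2):
                e = fn(s)
                arr[s] = -np.inf if math.isinf(e) else -e / rt
            return arr

        hairpin_lw = table_lw(self.hairpin_energy, self.min_hairpin_unpaired)
        bulge_lw = table_lw(lambda s: self.internal_energy(s, 0), 1)
        internal_lw = table_lw(lambda s: self.internal_energy(1, s - 1) if s >= 2 else math.inf, 2)
        a, b, c = self.multiloop_affine
        ext_pair_lw = np.zeros(7)
        for p in PAIR_TYPES:
            ext_pair_lw[PAIR_INDEX[p]] = -self.exterior_pair_energy(p) / rt
        return CompiledTables(
            stack_lw=stack_lw,
            hairpin_lw=hairpin_lw,
            bulge_lw=bulge_lw,
            internal_lw=internal_lw,
            ml_close_lw=-a / rt,
            ml_branch_lw=-b / rt,
            ml_unpaired_lw=-c / rt,
            ext_pair_lw=ext_pair_lw,
            max_internal=self.max_internal_loop,
            min_hairpin=self.min_hairpin_unpaired,
        )


@dataclass(frozen=True)
class CompiledTables:
    stack_lw: np.ndarray
    hairpin_lw: np.ndarray
    bulge_lw: np.ndarray
    internal_lw: np.ndarray
    ml_close_lw: float
    ml_branch_lw: float
    ml_unpaired_lw: float
    ext_pair_lw: np.ndarray
    max_internal: int
    min_hairpin: int


# ---------------------------------------------------------------------------
# native TSV parameter format
# ---------------------------------------------------------------------------

def load_parameters(text: str) -> EnergyModel:
    """Parse the native TSV parameter dialect (see data/default_params.tsv)."""
    stacks: dict[tuple[str, str], float] = {}
    hairpin: dict[int, float] = {}
    bulge: dict[int, float] = {}
    internal: dict[int, float] = {}
    multi = {"closing": 0.0, "branch": 0.0, "unpaired": 0.0}
    terminal_au = 0.0
    jacobson = 0.0
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        kind = parts[0]
        try:
            if kind == "STACK":
                p, q, e = parts[1], parts[2], float(parts[3])
                if p not in PAIR_INDEX or q not in PAIR_INDEX:
                    raise EnergyModelError(f"non-canonical pair in STACK line {ln}")
                stacks[(p, q)] = e
            elif kind == "HAIRPIN":
                hairpin[int(parts[1])] = float(parts[2])
            elif kind == "BULGE":
                bulge[int(parts[1])] = float(parts[2])
            elif kind == "INTERNAL":
                internal[int(parts[1])] = float(parts[2])
            elif kind == "MULTI":
                if parts[1] not in multi:
                    raise EnergyModelError(f"unknown MULTI term {parts[1]!r}")
                multi[parts[1]] = float(parts[2])
            elif kind == "TERMINAL_AU":
                terminal_au = float(parts[1])
            elif kind == "JACOBSON":
                jacobson = float(parts[1])
            else:
                raise EnergyModelError(f"unknown section {kind!r} at line {ln}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, EnergyModelError):
                raise
            raise EnergyModelError(f"malformed parameter line {ln}: {line!r}") from exc
    if not all(math.isfinite(v) for v in stacks.values()):
        raise EnergyModelError("non-finite stack energy")
    return EnergyModel(
        stack_energies=stacks,
        hairpin_by_length=hairpin or {3: 0.0},
        bulge_by_length=bulge or {1: 0.0},
        internal_by_length=internal or {2: 0.0},
        multiloop_affine=(multi["closing"], multi["branch"], multi["unpaired"]),
        terminal_au=terminal_au,
        jacobson=jacobson,
    )


def dump_parameters(model: EnergyModel) -> str:
    lines = [
        "# spanfold nearest-neighbour energy parameters, kcal/mol",
        f"# T={model.temperature} K, dangle_mode={model.dangle_mode}, "
        f"min_hairpin={model.min_hairpin_unpaired}, max_internal={model.max_internal_loop}",
    ]
    for (p, q), e in sorted(model.stack_energies.items()):
        lines.append(f"STACK\t{p}\t{q}\t{e:g}")
    for name, table in (
        ("HAIRPIN", model.hairpin_by_length),
        ("BULGE", model.bulge_by_length),
        ("INTERNAL", model.internal_by_length),
    ):
        for s, e in sorted(table.items()):
            lines.append(f"{name}\t{s}\t{e:g}")
    a, b, c = model.multiloop_affine
    lines += [
        f"MULTI\tclosing\t{a:g}",
        f"MULTI\tbranch\t{b:g}",
        f"MULTI\tunpaired\t{c:g}",
        f"TERMINAL_AU\t{model.terminal_au:g}",
        f"JACOBSON\t{model.jacobson:g}",
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# whole-structure energies (shared with the enumeration oracle)
# ---------------------------------------------------------------------------

def loop_weight(descriptor: Mapping, model: EnergyModel) -> float:
    """Boltzmann weight of one loop described by ``descriptor``.

    ``descriptor["kind"]`` selects the loop type:

    ``hairpin``            needs ``size``
    ``stack``              needs ``outer``/``inner`` pair types
    ``internal``/``bulge`` needs ``left``/``right`` unpaired counts
    ``multiloop``          needs ``branches``/``unpaired``
    ``exterior_pair``      needs ``ptype``
    ``exterior_unpaired``  no geometry
    """
    kind = descriptor["kind"]
    if kind == "hairpin":
        return model.weight(model.hairpin_energy(descriptor["size"]))
    if kind == "stack":
        return model.weight(model.stack_energy(descriptor["outer"], descriptor["inner"]))
    if kind in ("internal", "bulge"):
        return model.weight(model.internal_energy(descriptor["left"], descriptor["right"]))
    if kind == "multiloop":
        return model.weight(model.multiloop_energy(descriptor["branches"], descriptor["unpaired"]))
    if kind == "exterior_pair":
        return model.weight(model.exterior_pair_energy(descriptor["ptype"]))
    if kind == "exterior_unpaired":
        return 1.0
    raise EnergyModelError(f"unknown loop kind {kind!r}")


def structure_energy(residues: str, pairs, model: EnergyModel) -> float:
    """Free energy (kcal/mol) of a well-nested structure by loop decomposition.

    ``pairs`` are 1-based residue pairs.  Returns ``inf`` for structures the
    model excludes (short hairpins, oversized internal loops).
    """
    pairs = sorted(pairs)
    ptypes = {}
    for a, b in pairs:
        pt = pair_type(residues[a - 1], residues[b - 1])
        if pt is None:
            return math.inf
        ptypes[(a, b)] = pt
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    stack: list[tuple[int, int]] = []
    for p in pairs:  # sorted by opening position => parents precede children
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        parent = stack[-1] if stack else None
        children.setdefault(parent, []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    energy = 0.0
    for a, b in pairs:
        kids = children[(a, b)]
        if not kids:
            energy += model.hairpin_energy(b - a - 1)
        elif len(kids) == 1:
            (c, d) = kids[0]
            left, right = c - a - 1, b - d - 1
            if left == 0 and right == 0:
                energy += model.stack_energy(ptypes[(a, b)], ptypes[(c, d)])
            else:
                energy += model.internal_energy(left, right)
        else:
            unpaired = (b - a - 1) - sum(d - c + 1 for c, d in kids)
            energy += model.multiloop_energy(len(kids), unpaired)
    for a, b in children[None]:
        energy += model.exterior_pair_energy(ptypes[(a, b)])
    return energy


def structure_weight(residues: str, pairs, model: EnergyModel) -> float:
    return model.weight(structure_energy(residues, pairs, model))
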