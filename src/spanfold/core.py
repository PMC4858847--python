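"""Banded inside-outside computation under the maximal span constraint.

The ensemble is the set of globally consistent secondary structures whose
base pairs ``(k, l)`` (1-based residues) all satisfy ``5 <= l - k + 1 <= W``.
Structures decompose uniquely into exterior-loop fragments and blocks under
*outermost* pairs; an outermost pair is written as a gap pair ``(i, j)``
pairing residues ``(i+1, j)``, and the set of potential outermost pairs is
``P = {(i, j) : (x_{i+1}, x_j) canonical and 5 <= j - i <= W}``.

Inside variables for all grammar states are banded (span ``<= W``) and scale
with the window only, so they are safe in the log domain at any sequence
length.  The exterior-state variables ``alpha_Outer``/``beta_Outer`` scale
with N and are only materialised here by :func:`global_reference_fold`, a
reference path for short sequences; production code uses the ratio variables
in :mod:`spanfold.ratios`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .energy import PAIR_TABLE, EnergyModel
from .sequence import RnaSequence


@dataclass
class StateTables:
    """Banded log-domain DP tables for one (sequence, W, model) triple.

    ``inside[state][i, d]`` holds the inside value of the state over gap span
    ``(i, i+d)``.  Outside tables are on probability scale
    (``log beta_state/Z``) and are attached lazily once the ratio database
    is available.
    """

    seq: RnaSequence
    w: int
    model: EnergyModel
    inside: dict = field(repr=False)
    outside: dict | None = field(default=None, repr=False)
    logr: np.ndarray | None = field(default=None, repr=False)
    rho: np.ndarray | None = field(default=None, repr=False)
    log_z: float | None = None

    @property
    def alpha_stem(self) -> np.ndarray:
        return self.inside["Stem"]


STATE_ORDER = ("Stem", "StemEnd", "Multi", "MultiBif", "Multi1", "Multi2")


def potential_outermost_pairs(seq: RnaSequence, w: int) -> set[tuple[int, int]]:
    """The set P of gap pairs that can be outermost: canonical and 5 <= j-i <= W."""
    if w < 1:
        raise ValueError("W must be >= 1")
    code = seq.codes()
    n = seq.n
    out = set()
    for i in range(0, n):
        for j in range(i + 5, min(n, i + w) + 1):
            if PAIR_TABLE[code[i + 1], code[j]] > 0:
                out.add((i, j))
    return out


def inside_banded(seq: RnaSequence, w: int, model: EnergyModel | None = None) -> StateTables:
    """Fill the banded inside tables for all spans <= W."""
    model = model or EnergyModel.default()
    t = model.log_weight_tables(w)
    arrays = K.inside_kernel(
        seq.codes(), w, PAIR_TABLE, t.stack_lw, t.hairpin_lw, t.bulge_lw,
        t.internal_lw, t.ml_close_lw, t.ml_branch_lw, t.ml_unpaired_lw,
        t.max_internal,
    )
    inside = dict(zip(STATE_ORDER, arrays))
    return StateTables(seq=seq, w=w, model=model, inside=inside)


def u_weights(tables: StateTables) -> np.ndarray:
    """Exterior block weights u(p, q) as a banded log array ``u[p, q-p]``.

    ``u(p, p+1)`` is the unpaired-step weight t(Outer->Outer) = 1;
    ``u(p, q) = t(Outer->Outer.Stem) * exp(alpha_Stem(p, q))`` for (p,q) in P;
    0 (log -inf) otherwise.
    """
    t = tables.model.log_weight_tables(tables.w)
    code = tables.seq.codes()
    n = tables.seq.n
    s = tables.alpha_stem
    u = np.full((n + 1, tables.w + 1), -np.inf)
    for p in range(n):
        u[p, 1] = 0.0
        for d in range(5, min(tables.w, n - p) + 1):
            if s[p, d] != -np.inf:
                pt = PAIR_TABLE[code[p + 1], code[p + d]]
                u[p, d] = t.ext_pair_lw[pt] + s[p, d]
    return u


def global_reference_fold(seq: RnaSequence, w: int, model: EnergyModel | None = None,
                          tables: StateTables | None = None):
    """Raw log alpha_Outer / beta_Outer arrays and log Z (reference path).

    Accumulates the exterior recursion directly in the log domain; intended
    for short sequences (tests and cross-checks).  Returns
    ``(log_z, log_alpha_outer, log_beta_outer)`` with
    ``log_alpha_outer[N] == log_beta_outer[0] == log_z``.
    """
    model = model or EnergyModel.default()
    if tables is None:
        tables = inside_banded(seq, w, model)
    t = model.log_weight_tables(w)
    la, lb = K.outer_raw_kernel(seq.codes(), w, PAIR_TABLE, tables.alpha_stem, t.ext_pair_lw)
    tables.log_z = float(la[-1])
    return float(la[-1]), la, lb


def outside_local(tables: StateTables, outermost: tuple[int, int]) -> dict:
    """Window outside variables beta_state(k, l; i, j) for one outermost pair.

    Seeds only ``beta_Stem(i, j; i, j) = t(Outer,i,j -> Outer.Stem,i,j)`` and
    propagates inside the window; states unreachable from the seed stay at
    log 0.  Returned arrays share the banded global indexing.
    """
    i, j = outermost
    seq, w = tables.seq, tables.w
    if not (5 <= j - i <= w):
        raise ValueError(f"({i},{j}) violates the outermost-pair span bounds")
    if tables.alpha_stem[i, j - i] == -np.inf:
        raise ValueError(f"({i},{j}) is not a potential outermost pair")
    t = tables.model.log_weight_tables(w)
    seed_logr = np.full((seq.n + 1, w + 1), np.nan)
    seed_logr[i, j - i] = 0.0  # exterior context weight 1 for this window only
    arrays = K.outside_kernel(
        seq.codes(), w, PAIR_TABLE, *(tables.inside[s] for s in STATE_ORDER),
        seed_logr, t.stack_lw, t.hairpin_lw, t.bulge_lw, t.internal_lw,
        t.ml_close_lw, t.ml_branch_lw, t.ml_unpaired_lw, t.max_internal,
        t.ext_pair_lw,
    )
    return dict(zip(STATE_ORDER, arrays))


def attach_outside(tables: StateTables, logr: np.ndarray) -> None:
    """Fill probability-scale outside tables given the banded log r array."""
    t = tables.model.log_weight_tables(tables.w)
    arrays = K.outside_kernel(
        tables.seq.codes(), tables.w, PAIR_TABLE,
        *(tables.inside[s] for s in STATE_ORDER),
        logr, t.stack_lw, t.hairpin_lw, t.bulge_lw, t.internal_lw,
        t.ml_close_lw, t.ml_branch_lw, t.ml_unpaired_lw, t.max_internal,
        t.ext_pair_lw,
    )
    tables.logr = logr
    tables.outside = dict(zip(STATE_ORDER, arrays))
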