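"""User-facing structural quantities computed from the ratio database.

All per-position outputs are 1-based; array index ``t-1`` holds position
``t``.  Base-pair keys are 1-based residue pairs ``(a, b)``, ``a < b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .core import StateTables
from .energy import PAIR_TABLE
from .ratios import RatioDatabase, attach_ratios

PROFILE_COLUMNS = ("stem", "bulge", "exterior", "hairpin", "interior", "multi")


def _ensure_outside(tables: StateTables, db: RatioDatabase) -> None:
    if tables.outside is None:
        attach_ratios(tables, db)


@dataclass
class BasePairProbabilities:
    """Banded base-pairing probabilities p(a, b), 1-based residues.

    Backed by the band ``band[i, d] = p(i+1, i+d)`` (gap coordinates); only
    canonical pairs with residue span ``5 <= b - a + 1 <= W`` can be nonzero.
    """

    n: int
    w: int
    band: np.ndarray = field(repr=False)

    def get(self, a: int, b: int) -> float:
        """p(a, b) for 1-based residues a < b."""
        if not (1 <= a < b <= self.n):
            raise IndexError(f"pair ({a},{b}) outside the sequence")
        d = b - a + 1
        return float(self.band[a - 1, d]) if d <= self.w else 0.0

    def items(self):
        """Yield ((a, b), p) for every nonzero entry."""
        ii, dd = np.nonzero(self.band)
        for i, d in zip(ii, dd):
            yield (int(i) + 1, int(i + d)), float(self.band[i, d])

    def to_dict(self) -> dict:
        return dict(self.items())


def base_pair_probabilities(tables: StateTables, db: RatioDatabase) -> BasePairProbabilities:
    """Exact ensemble base-pairing probabilities under the span constraint."""
    _ensure_outside(tables, db)
    band = K.bpp_kernel(tables.alpha_stem, tables.outside["Stem"])
    return BasePairProbabilities(n=tables.seq.n, w=tables.w, band=band)


def stem_probability(bpp: BasePairProbabilities) -> np.ndarray:
    """p_stem(t) = sum_{b>t} p(t,b) + sum_{a<t} p(a,t); length-N array."""
    return K.stem_kernel(bpp.band)


def accessibility(bpp: BasePairProbabilities) -> np.ndarray:
    """1 - p_stem, the probability of being unpaired."""
    return 1.0 - stem_probability(bpp)


@dataclass
class StructuralProfile:
    """Per-position probabilities over the six structural contexts.

    Columns (in order): stem, bulge, exterior, hairpin, interior, multi.
    Rows sum to 1 within numerical tolerance.
    """

    values: np.ndarray = field(repr=False)  # shape (N, 6)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.values[:, PROFILE_COLUMNS.index(column)]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[f"p_{c}" for c in PROFILE_COLUMNS])
        df.insert(0, "pos", np.arange(1, self.n + 1))
        return df


def structural_profile(tables: StateTables, db: RatioDatabase) -> StructuralProfile:
    """Loop-type occupancy per position from the grammar's transition probabilities.

    A paired base is *stem*; an unpaired base is attributed to the loop that
    emits it: hairpin loop, two-branch loop (one unpaired side -> bulge, both
    sides -> interior), multibranch loop, or the exterior loop.
    """
    _ensure_outside(tables, db)
    t = tables.model.log_weight_tables(tables.w)
    args = [tables.inside[s] for s in ("Stem", "StemEnd", "Multi", "MultiBif", "Multi1", "Multi2")]
    outs = [tables.outside[s] for s in ("Stem", "StemEnd", "Multi", "MultiBif", "Multi1", "Multi2")]
    hair, bulge, inter, multi, exter = K.profile_kernel(
        tables.seq.codes(), tables.w, PAIR_TABLE, *args, *outs,
        t.hairpin_lw, t.bulge_lw, t.internal_lw,
        t.ml_close_lw, t.ml_branch_lw, t.ml_unpaired_lw, t.max_internal,
        tables.rho, db.log_dbeta,
    )
    stem = stem_probability(base_pair_probabilities(tables, db))
    values = np.column_stack([stem, bulge, exter, hair, inter, multi])
    return StructuralProfile(values=values)


class StructureError(ValueError):
    pass


@dataclass
class SecondaryStructure:
    """A well-nested set of 1-based base pairs with its dot-bracket rendering."""

    n: int
    pairs: tuple[tuple[int, int], ...]
    gamma: float | None = None
    max_span: int | None = None

    def __post_init__(self) -> None:
        pairs = tuple(sorted(tuple(p) for p in self.pairs))
        object.__setattr__(self, "pairs", pairs)
        seen: set[int] = set()
        for a, b in pairs:
            if not 1 <= a < b <= self.n:
                raise StructureError(f"pair ({a},{b}) outside 1..{self.n}")
            if b - a < 4:
                raise StructureError(f"pair ({a},{b}) closes a hairpin shorter than 3")
            if self.max_span is not None and b - a + 1 > self.max_span:
                raise StructureError(f"pair ({a},{b}) exceeds the span bound")
            if a in seen or b in seen:
                raise StructureError(f"position reused by pair ({a},{b})")
            seen.update((a, b))
        stack: list[tuple[int, int]] = []
        for a, b in pairs:  # sorted by opening position
            while stack and stack[-1][1] < a:
                stack.pop()
            if stack and stack[-1][1] < b:
                raise StructureError(
                    f"crossing pairs {stack[-1]} and ({a},{b})"
                )
            stack.append((a, b))

    def dot_bracket(self) -> str:
        chars = ["."] * self.n
        for a, b in self.pairs:
            chars[a - 1] = "("
            chars[b - 1] = ")"
        return "".join(chars)


def gamma_centroid(bpp: BasePairProbabilities, gamma: float = 1.0) -> SecondaryStructure:
    """The gamma-centroid structure for gamma <= 1: all pairs with p > 1/(gamma+1).

    Because the threshold is at least 1/2, no two incompatible pairs can both
    qualify, so the result is automatically conflict-free and well-nested.
    Ties at exactly the threshold are excluded (strict inequality).
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]; gamma > 1 needs DP assembly")
    thr = 1.0 / (gamma + 1.0)
    ii, dd = np.nonzero(bpp.band > thr)
    pairs = tuple((int(i) + 1, int(i + d)) for i, d in zip(ii, dd))
    return SecondaryStructure(n=bpp.n, pairs=pairs, gamma=gamma, max_span=bpp.w)


def window_average(values, length: int, mode: str = "non-overlapping") -> np.ndarray:
    """Window means of a per-position series.

    ``non-overlapping`` yields floor(N/L) windows (trailing partial window
    dropped); ``sliding`` yields N-L+1 means.  L > N yields an empty result.
    """
    values = np.asarray(values, dtype=float)
    if length < 1:
        raise ValueError("window length must be >= 1")
    n = values.size
    if length > n:
        return np.empty(0)
    if mode == "non-overlapping":
        m = n // length
        return values[: m * length].reshape(m, length).mean(axis=1)
    if mode == "sliding":
        c = np.concatenate([[0.0], np.cumsum(values)])
        return (c[length:] - c[:-length]) / length
    raise ValueError(f"unknown mode {mode!r}")


class CoordinateError(ValueError):
    pass


@dataclass
class SpliceDelta:
    """Per-exonic-position stem-probability change caused by splicing.

    ``delta[t-1] = p_stem,mRNA(t) - p_stem,pre-mRNA(map(t))`` for mRNA
    position ``t``; ``junctions`` holds the 1-based mRNA position of the last
    base of each upstream exon; ``junction_stats`` the (median, MAD) of delta
    within the ``window``-nt span centred on each junction.
    """

    delta: np.ndarray = field(repr=False)
    mrna_to_pre: np.ndarray = field(repr=False)
    junctions: tuple[int, ...]
    junction_stats: tuple[tuple[float, float], ...]
    window: int = 200

    def smoothed_around(self, junction_index: int, length: int = 32, span: int = 100):
        """Sliding-window means of delta, separately upstream and downstream
        of one junction (windows never straddle the junction)."""
        j = self.junctions[junction_index]
        up = self.delta[max(0, j - span) : j]
        down = self.delta[j : j + span]
        return window_average(up, length, "sliding"), window_average(down, length, "sliding")


def _median_mad(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    return med, float(np.median(np.abs(x - med)))


def splice_delta(pre_pstem, mrna_pstem, exons, window: int = 200) -> SpliceDelta:
    """Stem-probability differences at corresponding exonic sites.

    ``exons`` are (start, end) 1-based inclusive coordinates on the pre-mRNA,
    ascending and non-overlapping; their concatenation is the mRNA.
    """
    pre_pstem = np.asarray(pre_pstem, dtype=float)
    mrna_pstem = np.asarray(mrna_pstem, dtype=float)
    mapping = []
    last_end = 0
    for start, end in exons:
        if not (last_end < start <= end <= pre_pstem.size):
            raise CoordinateError(f"bad exon ({start},{end}) on pre-mRNA of length {pre_pstem.size}")
        mapping.extend(range(start, end + 1))
        last_end = end
    mapping = np.asarray(mapping, dtype=np.int64)
    if mapping.size != mrna_pstem.size:
        raise CoordinateError(
            f"exons cover {mapping.size} bases but mRNA series has {mrna_pstem.size}"
        )
    delta = mrna_pstem - pre_pstem[mapping - 1]
    junctions = []
    pos = 0
    for start, end in exons[:-1]:
        pos += end - start + 1
        junctions.append(pos)
    half = window // 2
    stats = tuple(
        _median_mad(delta[max(0, j - half) : min(delta.size, j + half)]) for j in junctions
    )
    return SpliceDelta(delta=delta, mrna_to_pre=mapping, junctions=tuple(junctions),
                       junction_stats=stats, window=window)
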