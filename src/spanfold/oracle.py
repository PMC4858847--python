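"""Ground-truth machinery: exhaustive enumeration and synthetic fixtures.

The oracle enumerates *every* span-constrained secondary structure of a tiny
sequence, scores each one independently by loop decomposition
(:func:`spanfold.energy.structure_energy`), and derives exact partition
values, pairing probabilities and loop-type profiles by direct summation.
It shares only the energy model with the grammar engine — no DP recursions —
so agreement between the two pins down the grammar semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, PAIR_TABLE, structure_weight
from .features import PROFILE_COLUMNS
from .sequence import CODES, RnaSequence

MAX_ORACLE_N = 25


class OracleError(ValueError):
    pass


def _canonical(residues: str, a: int, b: int) -> bool:
    return PAIR_TABLE[CODES[residues[a - 1]], CODES[residues[b - 1]]] > 0


def enumerate_structures(seq: RnaSequence, w: int) -> list[tuple[tuple[int, int], ...]]:
    """All well-nested structures with canonical pairs of span 5..W (1-based)."""
    if seq.n > MAX_ORACLE_N:
        raise OracleError(f"enumeration limited to N <= {MAX_ORACLE_N}")
    res = seq.residues
    cache: dict[tuple[int, int], list] = {}

    def rec(i: int, j: int):
        if j - i < 4:
            return [()]
        key = (i, j)
        if key in cache:
            return cache[key]
        out = list(rec(i + 1, j))
        for q in range(i + 4, min(j, i + w - 1) + 1):
            if not _canonical(res, i, q):
                continue
            inner = rec(i + 1, q - 1)
            rest = rec(q + 1, j)
            for s1 in inner:
                for s2 in rest:
                    out.append(((i, q),) + s1 + s2)
        cache[key] = out
        return out

    return rec(1, seq.n)


def count_structures(seq: RnaSequence, w: int) -> int:
    """Independent recursive census (no structure materialisation)."""
    res = seq.residues
    cache: dict[tuple[int, int], int] = {}

    def rec(i: int, j: int) -> int:
        if j - i < 4:
            return 1
        key = (i, j)
        if key in cache:
            return cache[key]
        total = rec(i + 1, j)
        for q in range(i + 4, min(j, i + w - 1) + 1):
            if _canonical(res, i, q):
                total += rec(i + 1, q - 1) * rec(q + 1, j)
        cache[key] = total
        return total

    return rec(1, seq.n)


def classify_positions(n: int, pairs) -> list[str]:
    """Geometric loop-type label for every position of one structure."""
    pairs = sorted(pairs)
    labels = ["exterior"] * n
    children: dict = {None: []}
    stack = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        children.setdefault(stack[-1] if stack else None, []).append(p)
        children.setdefault(p, [])
        stack.append(p)
    for a, b in pairs:
        labels[a - 1] = labels[b - 1] = "stem"
    for a, b in pairs:
        kids = children[(a, b)]
        inside = set(range(a + 1, b))
        for c, d in kids:
            inside -= set(range(c, d + 1))
        if not kids:
            lab = "hairpin"
        elif len(kids) == 1:
            (c, d) = kids[0]
            lab = "bulge" if (c - a - 1 == 0 or b - d - 1 == 0) else "interior"
        else:
            lab = "multi"
        for t in inside:
            labels[t - 1] = lab
    return labels


@dataclass
class StructureEnsemble:
    """The exact Boltzmann ensemble of a tiny sequence by brute force.

    Structures the model excludes (zero weight) are dropped, so
    ``sum(weights) == z`` and the stored list is exactly the support.
    """

    seq: RnaSequence
    w: int
    model: EnergyModel
    structures: list = field(repr=False)
    weights: np.ndarray = field(repr=False)

    @property
    def z(self) -> float:
        return float(self.weights.sum())

    @property
    def log_z(self) -> float:
        return float(np.log(self.z))

    def pair_probabilities(self) -> dict[tuple[int, int], float]:
        out: dict[tuple[int, int], float] = {}
        for zeta, wt in zip(self.structures, self.weights):
            for p in zeta:
                out[p] = out.get(p, 0.0) + wt
        return {p: v / self.z for p, v in out.items()}

    def stem_probability(self) -> np.ndarray:
        out = np.zeros(self.seq.n)
        for zeta, wt in zip(self.structures, self.weights):
            for a, b in zeta:
                out[a - 1] += wt
                out[b - 1] += wt
        return out / self.z

    def profile(self) -> np.ndarray:
        """(N, 6) loop-type frequencies, columns as PROFILE_COLUMNS."""
        col = {c: k for k, c in enumerate(PROFILE_COLUMNS)}
        out = np.zeros((self.seq.n, 6))
        for zeta, wt in zip(self.structures, self.weights):
            for t, lab in enumerate(classify_positions(self.seq.n, zeta)):
                out[t, col[lab]] += wt
        return out / self.z

    def outermost_frequency(self, p: int, q: int) -> float:
        """Probability that gap pair (p, q) is an outermost pair."""
        target = (p + 1, q)
        total = 0.0
        for zeta, wt in zip(self.structures, self.weights):
            if target in zeta and not any(a < p + 1 and q < b for a, b in zeta):
                total += wt
        return total / self.z

    def exterior_unpaired_frequency(self, t: int) -> float:
        """Probability that residue t lies in the exterior loop, unpaired."""
        total = 0.0
        for zeta, wt in zip(self.structures, self.weights):
            if not any(a <= t <= b for a, b in zeta):
                total += wt
        return total / self.z

    def restrict(self, w: int) -> "StructureEnsemble":
        """The sub-ensemble with all pair spans <= w (for W sweeps)."""
        keep = [
            (zeta, wt)
            for zeta, wt in zip(self.structures, self.weights)
            if all(b - a + 1 <= w for a, b in zeta)
        ]
        structures = [z for z, _ in keep]
        return StructureEnsemble(self.seq, w, self.model, structures,
                                 np.array([wt for _, wt in keep]))


def enumerate_ensemble(seq: RnaSequence, w: int,
                       model: EnergyModel | None = None) -> StructureEnsemble:
    model = model or EnergyModel.zero()
    structures = enumerate_structures(seq, w)
    kept, weights = [], []
    for zeta in structures:
        wt = structure_weight(seq.residues, zeta, model)
        if wt > 0.0:
            kept.append(zeta)
            weights.append(wt)
    return StructureEnsemble(seq, w, model, kept, np.array(weights))


# ---------------------------------------------------------------------------
# synthetic sequence generators
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}


def reverse_complement(residues: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(residues))


def random_sequence(n: int, gc_fraction: float = 0.5, seed: int = 0,
                    name: str | None = None) -> RnaSequence:
    """Reproducible i.i.d. sequence with expected GC content ``gc_fraction``."""
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = gc_fraction / 2.0
    a = (1.0 - gc_fraction) / 2.0
    draws = rng.choice(np.array(list("ACGU")), size=n, p=[a, g, g, a])
    return RnaSequence(name or f"random_n{n}_gc{gc_fraction:g}_s{seed}", "".join(draws))


def designed_hairpin(stem_len: int, loop_len: int = 4, seed: int = 0) -> RnaSequence:
    """A perfect Watson-Crick hairpin: random 5' arm, loop of A/U, 3' complement."""
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin size)")
    rng = np.random.default_rng(seed)
    arm = "".join(rng.choice(np.array(list("ACGU")), size=stem_len))
    loop = "".join(rng.choice(np.array(list("AU")), size=loop_len))
    return RnaSequence(f"hairpin_s{stem_len}_l{loop_len}_seed{seed}",
                       arm + loop + reverse_complement(arm))


def make_gene_fixture(seed: int = 0, exon_len: int = 40, intron_pad: int = 20,
                      motif_len: int = 10):
    """A toy gene whose introns base-pair with the neighbouring exon ends.

    Each intron starts with the reverse complement of the preceding exon's
    last ``motif_len`` bases, so splicing removes the pairing partner and
    lowers the stem probability of junction-proximal exonic sites.

    Returns ``(pre_mrna, mrna, exons)`` with ``exons`` as 1-based inclusive
    (start, end) coordinates on the pre-mRNA.
    """
    rng = np.random.default_rng(seed)

    def rand(n):
        return "".join(rng.choice(np.array(list("ACGU")), size=n))

    exon_seqs = [rand(exon_len) for _ in range(3)]
    parts = []
    exons = []
    pos = 0
    for k, ex in enumerate(exon_seqs):
        parts.append(ex)
        exons.append((pos + 1, pos + len(ex)))
        pos += len(ex)
        if k < 2:
            intron = reverse_complement(ex[-motif_len:]) + rand(intron_pad)
            parts.append(intron)
            pos += len(intron)
    pre = RnaSequence(f"gene_pre_seed{seed}", "".join(parts))
    mrna = RnaSequence(f"gene_mrna_seed{seed}", "".join(exon_seqs))
    return pre, mrna, exons
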