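"""Scale-free ratio variables: the per-position fold changes of the exterior DP.

The exterior inside/outside variables grow exponentially with N, but their
position-to-position fold changes

``dalpha(h) = alpha_Outer(h+1) / alpha_Outer(h)``
``dbeta(h)  = beta_Outer(h)   / beta_Outer(h+1)``

are bounded independently of N (each is 1 + a sum over at most W pairing
terms).  Stored as logarithms they form the persistent *ratio database* from
which every probability is reconstructed locally:

``r(i, j)   = Z / (alpha_Outer(i) beta_Outer(j))``
           ``= rho(i) * prod_{h=i}^{j-1} dbeta(h)``,

with ``rho(i) = Z/(alpha_Outer(i) beta_Outer(i))`` obtained from the anchor
decomposition of Z over the exterior block weights u(p, q): every structure
either leaves residue i+1 exterior-unpaired or covers it with an outermost
pair (p, q), p <= i < q.  All sums are log-sum-exp.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .core import STATE_ORDER, StateTables, attach_outside, inside_banded, u_weights
from .energy import PAIR_TABLE, EnergyModel
from .sequence import RnaSequence


class DatabaseError(ValueError):
    """Integrity failure of a ratio database (digest or header mismatch)."""


@dataclass
class RatioDatabase:
    """Per-position log fold changes of the exterior DP variables."""

    n: int
    w: int
    log_dalpha: np.ndarray  # shape (N,), entry h = log alpha(h+1)/alpha(h)
    log_dbeta: np.ndarray  # shape (N,), entry h = log beta(h)/beta(h+1)
    seq_digest: str
    model_digest: str

    def __post_init__(self) -> None:
        for arr in (self.log_dalpha, self.log_dbeta):
            if arr.shape != (self.n,):
                raise DatabaseError("ratio array length != N")
            if not np.all(np.isfinite(arr)):
                raise DatabaseError("non-finite ratio entry")
            if np.any(arr < -1e-12):
                raise DatabaseError("fold change below the unpaired-step weight")

    @property
    def log_z(self) -> float:
        """Telescoping: sum_h log dalpha(h) = log Z (alpha_Outer(0) = 1)."""
        return float(self.log_dalpha.sum())

    def check(self, seq: RnaSequence, model: EnergyModel) -> None:
        if seq.digest() != self.seq_digest:
            raise DatabaseError("sequence digest mismatch")
        if model.digest() != self.model_digest:
            raise DatabaseError("energy-model digest mismatch")

    # -- TSV round trip ----------------------------------------------------

    def dumps(self) -> str:
        buf = io.StringIO()
        buf.write("# spanfold ratio database (log fold changes, 0-based gap h)\n")
        buf.write(
            f"# N={self.n}\tW={self.w}\tseq_digest={self.seq_digest}"
            f"\tmodel_digest={self.model_digest}\n"
        )
        buf.write("h\tlog_dalpha\tlog_dbeta\n")
        for h in range(self.n):
            buf.write(f"{h}\t{self.log_dalpha[h]:.17g}\t{self.log_dbeta[h]:.17g}\n")
        return buf.getvalue()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def loads(cls, text: str) -> "RatioDatabase":
        header = {}
        rows = []
        for line in text.splitlines():
            if line.startswith("#"):
                for tok in line[1:].strip().split("\t"):
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
            elif line and not line.startswith("h\t"):
                rows.append(line.split("\t"))
        try:
            n, w = int(header["N"]), int(header["W"])
        except KeyError as exc:
            raise DatabaseError("missing N/W header") from exc
        if len(rows) != n:
            raise DatabaseError(f"expected {n} rows, found {len(rows)}")
        dal = np.array([float(r[1]) for r in rows])
        dbe = np.array([float(r[2]) for r in rows])
        return cls(n, w, dal, dbe, header.get("seq_digest", ""), header.get("model_digest", ""))

    @classmethod
    def from_file(cls, path) -> "RatioDatabase":
        with open(path) as fh:
            return cls.loads(fh.read())


def build_ratios(seq: RnaSequence, w: int, model: EnergyModel | None = None,
                 tables: StateTables | None = None) -> RatioDatabase:
    """Monolithic direct-ratio recursion for the whole sequence.

    Never materialises alpha_Outer/beta_Outer: each fold change is computed
    from the previous W fold changes and the banded alpha_Stem block weights.
    """
    model = model or EnergyModel.default()
    if tables is None:
        tables = inside_banded(seq, w, model)
    t = model.log_weight_tables(w)
    code = seq.codes()
    dal = K.delta_alpha_kernel(code, w, PAIR_TABLE, tables.alpha_stem, t.ext_pair_lw)
    dbe = K.delta_beta_kernel(code, w, PAIR_TABLE, tables.alpha_stem, t.ext_pair_lw)
    return RatioDatabase(seq.n, w, dal, dbe, seq.digest(), model.digest())


def attach_ratios(tables: StateTables, db: RatioDatabase) -> None:
    """Compute rho, the banded log r array, and the outside tables."""
    db.check(tables.seq, tables.model)
    if db.w != tables.w:
        raise DatabaseError("database W differs from table W")
    t = tables.model.log_weight_tables(tables.w)
    code = tables.seq.codes()
    rho = K.rho_kernel(code, tables.w, PAIR_TABLE, tables.alpha_stem,
                       t.ext_pair_lw, db.log_dalpha, db.log_dbeta)
    logr = K.logr_kernel(code, tables.w, PAIR_TABLE, tables.alpha_stem, rho, db.log_dbeta)
    tables.rho = rho
    attach_outside(tables, logr)


def ratio_r(i: int, j: int, db: RatioDatabase, tables: StateTables) -> float:
    """log r(i, j) = log Z/(alpha_Outer(i) beta_Outer(j)), gap coordinates."""
    if not (0 <= i <= j <= db.n and j - i <= db.w):
        raise ValueError(f"(i, j)=({i},{j}) outside 0 <= i <= j <= N, j-i <= W")
    if tables.rho is None:
        attach_ratios(tables, db)
    return float(tables.rho[i] + db.log_dbeta[i:j].sum())


def outside_over_z(state: str, k: int, l: int, db: RatioDatabase,
                   tables: StateTables) -> float:
    """beta_state(k, l)/Z: probability-scale outside value (linear scale)."""
    if state not in STATE_ORDER:
        raise ValueError(f"unknown state {state!r}")
    if not (0 <= k <= l <= db.n and l - k <= db.w):
        raise ValueError("span outside the band")
    if tables.outside is None:
        attach_ratios(tables, db)
    return float(np.exp(tables.outside[state][k, l - k]))


def transition_prob(transition: tuple, db: RatioDatabase, tables: StateTables) -> float:
    """Ensemble probability of one grammar transition.

    Supported transitions:

    ``("Outer", "Outer", i)``
        residue i+1 is exterior-unpaired (the degenerate step (i, i+1));
    ``("Outer", "OuterStem", p, q)``
        gap pair (p, q) is an outermost pair;
    ``("Stem", "pair", i, j)``
        gap pair (i, j) is paired at all (outermost or nested) — the
        base-pairing probability p(i+1, j).
    """
    if tables.outside is None:
        attach_ratios(tables, db)
    kind = transition[:2]
    if kind == ("Outer", "Outer"):
        i = transition[2]
        if not 0 <= i < db.n:
            raise ValueError("anchor outside 0..N-1")
        return float(np.exp(-tables.rho[i] - db.log_dbeta[i]))
    if kind == ("Outer", "OuterStem"):
        p, q = transition[2:]
        u = u_weights(tables)
        lu = u[p, q - p]
        if lu == -np.inf:
            return 0.0
        return float(np.exp(lu - tables.logr[p, q - p]))
    if kind == ("Stem", "pair"):
        i, j = transition[2:]
        s, bs = tables.alpha_stem[i, j - i], tables.outside["Stem"][i, j - i]
        if s == -np.inf or bs == -np.inf:
            return 0.0
        return float(np.exp(s + bs))
    raise ValueError(f"unsupported transition {transition!r}")
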