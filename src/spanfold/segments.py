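"""Divide/Connect: segment-parallel construction of the ratio database.

*Divide* splits the sequence into K contiguous segments.  For a segment with
gap range ``[s, e]`` the exterior recursion for ``alpha_Outer(k)``, ``k > s``,
is linear in the boundary values ``alpha_Outer(s - h)``; each node therefore
computes the coefficient chains

``alpha^h_k``:  coefficient of ``alpha_Outer(s-h)`` in ``alpha_Outer(k)``,

independently of every other node, reading at most W residues of context on
each side.  Because an outermost pair spans at most W gaps, only
``h = 0 .. min(W-1, s)`` can contribute.  What is persisted is scale-free:
``d alpha^h_k = alpha^h_k / alpha^0_k`` plus the chain-0 fold changes, both
bounded independently of segment length (log 0 entries do occur when no
outermost pair leaves gap ``s-h``, e.g. on a homopolymer).

*Connect* sweeps the segments in order, carrying the boundary ratios
``A_h = log alpha_Outer(s-h)/alpha_Outer(s)`` as products of already-merged
fold changes, and emits ``log dalpha`` via

``log dalpha(k-1) = F(k) - F(k-1) + log dalpha^0(k)``,
``F(k) = logsumexp_h(A_h + log d alpha^h_k)``.

The beta side runs the mirrored recursion right-to-left.  The low-disk
variant persists the d-chain columns only for the W+1 gaps at the segment
boundary (plus the chain-0 fold changes for every position, O(N) total);
Connect then first sweeps the boundary blocks to recover every segment's
``A_h``/``B_h`` exactly, and a second DP round per segment regenerates the
interior chains in memory — twice the DP time, byte-identical output.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from . import _kernels as K
from .core import inside_banded
from .energy import PAIR_TABLE, EnergyModel
from .ratios import DatabaseError, RatioDatabase
from .sequence import RnaSequence


class ConfigError(ValueError):
    pass


def segment_bounds(n: int, total: int) -> list[tuple[int, int]]:
    """Gap ranges [s, e] of the K segments: near-equal contiguous tiles."""
    if not 1 <= total <= n:
        raise ConfigError(f"need 1 <= K <= N, got K={total}, N={n}")
    base, rem = divmod(n, total)
    bounds, pos = [], 0
    for m in range(total):
        size = base + (1 if m < rem else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


@dataclass
class SegmentTable:
    """Persisted partial tables of one Divide job (see module docstring)."""

    job: int
    total: int
    s: int
    e: int
    n: int
    w: int
    seq_digest: str
    model_digest: str
    low_disk: bool
    # alpha side: dal0[k-s-1] = log alpha^0_k/alpha^0_{k-1} for k = s+1..e
    dal0: np.ndarray
    # ad[h, k - ad_k0] = log alpha^h_k - log alpha^0_k for stored k range
    ad: np.ndarray
    ad_k0: int
    # beta side, mirrored: dbe0[k-s] = log beta^0_k/beta^0_{k+1}, k = s..e-1
    dbe0: np.ndarray
    bd: np.ndarray
    bd_k0: int

    @property
    def h_alpha(self) -> int:
        return self.ad.shape[0]

    @property
    def h_beta(self) -> int:
        return self.bd.shape[0]

    # -- TSV persistence ---------------------------------------------------

    def dumps(self) -> str:
        buf = io.StringIO()
        buf.write("# spanfold segment table\n")
        buf.write(
            f"# job={self.job}\ttotal={self.total}\ts={self.s}\te={self.e}"
            f"\tN={self.n}\tW={self.w}\tseq_digest={self.seq_digest}"
            f"\tmodel_digest={self.model_digest}\tlow_disk={int(self.low_disk)}"
            f"\tad_k0={self.ad_k0}\tbd_k0={self.bd_k0}"
            f"\tha={self.h_alpha}\thb={self.h_beta}\n"
        )
        for k in range(self.s + 1, self.e + 1):
            buf.write(f"A0\t{k}\t{self.dal0[k - self.s - 1]:.17g}\n")
        for c in range(self.ad.shape[1]):
            vals = "\t".join(f"{v:.17g}" for v in self.ad[:, c])
            buf.write(f"AD\t{self.ad_k0 + c}\t{vals}\n")
        for k in range(self.s, self.e):
            buf.write(f"B0\t{k}\t{self.dbe0[k - self.s]:.17g}\n")
        for c in range(self.bd.shape[1]):
            vals = "\t".join(f"{v:.17g}" for v in self.bd[:, c])
            buf.write(f"BD\t{self.bd_k0 + c}\t{vals}\n")
        return buf.getvalue()

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def loads(cls, text: str) -> "SegmentTable":
        header: dict[str, str] = {}
        rows: dict[str, list[list[str]]] = {"A0": [], "AD": [], "B0": [], "BD": []}
        for line in text.splitlines():
            if line.startswith("#"):
                for tok in line[1:].strip().split("\t"):
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        header[k] = v
            elif line:
                parts = line.split("\t")
                rows[parts[0]].append(parts[1:])
        try:
            s, e = int(header["s"]), int(header["e"])
            ha, hb = int(header["ha"]), int(header["hb"])
            ad_k0, bd_k0 = int(header["ad_k0"]), int(header["bd_k0"])
        except KeyError as exc:
            raise DatabaseError(f"segment table missing header field {exc}") from exc
        dal0 = np.array([float(r[1]) for r in rows["A0"]])
        dbe0 = np.array([float(r[1]) for r in rows["B0"]])
        ad = np.full((ha, len(rows["AD"])), -np.inf)
        for c, r in enumerate(rows["AD"]):
            if int(r[0]) != ad_k0 + c:
                raise DatabaseError("non-contiguous AD columns")
            ad[:, c] = [float(v) for v in r[1:]]
        bd = np.full((hb, len(rows["BD"])), -np.inf)
        for c, r in enumerate(rows["BD"]):
            if int(r[0]) != bd_k0 + c:
                raise DatabaseError("non-contiguous BD columns")
            bd[:, c] = [float(v) for v in r[1:]]
        return cls(
            job=int(header["job"]), total=int(header["total"]), s=s, e=e,
            n=int(header["N"]), w=int(header["W"]),
            seq_digest=header["seq_digest"], model_digest=header["model_digest"],
            low_disk=bool(int(header["low_disk"])),
            dal0=dal0, ad=ad, ad_k0=ad_k0, dbe0=dbe0, bd=bd, bd_k0=bd_k0,
        )

    @classmethod
    def from_file(cls, path) -> "SegmentTable":
        with open(path) as fh:
            return cls.loads(fh.read())


def segment_filename(job: int, total: int) -> str:
    return f"segment_{job:04d}_of_{total:04d}.tsv"


def compute_segment(seq: RnaSequence, w: int, model: EnergyModel, job: int,
                    total: int, low_disk: bool = False) -> SegmentTable:
    """Run one Divide job: chain DP over segment ``job`` with W context."""
    n = seq.n
    s, e = segment_bounds(n, total)[job]
    lo, hi = max(0, s - w), min(n, e + w)
    sub = seq.subsequence(lo + 1, hi)
    tables = inside_banded(sub, w, model)
    t = model.log_weight_tables(w)
    code = sub.codes()
    ha = min(w - 1, s) + 1
    hb = min(w - 1, n - e) + 1
    ach = K.alpha_chain_kernel(code, w, PAIR_TABLE, tables.alpha_stem,
                               t.ext_pair_lw, s - lo, e - lo, ha)
    bch = K.beta_chain_kernel(code, w, PAIR_TABLE, tables.alpha_stem,
                              t.ext_pair_lw, s - lo, e - lo, hb)
    dal0 = ach[0, 1:] - ach[0, :-1]
    dbe0 = bch[0, :-1] - bch[0, 1:]
    ad = ach - ach[0]
    bd = bch - bch[0]
    tab = SegmentTable(
        job=job, total=total, s=s, e=e, n=n, w=w,
        seq_digest=seq.digest(), model_digest=model.digest(), low_disk=low_disk,
        dal0=dal0, ad=ad, ad_k0=s, dbe0=dbe0, bd=bd, bd_k0=s,
    )
    if low_disk:
        a_lo = max(s, e - w)
        b_hi = min(e, s + w)
        tab = replace(tab, ad=tab.ad[:, a_lo - s :], ad_k0=a_lo,
                      bd=tab.bd[:, : b_hi - s + 1], bd_k0=s)
    return tab


def divide(seq: RnaSequence, total: int, w: int, model: EnergyModel | None = None,
           outdir=None, job: int | None = None, low_disk: bool = False):
    """Run all (or one) Divide jobs; persist to ``outdir`` if given.

    Jobs are mutually independent; any subset may be re-run at any time and
    reproduces byte-identical files.
    """
    model = model or EnergyModel.default()
    jobs = range(total) if job is None else [job]
    tables = []
    for m in jobs:
        tab = compute_segment(seq, w, model, m, total, low_disk=low_disk)
        if outdir is not None:
            tab.to_file(os.path.join(outdir, segment_filename(m, total)))
        tables.append(tab)
    return tables


def load_segments(outdir, total: int) -> list[SegmentTable]:
    tables = []
    for m in range(total):
        path = os.path.join(outdir, segment_filename(m, total))
        if not os.path.exists(path):
            raise DatabaseError(f"missing segment file {path}")
        tables.append(SegmentTable.from_file(path))
    return tables


def _check_tables(tables: list[SegmentTable], seq: RnaSequence, w: int,
                  model: EnergyModel) -> list[SegmentTable]:
    tables = sorted(tables, key=lambda t: t.s)
    if not tables:
        raise DatabaseError("no segment tables")
    n = seq.n
    expected = segment_bounds(n, tables[0].total)
    if [(t.s, t.e) for t in tables] != expected:
        raise DatabaseError("segment tables do not tile 1..N")
    for t in tables:
        if t.n != n or t.w != w:
            raise DatabaseError("segment table N/W mismatch")
        if t.seq_digest != seq.digest():
            raise DatabaseError("sequence digest mismatch in segment table")
        if t.model_digest != model.digest():
            raise DatabaseError("energy-model digest mismatch in segment table")
    return tables


def _merge_alpha(a_bound: np.ndarray, tab: SegmentTable, dal: np.ndarray) -> None:
    """Emit dalpha(s..e-1) given boundary ratios A_h at s; fills ``dal``."""
    cols = a_bound[:, None] + tab.ad[:, tab.s - tab.ad_k0 :]
    f = logsumexp(cols, axis=0)
    dal[tab.s : tab.e] = f[1:] - f[:-1] + tab.dal0


def _merge_beta(b_bound: np.ndarray, tab: SegmentTable, dbe: np.ndarray) -> None:
    cols = b_bound[:, None] + tab.bd[:, : tab.e - tab.bd_k0 + 1]
    g = logsumexp(cols, axis=0)
    dbe[tab.s : tab.e] = g[:-1] - g[1:] + tab.dbe0


def _alpha_boundary(dal: np.ndarray, s: int, w: int) -> np.ndarray:
    """A_h = log alpha(s-h)/alpha(s) from already-merged fold changes."""
    h = min(w - 1, s) + 1
    out = np.zeros(h)
    out[1:] = -np.cumsum(dal[s - h + 1 : s][::-1])
    return out


def _beta_boundary(dbe: np.ndarray, e: int, n: int, w: int) -> np.ndarray:
    h = min(w - 1, n - e) + 1
    out = np.zeros(h)
    out[1:] = -np.cumsum(dbe[e : e + h - 1])
    return out


def connect(tables: list[SegmentTable], seq: RnaSequence, w: int,
            model: EnergyModel | None = None) -> RatioDatabase:
    """Merge Divide outputs into the exact full-sequence ratio database."""
    model = model or EnergyModel.default()
    tables = _check_tables(tables, seq, w, model)
    if any(t.low_disk for t in tables):
        return connect_low_disk(tables, seq, w, model)
    n = seq.n
    dal = np.empty(n)
    dbe = np.empty(n)
    for tab in tables:
        _merge_alpha(_alpha_boundary(dal, tab.s, w), tab, dal)
    for tab in reversed(tables):
        _merge_beta(_beta_boundary(dbe, tab.e, n, w), tab, dbe)
    return RatioDatabase(n, w, dal, dbe, seq.digest(), model.digest())


def connect_low_disk(tables: list[SegmentTable], seq: RnaSequence, w: int,
                     model: EnergyModel | None = None) -> RatioDatabase:
    """Connect from boundary-block tables via a second DP round per segment.

    Phase 1 sweeps the persisted boundary blocks to recover every segment's
    boundary ratios exactly; phase 2 recomputes each segment's chains in
    memory and emits the fold changes.  Output is byte-identical to
    :func:`connect` on full tables.
    """
    model = model or EnergyModel.default()
    tables = _check_tables(tables, seq, w, model)
    n = seq.n
    dal = np.full(n, np.nan)
    dbe = np.full(n, np.nan)
    a_bounds: list[np.ndarray] = []
    for tab in tables:
        a_bound = _alpha_boundary(dal, tab.s, w) if tab.s else np.zeros(1)
        a_bounds.append(a_bound)
        # tail fold changes from the persisted block: enough for the next boundary
        k0 = max(tab.s, tab.ad_k0)
        cols = a_bound[:, None] + tab.ad[:, k0 - tab.ad_k0 :]
        f = logsumexp(cols, axis=0)
        dal[k0 : tab.e] = f[1:] - f[:-1] + tab.dal0[k0 - tab.s :]
    b_bounds: list[np.ndarray] = [np.zeros(1)] * len(tables)
    for idx in range(len(tables) - 1, -1, -1):
        tab = tables[idx]
        b_bound = _beta_boundary(dbe, tab.e, n, w) if tab.e < n else np.zeros(1)
        b_bounds[idx] = b_bound
        k1 = min(tab.e, tab.bd_k0 + tab.bd.shape[1] - 1)
        cols = b_bound[:, None] + tab.bd[:, : k1 - tab.bd_k0 + 1]
        g = logsumexp(cols, axis=0)
        dbe[tab.s : k1] = g[:-1] - g[1:] + tab.dbe0[: k1 - tab.s]
    for idx, tab in enumerate(tables):
        full = compute_segment(seq, w, model, tab.job, tab.total, low_disk=False)
        _merge_alpha(a_bounds[idx], full, dal)
        _merge_beta(b_bounds[idx], full, dbe)
    return RatioDatabase(n, w, dal, dbe, seq.digest(), model.digest())
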