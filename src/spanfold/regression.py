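"""k-mer composition normalization of windowed stem probabilities.

Average stem probabilities of 32-nt windows correlate strongly with local
sequence composition.  To isolate structure propensity beyond composition,
windowed means are regressed on 4-mer frequencies by ridge regression

    (1/2) sum_n (y_n - w^T x_n)^2 + (lambda/2) w^T w,

with features ``x_n = (1/32, #AAAA/32, ..., #UUUU/32)`` (dimension 257; a
32-mer contains 29 4-mers, so the 256 count features sum to 29/32) and
targets ``y_n`` the window means.  The residual ``y_n - w^T x_n`` is the
normalized stem propensity of the window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .features import window_average
from .sequence import RnaSequence

DEFAULT_WINDOW = 32
DEFAULT_K = 4

_BASES = "ACGU"


def kmer_index(k: int = DEFAULT_K) -> dict[str, int]:
    """Lexicographic 4-mer -> feature column (column 0 is the intercept)."""
    return {"".join(t): i + 1 for i, t in enumerate(itertools.product(_BASES, repeat=k))}


@dataclass
class KmerDesign:
    """Feature matrix / target vector for the windowed regression.

    One row per non-overlapping window; windows containing ``N`` residues
    are excluded.  ``positions`` holds the 1-based start of each window.
    """

    x: np.ndarray = field(repr=False)  # (n_windows, 4**k + 1)
    y: np.ndarray = field(repr=False)
    positions: np.ndarray = field(repr=False)
    length: int = DEFAULT_WINDOW
    k: int = DEFAULT_K

    @property
    def n_features(self) -> int:
        return self.x.shape[1]


def window_features(window: str, k: int = DEFAULT_K, index: dict | None = None) -> np.ndarray:
    """Feature vector (1/L, counts/L) of one window; None for windows with N."""
    index = index or kmer_index(k)
    length = len(window)
    row = np.zeros(len(index) + 1)
    row[0] = 1.0 / length
    for i in range(length - k + 1):
        kmer = window[i : i + k]
        if kmer not in index:
            return None  # contains N
        row[index[kmer]] += 1.0 / length
    return row


def build_design(seq: RnaSequence, pstem_series, length: int = DEFAULT_WINDOW,
                 k: int = DEFAULT_K) -> KmerDesign:
    """One row per non-overlapping window of ``length``; y = window mean p_stem."""
    pstem_series = np.asarray(pstem_series, dtype=float)
    if pstem_series.size != seq.n:
        raise ValueError("p_stem series length differs from sequence length")
    index = kmer_index(k)
    means = window_average(pstem_series, length, "non-overlapping")
    rows, ys, pos = [], [], []
    for m in range(means.size):
        start = m * length
        row = window_features(seq.residues[start : start + length], k, index)
        if row is None:
            continue
        rows.append(row)
        ys.append(means[m])
        pos.append(start + 1)
    x = np.array(rows) if rows else np.empty((0, len(index) + 1))
    return KmerDesign(x=x, y=np.array(ys), positions=np.array(pos, dtype=np.int64),
                      length=length, k=k)


@dataclass
class RidgeModel:
    """Closed-form ridge solution; deterministic given (X, y, lambda)."""

    weights: np.ndarray = field(repr=False)
    penalty: float = 1.0
    k: int = DEFAULT_K

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x) @ self.weights

    # -- TSV persistence ---------------------------------------------------

    def dumps(self) -> str:
        names = ["intercept"] + sorted(kmer_index(self.k), key=kmer_index(self.k).get)
        lines = [f"# spanfold ridge model\tlambda={self.penalty:.17g}\tk={self.k}"]
        lines += [f"{n}\t{w:.17g}" for n, w in zip(names, self.weights)]
        return "\n".join(lines) + "\n"

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.dumps())

    @classmethod
    def loads(cls, text: str) -> "RidgeModel":
        lines = text.strip().splitlines()
        header = dict(tok.split("=", 1) for tok in lines[0][1:].strip().split("\t") if "=" in tok)
        weights = np.array([float(line.split("\t")[1]) for line in lines[1:]])
        return cls(weights=weights, penalty=float(header["lambda"]), k=int(header["k"]))

    @classmethod
    def from_file(cls, path) -> "RidgeModel":
        with open(path) as fh:
            return cls.loads(fh.read())


def fit_ridge(design: KmerDesign, penalty: float = 1.0) -> RidgeModel:
    """argmin of the penalised least squares in closed form.

    The penalty applies to every weight, intercept included (the objective
    does not single it out).  With ``penalty == 0`` the normal equations are
    rank-deficient (the 256 count features sum to a constant), and the
    minimum-norm least-squares solution is returned via the pseudoinverse.
    """
    if design.x.shape[0] < 1:
        raise ValueError("design has no rows")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    x, y = design.x, design.y
    if penalty == 0.0:
        w, *_ = np.linalg.lstsq(x, y, rcond=None)
    else:
        g = x.T @ x + penalty * np.eye(x.shape[1])
        w = np.linalg.solve(g, x.T @ y)
    return RidgeModel(weights=w, penalty=penalty, k=design.k)


def residualize(design: KmerDesign, model: RidgeModel) -> np.ndarray:
    """Normalized windowed stem propensity: y_n - w^T x_n per window."""
    return design.y - model.predict(design.x)


def simulate_design(n_windows: int, seed: int = 0, length: int = DEFAULT_WINDOW,
                    k: int = DEFAULT_K, noise: float = 0.01,
                    weights: np.ndarray | None = None,
                    concentration: float = 0.1):
    """Synthetic window compositions with a planted weight vector.

    Per-window 4-mer counts are Dirichlet-multinomial (``concentration``
    controls compositional diversity; small values mimic the heterogeneity of
    genomic windows), scaled exactly like :func:`build_design` rows, so the
    count features sum to ``(L - k + 1)/L`` per row.  The planted weights are
    drawn orthogonal to the one exact collinearity of this feature map (the
    intercept equals ``1/(L-k+1)`` times the count-feature sum), making the
    recovery problem identifiable.  Targets are ``X w* + N(0, noise^2)``.

    Returns ``(design, true_weights)``.
    """
    rng = np.random.default_rng(seed)
    index = kmer_index(k)
    n_feat = len(index) + 1
    n_kmers = length - k + 1
    if weights is None:
        weights = rng.uniform(-0.5, 0.5, size=n_feat)
        null = np.full(n_feat, -1.0)
        null[0] = float(n_kmers)
        weights = weights - (null @ weights) / (null @ null) * null
    probs = rng.dirichlet(np.full(len(index), concentration), size=n_windows)
    counts = np.array([rng.multinomial(n_kmers, p) for p in probs], dtype=float)
    x = np.concatenate([np.ones((n_windows, 1)), counts], axis=1) / length
    y = x @ weights + rng.normal(0.0, noise, size=n_windows)
    design = KmerDesign(x=x, y=y, positions=np.arange(1, n_windows + 1, dtype=np.int64),
                        length=length, k=k)
    return design, weights
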