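"""File input/output: FASTA, per-position TSV, window TSV, exon tables.

Per-position outputs are 1-based inclusive; window outputs are 1-based
half-open.  Every writer stamps the sequence name, N, W and the energy-model
digest into the header so databases and feature files cannot be silently
mixed across parameter sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio import SeqIO

from .features import CoordinateError
from .sequence import RnaSequence, SequenceError


def read_fasta(path, name: str | None = None) -> RnaSequence:
    """First (or named) record of a FASTA file as an RnaSequence (T -> U)."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, OSError) as exc:
        raise SequenceError(f"cannot parse FASTA {path}: {exc}") from exc
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    if name is not None:
        for rec in records:
            if rec.id == name:
                return RnaSequence(rec.id, str(rec.seq))
        raise SequenceError(f"record {name!r} not found in {path}")
    return RnaSequence(records[0].id, str(records[0].seq))


def read_fasta_all(path) -> list[RnaSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    return [RnaSequence(rec.id, str(rec.seq)) for rec in records]


def write_fasta(seq: RnaSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.name}\n")
        for k in range(0, seq.n, 70):
            fh.write(seq.residues[k : k + 70] + "\n")


def _header(kind: str, seq: RnaSequence, w: int, model_digest: str, coords: str) -> str:
    return (
        f"# spanfold {kind}\n"
        f"# seq={seq.name}\tN={seq.n}\tW={w}\tmodel_digest={model_digest}\tcoords={coords}\n"
    )


def write_positions(path, kind: str, seq: RnaSequence, w: int, model_digest: str,
                    frame: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write(_header(kind, seq, w, model_digest, "1-based inclusive"))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_stem(path, seq: RnaSequence, w: int, model_digest: str,
               p_stem: np.ndarray) -> None:
    frame = pd.DataFrame({
        "pos": np.arange(1, p_stem.size + 1),
        "p_stem": p_stem,
        "accessibility": 1.0 - p_stem,
    })
    write_positions(path, "stem probability", seq, w, model_digest, frame)


def write_profile(path, seq: RnaSequence, w: int, model_digest: str, profile) -> None:
    write_positions(path, "structural profile", seq, w, model_digest, profile.to_frame())


def write_bpp(path, seq: RnaSequence, w: int, model_digest: str, bpp,
              threshold: float = 0.0) -> None:
    rows = [(a, b, p) for (a, b), p in bpp.items() if p > threshold]
    frame = pd.DataFrame(rows, columns=["i", "j", "p"])
    write_positions(path, "base-pair probabilities", seq, w, model_digest, frame)


def write_windows(path, kind: str, seq: RnaSequence, w: int, model_digest: str,
                  starts: np.ndarray, length: int, columns: dict) -> None:
    """BED-like window scores; start 1-based, end exclusive (half-open)."""
    frame = pd.DataFrame({"name": seq.name, "start": starts, "end": starts + length, **columns})
    with open(path, "w") as fh:
        fh.write(_header(kind, seq, w, model_digest, "1-based half-open"))
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_window_scores(path, column: str) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", comment="#")
    if column not in frame.columns:
        raise CoordinateError(f"column {column!r} not in {path} (has {list(frame.columns)})")
    return frame[column].to_numpy(dtype=float)


def read_positions(path, column: str) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", comment="#")
    if column not in frame.columns:
        raise CoordinateError(f"column {column!r} not in {path} (has {list(frame.columns)})")
    return frame[column].to_numpy(dtype=float)


def read_exons(path) -> list[tuple[int, int]]:
    """Exon table: TSV of (name, start, end), 1-based inclusive, ascending."""
    exons = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CoordinateError(f"exon line {ln} needs (name, start, end)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise CoordinateError(f"non-integer exon coordinates at line {ln}") from exc
            exons.append((start, end))
    if not exons:
        raise CoordinateError(f"no exons in {path}")
    return exons


def write_exons(path, name: str, exons) -> None:
    with open(path, "w") as fh:
        fh.write("# spanfold exon table\tcoords=1-based inclusive\n")
        for start, end in exons:
            fh.write(f"{name}\t{start}\t{end}\n")


def write_structure(path, seq: RnaSequence, structure) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq.name}\tgamma={structure.gamma}\n")
        fh.write(seq.residues + "\n")
        fh.write(structure.dot_bracket() + "\n")
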