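"""High-level facade: fold a sequence once, query every feature from it."""

from __future__ import annotations

from functools import cached_property

import numpy as np

from .core import StateTables, inside_banded
from .energy import EnergyModel
from .features import (BasePairProbabilities, SecondaryStructure, StructuralProfile,
                       accessibility, base_pair_probabilities, gamma_centroid,
                       stem_probability, structural_profile)
from .ratios import RatioDatabase, attach_ratios, build_ratios
from .sequence import RnaSequence


class Fold:
    """One folded sequence: ratio database plus banded tables, queried lazily.

    Parameters
    ----------
    seq : str or RnaSequence
    w : maximal base-pair span (residue span of a pair is at most ``w``)
    model : energy model; the bundled Turner-like defaults if omitted
    db : an existing ratio database (e.g. from Divide/Connect); it is
        integrity-checked against the sequence and model digests
    """

    def __init__(self, seq, w: int = 200, model: EnergyModel | None = None,
                 db: RatioDatabase | None = None):
        self.seq = seq if isinstance(seq, RnaSequence) else RnaSequence("seq", seq)
        self.w = int(w)
        self.model = model or EnergyModel.default()
        self.tables: StateTables = inside_banded(self.seq, self.w, self.model)
        self.db = db if db is not None else build_ratios(self.seq, self.w, self.model,
                                                         tables=self.tables)
        attach_ratios(self.tables, self.db)

    @property
    def n(self) -> int:
        return self.seq.n

    @property
    def log_z(self) -> float:
        """log partition function, by telescoping the alpha fold changes."""
        return self.db.log_z

    @cached_property
    def bpp(self) -> BasePairProbabilities:
        return base_pair_probabilities(self.tables, self.db)

    @cached_property
    def p_stem(self) -> np.ndarray:
        return stem_probability(self.bpp)

    @property
    def accessibility(self) -> np.ndarray:
        return accessibility(self.bpp)

    @cached_property
    def profile(self) -> StructuralProfile:
        return structural_profile(self.tables, self.db)

    def centroid(self, gamma: float = 1.0) -> SecondaryStructure:
        return gamma_centroid(self.bpp, gamma)


def fold(seq, w: int = 200, model: EnergyModel | None = None,
         db: RatioDatabase | None = None) -> Fold:
    """Convenience constructor for :class:`Fold`."""
    return Fold(seq, w=w, model=model, db=db)
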