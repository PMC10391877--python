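"""Alignment columns as compressed site patterns with per-taxon leaf vectors.

Each alignment column maps every taxon to a nucleotide symbol (IUPAC
ambiguity codes allowed).  Identical columns are collapsed into unique
*patterns* with integer weights; likelihoods factorize over sites, so
evaluating each pattern once and weighting is exact.

A symbol becomes a length-4 indicator over {A,C,G,T}: observed bases get a
single 1, ambiguity codes are multi-hot, and gaps/unknowns (``-``, ``N``,
``?``, ``.``) are all-ones (fully missing data marginalizes out).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .taxa import TaxonSet

__all__ = ["SitePatterns", "IUPAC_VECTORS"]

_BASE_BITS = {"A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000}

# IUPAC nucleotide codes as bit masks over (A, C, G, T).
_IUPAC_BITS = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000, "U": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011,
    "B": 0b1110, "D": 0b1101, "H": 0b1011, "V": 0b0111,
    "N": 0b1111, "-": 0b1111, "?": 0b1111, ".": 0b1111, "X": 0b1111,
}

IUPAC_VECTORS = {
    sym: np.array([float(bits >> i & 1) for i in range(4)])
    for sym, bits in _IUPAC_BITS.items()
}


class SitePatterns:
    """Compressed alignment columns for a fixed taxon set.

    Attributes
    ----------
    taxa : TaxonSet
    codes : (n_patterns, n_taxa) uint8 array of IUPAC bit masks.
    weights : (n_patterns,) float array; sums to the alignment length M.
    """

    def __init__(
        self,
        taxa: TaxonSet,
        codes: np.ndarray,
        weights: np.ndarray,
    ):
        codes = np.asarray(codes, dtype=np.uint8)
        weights = np.asarray(weights, dtype=float)
        if codes.ndim != 2 or codes.shape[1] != len(taxa):
            raise ValueError("codes must be (n_patterns, n_taxa)")
        if codes.shape[0] != weights.shape[0] or codes.shape[0] < 1:
            raise ValueError("need at least one site pattern with matching weights")
        self.taxa = taxa
        self.codes = codes
        self.weights = weights

    @classmethod
    def from_sequences(
        cls, taxa: TaxonSet, sequences: Mapping[str, str], compress: bool = True
    ) -> "SitePatterns":
        """Build from per-taxon sequences of equal length."""
        missing = [lab for lab in taxa if lab not in sequences]
        if missing:
            raise ValueError(f"alignment is missing taxa: {missing}")
        rows = []
        length = None
        for lab in taxa:
            seq = str(sequences[lab]).upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"sequence length mismatch for {lab!r}: {len(seq)} != {length}"
                )
            try:
                rows.append([_IUPAC_BITS[c] for c in seq])
            except KeyError as exc:
                raise ValueError(f"illegal character {exc} in sequence for {lab!r}")
        if not length:
            raise ValueError("alignment must have at least one column")
        cols = np.array(rows, dtype=np.uint8).T  # (M, n_taxa)
        if compress:
            uniq, inverse = np.unique(cols, axis=0, return_inverse=True)
            weights = np.bincount(inverse, minlength=uniq.shape[0]).astype(float)
            return cls(taxa, uniq, weights)
        return cls(taxa, cols, np.ones(cols.shape[0]))

    @property
    def n_patterns(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return int(round(self.weights.sum()))

    def leaf_likelihoods(self) -> np.ndarray:
        """(n_taxa, n_patterns, 4) indicator vectors for the leaf PLVs."""
        bits = self.codes.T[:, :, None]  # (n_taxa, n_patterns, 1)
        shifts = np.arange(4, dtype=np.uint8)
        return ((bits >> shifts) & 1).astype(float)

    def column_symbols(self, pattern: int) -> Sequence[str]:
        rev = {v: k for k, v in _BASE_BITS.items()}
        rev.update({0b1111: "N"})
        out = []
        for b in self.codes[pattern]:
            out.append(rev.get(int(b), next(k for k, v in _IUPAC_BITS.items() if v == b)))
        return out
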