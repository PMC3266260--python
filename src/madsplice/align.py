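"""Pairwise alignment helpers (Needleman-Wunsch / Smith-Waterman wrappers).

All protein alignments use BLOSUM62 with affine gaps (open 10, extend 0.5,
free end gaps for global mode, as in EMBOSS needle); nucleotide local
alignments use +5/-4 match/mismatch with the same gap costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .models import PipelineConfig

__all__ = [
    "protein_aligner",
    "nucleotide_aligner",
    "PairwiseAlignmentView",
    "align_global",
    "align_local",
]

_MATRIX_CACHE: dict[str, substitution_matrices.Array] = {}


def _matrix(name: str) -> substitution_matrices.Array:
    if name not in _MATRIX_CACHE:
        _MATRIX_CACHE[name] = substitution_matrices.load(name)
    return _MATRIX_CACHE[name]


def protein_aligner(
    config: PipelineConfig | None = None, mode: str = "global"
) -> Align.PairwiseAligner:
    config = config or PipelineConfig()
    al = Align.PairwiseAligner()
    al.substitution_matrix = _matrix(config.protein_matrix)
    al.open_gap_score = -config.protein_gap_open
    al.extend_gap_score = -config.protein_gap_extend
    al.mode = mode
    if mode == "global":
        al.end_gap_score = 0.0  # needle-like: end gaps are free
    return al


def nucleotide_aligner(
    config: PipelineConfig | None = None, mode: str = "local"
) -> Align.PairwiseAligner:
    config = config or PipelineConfig()
    al = Align.PairwiseAligner()
    al.match_score = config.nt_match
    al.mismatch_score = config.nt_mismatch
    al.open_gap_score = -config.nt_gap_open
    al.extend_gap_score = -config.nt_gap_extend
    al.mode = mode
    if mode == "global":
        al.end_gap_score = 0.0
    return al


@dataclass
class PairwiseAlignmentView:
    """Column-level view of one pairwise alignment.

    ``a_idx``/``b_idx`` hold, per alignment column, the 0-based residue index
    in each sequence or -1 where that sequence is gapped.
    """

    a: str
    b: str
    a_idx: np.ndarray
    b_idx: np.ndarray
    score: float
    matrix_name: str = "BLOSUM62"
    protein: bool = True

    @property
    def n_columns(self) -> int:
        return len(self.a_idx)

    def column(self, col: int) -> tuple[str | None, str | None]:
        ai, bi = self.a_idx[col], self.b_idx[col]
        return (
            self.a[ai] if ai >= 0 else None,
            self.b[bi] if bi >= 0 else None,
        )

    def is_gap(self, col: int) -> bool:
        return self.a_idx[col] < 0 or self.b_idx[col] < 0

    def is_identical(self, col: int) -> bool:
        ca, cb = self.column(col)
        if ca is None or cb is None:
            return False
        ambiguous = "X" if self.protein else "N"
        if ambiguous in (ca, cb):
            return False  # ambiguity never counts as identity
        return ca == cb

    def is_positive(self, col: int) -> bool:
        """Column scores > 0 under the substitution matrix (gaps never do)."""
        ca, cb = self.column(col)
        if ca is None or cb is None:
            return False
        try:
            return float(_matrix(self.matrix_name)[ca, cb]) > 0
        except IndexError:
            return False

    def identity_pct(self) -> float:
        """Identities / aligned (gap-free) columns, as a percentage."""
        aligned = [c for c in range(self.n_columns) if not self.is_gap(c)]
        if not aligned:
            return 0.0
        ident = sum(self.is_identical(c) for c in aligned)
        return 100.0 * ident / len(aligned)

    def similarity_pct(self) -> float:
        """Positive-scoring columns / all columns (gaps in denominator)."""
        if self.n_columns == 0:
            return 0.0
        pos = sum(self.is_positive(c) for c in range(self.n_columns))
        return 100.0 * pos / self.n_columns

    def a_to_column(self, a_residue: int) -> int:
        """Alignment column of 0-based residue ``a_residue`` of sequence a."""
        cols = np.nonzero(self.a_idx == a_residue)[0]
        if len(cols) == 0:
            raise IndexError(f"residue {a_residue} not in alignment")
        return int(cols[0])

    def b_to_column(self, b_residue: int) -> int:
        cols = np.nonzero(self.b_idx == b_residue)[0]
        if len(cols) == 0:
            raise IndexError(f"residue {b_residue} not in alignment")
        return int(cols[0])

    def map_a_to_b(self, a_residue: int) -> int | None:
        """Residue of b aligned to residue ``a_residue`` of a (None if gap)."""
        col = self.a_to_column(a_residue)
        bi = self.b_idx[col]
        return int(bi) if bi >= 0 else None


def _view(
    alignment: Align.Alignment, a: str, b: str, matrix: str, protein: bool
) -> PairwiseAlignmentView:
    idx = alignment.indices
    return PairwiseAlignmentView(
        a=a,
        b=b,
        a_idx=idx[0],
        b_idx=idx[1],
        score=float(alignment.score),
        matrix_name=matrix,
        protein=protein,
    )


def align_global(
    a: str, b: str, config: PipelineConfig | None = None, protein: bool = True
) -> PairwiseAlignmentView:
    """Needleman-Wunsch alignment of two sequences (first optimum)."""
    config = config or PipelineConfig()
    al = (
        protein_aligner(config, "global")
        if protein
        else nucleotide_aligner(config, "global")
    )
    aln = al.align(a, b)[0]
    return _view(aln, a, b, config.protein_matrix, protein)


def align_local(
    a: str, b: str, config: PipelineConfig | None = None, protein: bool = True
) -> PairwiseAlignmentView:
    """Smith-Waterman alignment of two sequences (first optimum)."""
    config = config or PipelineConfig()
    al = (
        protein_aligner(config, "local")
        if protein
        else nucleotide_aligner(config, "local")
    )
    aln = al.align(a, b)[0]
    return _view(aln, a, b, config.protein_matrix, protein)
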