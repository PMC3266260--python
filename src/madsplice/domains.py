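"""Transfer of MIKC domain boundaries between proteins by global alignment.

Reference boundary residues are pushed through the alignment columns onto the
query; a boundary that lands in a query gap is snapped to the nearest aligned
query residue toward the domain interior (start boundaries snap downstream,
end boundaries upstream).
"""

from __future__ import annotations

from typing import Optional

from .align import PairwiseAlignmentView, align_global
from .models import DomainAnnotation, PipelineConfig, ResidueInterval

__all__ = ["transfer_domains"]


def _map_boundary(
    view: PairwiseAlignmentView, ref_residue0: int, snap: int
) -> Optional[int]:
    """Map a 0-based reference residue to a 0-based query residue.

    ``snap`` is +1 for start boundaries (snap toward higher residues) and -1
    for end boundaries.  Returns None only if no aligned query residue exists
    in the snap direction at all.
    """
    col = view.a_to_column(ref_residue0)
    n = view.n_columns
    while 0 <= col < n:
        qi = view.b_idx[col]
        if qi >= 0:
            return int(qi)
        col += snap
    return None


def transfer_domains(
    query_protein: str,
    reference_protein: str,
    reference_domains: DomainAnnotation,
    config: PipelineConfig | None = None,
    query_id: str = "query",
) -> Optional[DomainAnnotation]:
    """Map M/I/K/C boundaries from an annotated reference onto a query.

    Returns ``None`` (unannotatable) when the global-alignment identity falls
    below ``config.domain_transfer_min_identity_pct``.
    """
    config = config or PipelineConfig()
    view = align_global(reference_protein, query_protein, config)
    if view.identity_pct() < config.domain_transfer_min_identity_pct:
        return None

    def _interval(ref_iv: ResidueInterval) -> Optional[ResidueInterval]:
        start0 = _map_boundary(view, ref_iv.start - 1, snap=+1)
        end0 = _map_boundary(view, ref_iv.end - 1, snap=-1)
        if start0 is None or end0 is None or end0 < start0:
            return None
        return ResidueInterval(start0 + 1, end0 + 1)

    mapped = {}
    for label, ref_iv in reference_domains.labelled():
        iv = _interval(ref_iv)
        if iv is None:
            return None
        mapped[label.lower()] = iv
    kc = _interval(reference_domains.kbox_cterm)
    try:
        return DomainAnnotation(
            protein_id=query_id,
            m=mapped["m"],
            i=mapped["i"],
            k=mapped["k"],
            c=mapped["c"],
            kbox_cterm=kc,
        )
    except ValueError:
        # snapped boundaries collided (heavily gapped alignment)
        return None
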