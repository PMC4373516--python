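"""22-amplicon qPCR panel selection of well-amplified cells."""

from __future__ import annotations

from .io import QCMatrix


def select_cells(qc: QCMatrix, min_amplicons: int = 22) -> tuple[list[str], float]:
    """Cells passing the WGA quality panel.

    A cell passes iff at least ``min_amplicons`` of its 22 chromosome-
    specific amplicons amplified (default: the strict 22/22 rule; 20/22 is
    a common looser criterion for cells that may carry deletions).
    Returns (passing cell ids, pass rate).
    """
    if qc.n_cells == 0:
        raise ValueError("empty QC matrix")
    sums = qc.positives_per_cell()
    passing = [cid for cid, s in zip(qc.cell_ids, sums) if s >= min_amplicons]
    return passing, len(passing) / qc.n_cells
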