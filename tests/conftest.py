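"""Shared fixtures: compact builders for hand-written call sets."""

import numpy as np
import pandas as pd
import pytest

from scwga.io import (CELL_COLUMNS, REF_COLUMNS, CellCallSet,
                      PopulationReference, classify_variant)


def make_reference(records, sample_id="population"):
    """records: (chrom, pos, ref, alt, gt, depth) tuples; vtype inferred,
    MQ fixed at 60."""
    rows = [(c, p, r, a, classify_variant(r, a), gt, d, 60)
            for c, p, r, a, gt, d in records]
    return PopulationReference(pd.DataFrame(rows, columns=REF_COLUMNS),
                               sample_id=sample_id)


def make_cell(records, cell_id="cell0", hom_ref_callable_bp=None):
    """records: (chrom, pos, ref, alt, gt, depth, alt_reads) tuples, with
    optional trailing mq and bq_pass entries."""
    rows = []
    for rec in records:
        c, p, r, a, gt, d, alt = rec[:7]
        mq = rec[7] if len(rec) > 7 else 60
        bq = rec[8] if len(rec) > 8 else True
        rows.append((c, p, r, a, classify_variant(r, a), gt, d, mq, alt, bq))
    return CellCallSet(pd.DataFrame(rows, columns=CELL_COLUMNS),
                       cell_id=cell_id, hom_ref_callable_bp=hom_ref_callable_bp)


@pytest.fixture
def rng():
    return np.random.default_rng(20150325)
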