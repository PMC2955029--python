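"""Non-parametric bootstrap resampling of alignment columns."""

from __future__ import annotations

import numpy as np

from ..formats_io import MultipleAlignment, SequenceRecord


def bootstrap_columns(aln: MultipleAlignment,
                      seed: int | np.random.Generator) -> MultipleAlignment:
    """Resample ``n_cols`` columns i.i.d. with replacement; seeded."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, aln.n_cols, size=aln.n_cols)
    rows = np.array([list(r.seq) for r in aln.records])
    boot = rows[:, idx]
    return MultipleAlignment([
        SequenceRecord(r.id, "".join(row), r.alphabet)
        for r, row in zip(aln.records, boot)
    ])
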