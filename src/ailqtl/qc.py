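"""Marker quality control for intercross genotype matrices.

Three rules, applied in order:

1. drop markers whose calls are all missing;
2. drop non-segregating markers (exactly one observed genotype class);
3. require at least two genotype classes with ``group_min`` observations
   each — markers failing this are dropped; markers passing it but carrying
   a third, under-sized class have that class's calls masked to missing
   (the marker is kept).

Masking never flips a call between non-missing classes, and the whole
procedure is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io import GenotypeMatrix, GENOTYPE_CLASSES, MISSING, logger


@dataclass
class QCReport:
    n_input_markers: int
    n_removed_all_missing: int
    n_removed_non_segregating: int
    n_removed_group_rule: int
    n_masked_calls: int
    n_output_markers: int

    def __post_init__(self) -> None:
        removed = (self.n_removed_all_missing + self.n_removed_non_segregating
                   + self.n_removed_group_rule)
        assert self.n_output_markers == self.n_input_markers - removed
        assert min(asdict(self).values()) >= 0

    def to_dict(self) -> dict:
        return asdict(self)


def apply_marker_qc(genotypes: GenotypeMatrix, group_min: int = 10
                    ) -> tuple[GenotypeMatrix, QCReport]:
    """Filter and mask markers; returns the surviving matrix and a report.

    Any matrix is processable; an empty output is allowed (and logged
    prominently).
    """
    if group_min < 1:
        raise ValueError("group_min must be >= 1")
    calls = genotypes.calls.copy()
    n_in = genotypes.n_markers

    counts = np.stack([(calls == g).sum(axis=0) for g in GENOTYPE_CLASSES])
    observed = counts > 0

    all_missing = observed.sum(axis=0) == 0
    non_seg = observed.sum(axis=0) == 1
    big = counts >= group_min
    fails_group = (~all_missing) & (~non_seg) & (big.sum(axis=0) < 2)

    keep = ~(all_missing | non_seg | fails_group)

    # small-class masking on surviving markers (symmetric: any class,
    # including HET, with 1..group_min-1 observations is set to missing)
    n_masked = 0
    for gi, g in enumerate(GENOTYPE_CLASSES):
        mask_cols = keep & (counts[gi] > 0) & (counts[gi] < group_min)
        if mask_cols.any():
            sel = (calls[:, mask_cols] == g)
            n_masked += int(sel.sum())
            block = calls[:, mask_cols]
            block[sel] = MISSING
            calls[:, mask_cols] = block

    out = GenotypeMatrix(
        list(genotypes.individuals),
        genotypes.markers.loc[keep].reset_index(drop=True),
        calls[:, keep],
    )
    report = QCReport(
        n_input_markers=n_in,
        n_removed_all_missing=int(all_missing.sum()),
        n_removed_non_segregating=int(non_seg.sum()),
        n_removed_group_rule=int(fails_group.sum()),
        n_masked_calls=n_masked,
        n_output_markers=out.n_markers,
    )
    logger.info(
        "marker QC: %d in, %d all-missing, %d non-segregating, %d group-rule, "
        "%d calls masked, %d out",
        n_in, report.n_removed_all_missing, report.n_removed_non_segregating,
        report.n_removed_group_rule, n_masked, out.n_markers,
    )
    if out.n_markers == 0:
        logger.warning("marker QC removed every marker — empty output matrix")
    return out, report
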