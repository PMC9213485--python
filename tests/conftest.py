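import numpy as np
import pandas as pd
import pytest

from ailqtl import (GenotypeMatrix, PhenotypeTable, make_marker_map,
                    HOM_LINE1, HET, HOM_LINE2, MISSING)


def gm_from_counts(class_counts_per_marker, group_min_pad=None):
    """Genotype matrix built from per-marker class-count dicts.

    Each dict maps genotype code -> count; missing calls fill the rest.
    All markers share the individual count of the largest marker.
    """
    n = max(sum(c.values()) for c in class_counts_per_marker)
    cols = []
    for counts in class_counts_per_marker:
        col = []
        for g, k in counts.items():
            col.extend([g] * k)
        col.extend([MISSING] * (n - len(col)))
        cols.append(col)
    calls = np.array(cols, dtype=np.int8).T
    mm = make_marker_map(
        [f"mk{i}" for i in range(len(cols))],
        ["1"] * len(cols),
        [1000 * (i + 1) for i in range(len(cols))],
    )
    return GenotypeMatrix([f"ind{i}" for i in range(n)], mm, calls)


@pytest.fixture
def toy_genotypes():
    """3 markers x 6 individuals, no missing calls."""
    mm = make_marker_map(["m1", "m2", "m3"], ["1", "1", "2"],
                         [100, 200, 50])
    calls = np.array(
        [
            [HOM_LINE1, HET, HOM_LINE2],
            [HOM_LINE1, HET, HOM_LINE2],
            [HET, HOM_LINE2, HET],
            [HET, HOM_LINE1, HET],
            [HOM_LINE2, HET, HOM_LINE1],
            [HOM_LINE2, HOM_LINE1, HOM_LINE1],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix([f"i{k}" for k in range(6)], mm, calls)


@pytest.fixture
def toy_phenotypes(toy_genotypes):
    rng = np.random.default_rng(0)
    data = pd.DataFrame(
        {
            "individual_id": toy_genotypes.individuals,
            "sex": ["M", "F", "M", "F", "M", "F"],
            "subfamily": ["a", "a", "b", "b", "c", "c"],
            "litter_size": [3, 3, 4, 4, 5, 5],
            "bw": rng.normal(30, 3, 6),
        }
    )
    return PhenotypeTable(data)
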