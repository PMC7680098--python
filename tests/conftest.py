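import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from radclone import SampleSheet, SimulationConfig, VariantTable, simulate_population


def make_variant_table(ref, alt, sample_ids=None, conserved=None):
    """Small hand-built VariantTable from depth arrays (sites x samples)."""
    ref = np.atleast_2d(np.asarray(ref))
    alt = np.atleast_2d(np.asarray(alt))
    n_sites, n_samples = ref.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    if conserved is None:
        conserved = np.zeros(n_sites, dtype=bool)
    return VariantTable(
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1),
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["T"] * n_sites, dtype=object),
        sample_ids=list(sample_ids),
        ref_depth=ref,
        alt_depth=alt,
        conserved_flag=conserved,
    )


def make_sheet(circle_of, centers=None):
    """SampleSheet from {sample: circle}; centers default to a unit grid."""
    circles = list(dict.fromkeys(circle_of.values()))
    if centers is None:
        centers = {c: (10.0 * i, 0.0) for i, c in enumerate(circles)}
    rows = []
    position_count = {}
    for s, c in circle_of.items():
        k = position_count.get(c, 0)
        position_count[c] = k + 1
        label = ["near_1", "near_2", "far_3"][k] if k < 3 else f"far_{k + 1}"
        rows.append(
            {
                "sample_id": s,
                "circle_id": c,
                "position_label": label,
                "center_x": centers[c][0],
                "center_y": centers[c][1],
            }
        )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at default study conditions (reused read-only)."""
    cfg = SimulationConfig(n_circles=6, samples_per_circle=3, n_sites=2000, seed=7)
    return simulate_population(cfg)
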