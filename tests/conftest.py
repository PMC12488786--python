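"""Shared fixtures: small hand-built summary tables and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

from mrpath import SimulationConfig, SummaryDataset, simulate_pair
from mrpath.simulate import harmonized_from_truth


def make_frame(rows: list[dict]) -> pd.DataFrame:
    """Summary-statistics frame from partial row dicts with sane defaults."""
    defaults = dict(
        chrom="1",
        pos=1000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.01,
        pvalue=1e-10,
        n=100_000,
    )
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults, variant_id=f"rs{i + 1}", pos=1000 + i * 50_000_000)
        r.update(row)
        out.append(r)
    columns = ["variant_id"] + list(defaults)
    return pd.DataFrame(out, columns=columns if not out else None)


def make_dataset(rows, name="trait", trait_type="continuous", validate=True):
    return SummaryDataset.from_frame(make_frame(rows), name, trait_type, validate=validate)


@pytest.fixture(scope="session")
def sim_pair():
    """One simulated exposure/outcome pair plus its truth (no pleiotropy)."""
    cfg = SimulationConfig(n_snv=36, n_null_snv=100)
    return simulate_pair(cfg, seed=11)


@pytest.fixture(scope="session")
def sim_harmonized(sim_pair):
    ex, out, truth = sim_pair
    return harmonized_from_truth(ex, out, truth.instrument_ids)
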