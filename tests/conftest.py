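"""Shared fixtures and builders for the test suite.

Harmonized sets are built either directly from arrays (unit tests of
the estimators) or through the full selection pipeline on synthetic
chains (integration and recovery tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrmediate.instruments import HarmonizedSet, InstrumentSet, harmonize
from mrmediate.sumstats import SummaryStats


def make_h(beta_x, se_x, beta_y, se_y, ids=None,
           exposure="exposure", outcome="outcome") -> HarmonizedSet:
    """Harmonized set straight from arrays."""
    beta_x = np.asarray(beta_x, dtype=float)
    if ids is None:
        ids = np.array([f"rs{i + 1}" for i in range(len(beta_x))], dtype=object)
    return HarmonizedSet(exposure, outcome, np.asarray(ids, dtype=object),
                         beta_x, np.asarray(se_x, dtype=float),
                         np.asarray(beta_y, dtype=float),
                         np.asarray(se_y, dtype=float))


def harmonize_all(exposure: SummaryStats, outcome: SummaryStats) -> HarmonizedSet:
    """Harmonize every SNP of a GWAS against an outcome (no selection)."""
    inst = InstrumentSet(exposure.trait_name, exposure.records, {})
    return harmonize(inst, outcome)


def random_h(k: int, seed: int, theta: float = 0.5) -> HarmonizedSet:
    """A quick valid harmonized set around slope ``theta`` for algebra tests."""
    rng = np.random.default_rng(seed)
    bx = rng.normal(0.0, 0.2, k)
    bx[np.abs(bx) < 0.02] = 0.05  # keep ratios well-defined
    sx = rng.uniform(0.005, 0.02, k)
    sy = rng.uniform(0.01, 0.05, k)
    by = theta * bx + rng.normal(0.0, sy)
    return make_h(bx, sx, by, sy)


def sumstats_frame(rows: list[dict]) -> pd.DataFrame:
    defaults = dict(chrom="1", eaf=0.3, n=10_000)
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.setdefault("pos", 1000 + i * 1_000_000)
        rec.update(row)
        records.append(rec)
    return pd.DataFrame.from_records(records)


@pytest.fixture(scope="session")
def default_chain():
    """One simulated chain under the default study conditions."""
    from mrmediate.simulate import ChainSimConfig, simulate_chain

    return simulate_chain(ChainSimConfig(seed=11))
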