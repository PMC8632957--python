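from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pharmtree.io_formats import ResponseMatrix


def make_responses(
    values: dict[str, dict[str, float]],
    max_conc: dict[str, float],
    histology: dict[str, str] | None = None,
) -> ResponseMatrix:
    """Build a ResponseMatrix from {drug: {cell: ln_ic50}} mappings."""
    ln = pd.DataFrame(values)
    hist = pd.Series(histology) if histology else pd.Series("NA", index=ln.index)
    return ResponseMatrix(
        ln_ic50=ln, max_conc=pd.Series(max_conc), histology=hist
    )


def single_drug_responses(
    ln_values, max_conc: float = 1.0, drug: str = "DRUG", prefix: str = "C"
) -> ResponseMatrix:
    """One-drug cohort with cells C00, C01, ... in the order given."""
    cells = [f"{prefix}{i:02d}" for i in range(len(ln_values))]
    return make_responses(
        {drug: dict(zip(cells, map(float, ln_values)))}, {drug: max_conc}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_cohort() -> ResponseMatrix:
    """Exactly 10 sensitive (mean -4) and 10 resistant (mean +4) cells,
    ceiling 1 uM (threshold ln 1 = 0)."""
    gen = np.random.default_rng(7)
    vals = np.concatenate([gen.normal(-4, 0.5, 10), gen.normal(4, 0.5, 10)])
    return single_drug_responses(vals)
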