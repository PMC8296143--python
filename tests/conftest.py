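import numpy as np
import pandas as pd
import pytest

import durumpanel as dp


@pytest.fixture(scope="session")
def small_panel_sim() -> dp.PanelSim:
    """A modest admixed panel shared by read-only tests."""
    cfg = dp.PanelConfig(
        n_genotypes=120, n_landraces=60, n_markers=400,
        fst_like_differentiation=0.12, missing_rate=0.03, seed=101,
    )
    return dp.simulate_panel(cfg)


@pytest.fixture(scope="session")
def structured_panel_300() -> dp.PanelSim:
    """The 300-genotype panel used for the calibration/power checks."""
    cfg = dp.PanelConfig(
        n_genotypes=300, n_landraces=150, n_markers=2200,
        fst_like_differentiation=0.15, missing_rate=0.03, seed=11,
    )
    return dp.simulate_panel(cfg)


def make_mtas(rows) -> pd.DataFrame:
    """MTA frame from (marker, chrom, pos, trait, scope[, fdr]) tuples."""
    out = []
    for r in rows:
        marker, chrom, pos, trait, scope = r[:5]
        fdr = r[5] if len(r) > 5 else False
        out.append(
            {
                "marker_id": marker, "chromosome": chrom, "position_cM": pos,
                "trait": trait, "scope": str(scope), "p": 1e-4,
                "neg_log10_p": 4.0, "fdr_significant": fdr,
            }
        )
    return pd.DataFrame(out)
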