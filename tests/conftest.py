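import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mrvalve.harmonize import HarmonizedSet
from mrvalve.sumstats import CANONICAL_FIELDS, TraitPanel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_panel(rows, name="trait", **meta) -> TraitPanel:
    """Panel from (vid, chrom, pos, ea, oa, eaf, beta, se, pval, n) tuples."""
    df = pd.DataFrame(rows, columns=CANONICAL_FIELDS)
    return TraitPanel(trait_name=name, data=df, **meta)


def make_hset(beta_exp, se_exp, beta_out, se_out, name="exp", outcome="out") -> HarmonizedSet:
    ids = [f"rs{i}" for i in range(len(beta_exp))]
    data = pd.DataFrame(
        {
            "variant_id": ids,
            "beta_exp": np.asarray(beta_exp, float),
            "se_exp": np.asarray(se_exp, float),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
            "eaf": 0.3,
        }
    )
    return HarmonizedSet(
        exposure_name=name,
        outcome_name=outcome,
        data=data,
        audit={i: "kept" for i in ids},
    )


@pytest.fixture
def simple_hset():
    """Five variants, strong instruments, mild heterogeneity."""
    rng = np.random.default_rng(42)
    J = 5
    bx = rng.uniform(0.05, 0.2, J)
    sx = np.full(J, 0.005)
    sy = rng.uniform(0.02, 0.06, J)
    by = 0.4 * bx + 0.01 * rng.standard_normal(J)
    return make_hset(bx, sx, by, sy)
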