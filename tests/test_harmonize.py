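import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mrvalve.estimators import ivw_random_effects, mr_egger, weighted_median
from mrvalve.harmonize import (
    DROPPED_PALINDROMIC,
    FLIPPED,
    INFERRED_PALINDROMIC,
    KEPT,
    HarmonizationError,
    harmonize,
    orient_positive_exposure,
)
from mrvalve.synthetic import Corruption, SynthConfig, simulate_two_sample

from conftest import make_hset, make_panel

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def exp_panel(ea="A", oa="G", eaf=0.2, beta=0.1):
    return make_panel(
        [("rs1", "1", 100, ea, oa, eaf, beta, 0.01, 1e-10, 1000)], name="exp"
    )


def out_panel(ea, oa, eaf=0.2, beta=-0.2):
    return make_panel(
        [("rs1", "1", 100, ea, oa, eaf, beta, 0.02, 1e-4, 1000)],
        name="out",
        trait_type="binary",
    )


class TestAlleleAlignment:
    def test_same_alleles_kept(self):
        h = harmonize(exp_panel(), out_panel("A", "G"))
        assert h.audit["rs1"] == KEPT
        assert h.data["beta_out"].iloc[0] == -0.2

    def test_swapped_alleles_flip_sign(self):
        h = harmonize(exp_panel(), out_panel("G", "A"))
        assert h.audit["rs1"] == FLIPPED
        assert h.data["beta_out"].iloc[0] == pytest.approx(0.2)

    def test_strand_complement_resolved(self):
        # exposure A/G; outcome reported on the other strand as T/C
        h = harmonize(exp_panel(), out_panel("T", "C"))
        assert h.audit["rs1"] == KEPT
        assert h.data["beta_out"].iloc[0] == -0.2

    def test_swapped_complement_resolved(self):
        h = harmonize(exp_panel(), out_panel("C", "T"))
        assert h.audit["rs1"] == FLIPPED
        assert h.data["beta_out"].iloc[0] == pytest.approx(0.2)

    def test_incompatible_alleles_dropped(self):
        h2 = harmonize(
            make_panel(
                [
                    ("rs1", "1", 100, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
                    ("rs2", "1", 200, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
                ],
                name="exp",
            ),
            make_panel(
                [
                    ("rs1", "1", 100, "A", "C", 0.2, 0.1, 0.02, 1e-4, 1000),
                    ("rs2", "1", 200, "A", "G", 0.2, 0.1, 0.02, 1e-4, 1000),
                ],
                name="out",
            ),
        )
        assert h2.audit["rs1"].startswith("dropped")
        assert len(h2) == 1

    def test_unmatched_variant_audited(self):
        exp = make_panel(
            [
                ("rs1", "1", 100, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
                ("rs9", "1", 200, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
            ],
            name="exp",
        )
        h = harmonize(exp, out_panel("A", "G"))
        assert h.audit["rs9"] == "dropped_unmatched"
        # audit covers every exposure instrument
        assert set(h.audit) == {"rs1", "rs9"}

    def test_all_unmatched_raises(self):
        exp = exp_panel()
        out = make_panel(
            [("rs99", "1", 100, "A", "G", 0.2, 0.1, 0.02, 1e-4, 1000)], name="out"
        )
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)


class TestPalindromic:
    def test_drop_ambiguous_policy_always_drops(self):
        h_audit = {}
        with pytest.raises(HarmonizationError):
            harmonize(
                exp_panel("A", "T", eaf=0.1),
                out_panel("A", "T", eaf=0.1),
                palindrome_policy="drop_ambiguous",
            )

    def test_frequency_inference_same_side_keeps_orientation(self):
        exp = make_panel(
            [
                ("rs1", "1", 100, "A", "T", 0.10, 0.1, 0.01, 1e-10, 1000),
                ("rs2", "1", 300, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
            ],
            name="exp",
        )
        out = make_panel(
            [
                ("rs1", "1", 100, "A", "T", 0.12, -0.2, 0.02, 1e-4, 1000),
                ("rs2", "1", 300, "A", "G", 0.2, 0.1, 0.02, 1e-4, 1000),
            ],
            name="out",
        )
        h = harmonize(exp, out, palindrome_policy="infer_by_frequency", ambiguity_band=0.08)
        assert h.audit["rs1"] == INFERRED_PALINDROMIC
        assert h.data.set_index("variant_id").loc["rs1", "beta_out"] == -0.2

    def test_frequency_inference_opposite_side_flips(self):
        h = harmonize(
            exp_panel("A", "T", eaf=0.10),
            out_panel("A", "T", eaf=0.88),
            palindrome_policy="infer_by_frequency",
        )
        assert h.audit["rs1"] == INFERRED_PALINDROMIC
        assert h.data["beta_out"].iloc[0] == pytest.approx(0.2)

    def test_ambiguity_band_drops(self):
        exp = make_panel(
            [
                ("rs1", "1", 100, "C", "G", 0.30, 0.1, 0.01, 1e-10, 1000),
                ("rs2", "1", 300, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
            ],
            name="exp",
        )
        out = make_panel(
            [
                ("rs1", "1", 100, "C", "G", 0.45, -0.2, 0.02, 1e-4, 1000),
                ("rs2", "1", 300, "A", "G", 0.2, 0.1, 0.02, 1e-4, 1000),
            ],
            name="out",
        )
        h = harmonize(exp, out, palindrome_policy="infer_by_frequency", ambiguity_band=0.08)
        assert h.audit["rs1"] == DROPPED_PALINDROMIC

    def test_missing_eaf_palindrome_dropped(self):
        exp = make_panel(
            [
                ("rs1", "1", 100, "A", "T", np.nan, 0.1, 0.01, 1e-10, 1000),
                ("rs2", "1", 300, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000),
            ],
            name="exp",
        )
        out = make_panel(
            [
                ("rs1", "1", 100, "A", "T", 0.1, -0.2, 0.02, 1e-4, 1000),
                ("rs2", "1", 300, "A", "G", 0.2, 0.1, 0.02, 1e-4, 1000),
            ],
            name="out",
        )
        h = harmonize(exp, out)
        assert h.audit["rs1"] == DROPPED_PALINDROMIC


class TestOrientPositiveExposure:
    def test_double_negation(self):
        h = make_hset([-0.05], [0.01], [-0.02], [0.02])
        o = orient_positive_exposure(h)
        assert o.data["beta_exp"].iloc[0] == 0.05
        assert o.data["beta_out"].iloc[0] == 0.02

    def test_all_positive_unchanged(self):
        h = make_hset([0.05, 0.1], [0.01, 0.01], [0.02, 0.03], [0.02, 0.02])
        o = orient_positive_exposure(h)
        assert np.array_equal(o.data[["beta_exp", "beta_out"]], h.data[["beta_exp", "beta_out"]])

    def test_zero_exposure_excluded_with_warning(self):
        h = make_hset([0.0, 0.1], [0.01, 0.01], [0.02, 0.03], [0.02, 0.02])
        with pytest.warns(UserWarning):
            o = orient_positive_exposure(h)
        assert len(o) == 1

    def test_estimates_invariant_under_orientation(self):
        rng = np.random.default_rng(3)
        J = 12
        bx = rng.uniform(-0.2, 0.2, J)
        bx[bx == 0] = 0.05
        h = make_hset(bx, np.full(J, 0.01), 0.4 * bx + 0.01 * rng.standard_normal(J),
                      rng.uniform(0.02, 0.05, J))
        o = orient_positive_exposure(h)
        a, b = ivw_random_effects(h), ivw_random_effects(o)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.se == pytest.approx(b.se, rel=1e-12)
        wa = weighted_median(h, n_boot=50, seed=0)
        wb = weighted_median(o, n_boot=50, seed=0)
        assert wa.beta == pytest.approx(wb.beta, rel=1e-12)


class TestRecodingInvariance:
    """Downstream estimates are invariant to per-variant allele recoding."""

    @given(st.integers(0, 10_000))
    def test_random_recoding_of_outcome_panel(self, seed):
        cfg = SynthConfig(n_variants=15, true_beta=0.3, seed=seed)
        exp, out, _ = simulate_two_sample(cfg)
        rng = np.random.default_rng(seed + 1)
        df = out.data.copy()
        for i in range(len(df)):
            if rng.random() < 0.5:  # swap EA/OA, negate beta
                df.loc[i, ["effect_allele", "other_allele"]] = (
                    df.loc[i, "other_allele"],
                    df.loc[i, "effect_allele"],
                )
                df.loc[i, "beta"] = -df.loc[i, "beta"]
                df.loc[i, "eaf"] = 1.0 - df.loc[i, "eaf"]
            if rng.random() < 0.5:  # strand flip (non-palindromic panels)
                df.loc[i, "effect_allele"] = COMPLEMENT[df.loc[i, "effect_allele"]]
                df.loc[i, "other_allele"] = COMPLEMENT[df.loc[i, "other_allele"]]
        recoded = dataclasses.replace(out, data=df)
        h0 = orient_positive_exposure(harmonize(exp, out))
        h1 = orient_positive_exposure(harmonize(exp, recoded))
        f0, f1 = ivw_random_effects(h0), ivw_random_effects(h1)
        assert f0.beta == pytest.approx(f1.beta, abs=1e-12)
        e0, e1 = mr_egger(h0), mr_egger(h1)
        assert e0.beta == pytest.approx(e1.beta, abs=1e-12)
        assert e0.extras["intercept"] == pytest.approx(e1.extras["intercept"], abs=1e-12)
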