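import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splicegrade.diffexpr import DesignInfo, FitResult, ModerationParams
from splicegrade.errors import ValidationError
from splicegrade.splicing import (
    classify_das,
    compute_psi,
    delta_psi,
    dtu_test,
    simes_combine,
)

from conftest import group_series
from oracles import delta_psi_oracle, psi_oracle, simes_oracle


class TestComputePsi:
    def test_definitions(self, toy_ann):
        tpm = pd.DataFrame(
            {
                "s1": [30.0, 10.0, 7.0, 1.0, 1.0, 2.0],
                "s2": [5.0, 5.0, 0.0, 0.0, 0.0, 0.0],
            },
            index=list(toy_ann.transcript_gene),
        )
        psi = compute_psi(tpm, toy_ann)
        # single-isoform gene with nonzero expression: psi = 1
        assert psi.psi.loc["t2a", "s1"] == pytest.approx(1.0)
        # two equally expressed isoforms: psi = 0.5 each
        assert psi.psi.loc["t1a", "s2"] == pytest.approx(0.5)
        # proportions by definition
        assert psi.psi.loc["t1a", "s1"] == pytest.approx(0.75)
        assert psi.psi.loc["t1b", "s1"] == pytest.approx(0.25)
        # masked where the gene total is zero
        assert not psi.valid.loc["t3a", "s2"]
        assert np.isnan(psi.psi.loc["t3a", "s2"])

    def test_gene_rows_sum_to_one_where_defined(self, small_sim):
        ems = next(iter(small_sim.tissues.values()))
        psi = compute_psi(ems.tpm, small_sim.annotation)
        sums = psi.psi.groupby(psi.gene_of.to_numpy()).sum(min_count=1)
        defined = ~sums.isna()
        np.testing.assert_allclose(sums.to_numpy()[defined.to_numpy()], 1.0, atol=1e-8)

    def test_matches_per_sample_oracle(self, toy_ann, rng):
        tpm = pd.DataFrame(
            rng.uniform(0, 50, size=(6, 4)), index=list(toy_ann.transcript_gene),
            columns=list("abcd"),
        )
        psi = compute_psi(tpm, toy_ann)
        for gene, isoforms in (("g1", ["t1a", "t1b"]), ("g3", ["t3a", "t3b", "t3c"])):
            expect = psi_oracle({i: tpm.loc[i].tolist() for i in isoforms})
            for iso in isoforms:
                got = psi.psi.loc[iso].tolist()
                for a, b in zip(got, expect[iso]):
                    assert a == pytest.approx(b, abs=1e-12)


class TestDeltaPsi:
    def _design(self):
        return DesignInfo(
            groups=group_series({"ctl": 4, "trt": 4}), contrasts=[("trt", "ctl")]
        )

    def _psi_from(self, toy_ann, values):
        tpm = pd.DataFrame(values, index=list(toy_ann.transcript_gene))
        tpm.columns = self._design().groups.index
        return compute_psi(tpm, toy_ann)

    def test_constant_groups(self, toy_ann):
        # t1a: ctl psi 0.6, trt psi 0.8
        row_a = [6.0] * 4 + [8.0] * 4
        row_b = [4.0] * 4 + [2.0] * 4
        vals = np.vstack([row_a, row_b, np.ones(8), np.ones(8), np.ones(8), np.ones(8)])
        psi = self._psi_from(toy_ann, vals)
        d = delta_psi(psi, self._design(), ("trt", "ctl"))
        assert d.loc["t1a", "delta_psi"] == pytest.approx(0.2)
        assert d.loc["t1b", "delta_psi"] == pytest.approx(-0.2)

    def test_identical_groups_zero(self, toy_ann, rng):
        half = rng.uniform(1, 10, size=(6, 4))
        psi = self._psi_from(toy_ann, np.hstack([half, half]))
        d = delta_psi(psi, self._design(), ("trt", "ctl"))
        np.testing.assert_allclose(d["delta_psi"].dropna().to_numpy(), 0.0, atol=1e-12)

    def test_masked_entries_excluded_and_min_valid(self, toy_ann, rng):
        vals = rng.uniform(1, 10, size=(6, 8))
        # zero out gene g1 entirely in two control samples -> masked there
        vals[0:2, 0:2] = 0.0
        psi = self._psi_from(toy_ann, vals)
        ctl_psi = psi.psi.loc["t1a"].iloc[:4].tolist()
        trt_psi = psi.psi.loc["t1a"].iloc[4:].tolist()
        d2 = delta_psi(psi, self._design(), ("trt", "ctl"), min_valid=2)
        expect = delta_psi_oracle(
            [x if not np.isnan(x) else None for x in trt_psi],
            [x if not np.isnan(x) else None for x in ctl_psi],
            2,
        )
        assert d2.loc["t1a", "delta_psi"] == pytest.approx(expect, abs=1e-12)
        # min_valid above the masked control support makes it untestable
        d3 = delta_psi(psi, self._design(), ("trt", "ctl"), min_valid=3)
        assert d3.loc["t1a", "n_valid_control"] == 2
        assert np.isnan(d3.loc["t1a", "delta_psi"])


def make_fit(ann, beta, se, df=10.0):
    """Build a FitResult/ModerationParams pair with fully specified moments."""
    features = list(beta)
    coef = np.array([[beta[f]] for f in features])
    use = np.array([[se[f]] for f in features])
    fit = FitResult(
        features=features,
        contrasts=[("trt", "ctl")],
        coef=coef,
        unscaled_se=use,
        s2=np.ones(len(features)),
        df_residual=np.full(len(features), df),
        amean=np.zeros(len(features)),
    )
    mod = ModerationParams(
        prior_df=0.0,
        prior_var=1.0,
        posterior_var=np.ones(len(features)),
        total_df=np.full(len(features), df),
    )
    return fit, mod


class TestDtuTest:
    def test_identical_isoforms_null(self, toy_ann):
        fit, mod = make_fit(
            toy_ann,
            {"t1a": 0.7, "t1b": 0.7, "t2a": 0.0, "t3a": 0.1, "t3b": 0.1, "t3c": 0.1},
            {t: 0.3 for t in toy_ann.transcript_gene},
        )
        out = dtu_test(fit, mod, toy_ann, ("trt", "ctl"))
        assert out.loc["t1a", "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["t1a", "p"] == pytest.approx(1.0)
        # single-isoform gene omitted
        assert "t2a" not in out.index

    def test_common_shift_is_invisible(self, toy_ann):
        base = {"t3a": 0.2, "t3b": -0.1, "t3c": 0.05}
        se = {t: 0.25 for t in toy_ann.transcript_gene}
        fit1, mod1 = make_fit(toy_ann, {**base, "t1a": 0, "t1b": 0, "t2a": 0}, se)
        shifted = {k: v + 1.5 for k, v in base.items()}
        fit2, mod2 = make_fit(toy_ann, {**shifted, "t1a": 0, "t1b": 0, "t2a": 0}, se)
        out1 = dtu_test(fit1, mod1, toy_ann, ("trt", "ctl"))
        out2 = dtu_test(fit2, mod2, toy_ann, ("trt", "ctl"))
        for iso in ["t3a", "t3b", "t3c"]:
            assert out1.loc[iso, "t"] == pytest.approx(out2.loc[iso, "t"], abs=1e-10)

    def test_three_isoform_closed_form(self, toy_ann):
        beta = {"t3a": 1.0, "t3b": -0.5, "t3c": 0.2, "t1a": 0, "t1b": 0, "t2a": 0}
        se = {"t3a": 0.2, "t3b": 0.4, "t3c": 0.3, "t1a": 1, "t1b": 1, "t2a": 1}
        fit, mod = make_fit(toy_ann, beta, se)
        out = dtu_test(fit, mod, toy_ann, ("trt", "ctl"))
        w = {i: 1.0 / se[i] ** 2 for i in ("t3a", "t3b", "t3c")}
        wsum = sum(w.values())
        gene_beta = sum(w[i] * beta[i] for i in w) / wsum
        for iso in w:
            var = se[iso] ** 2 * (1.0 - w[iso] / wsum)
            expect_t = (beta[iso] - gene_beta) / np.sqrt(var)
            assert out.loc[iso, "t"] == pytest.approx(expect_t, abs=1e-10)
            assert out.loc[iso, "gene_log2FC"] == pytest.approx(gene_beta, abs=1e-12)


class TestSimes:
    def test_examples(self):
        assert simes_combine([0.03]) == pytest.approx(0.03)
        assert simes_combine([0.01, 0.04, 0.03]) == pytest.approx(0.03)
        assert simes_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_empty_after_nan_removal(self):
        with pytest.raises(ValidationError):
            simes_combine([np.nan, np.nan])

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=15))
    def test_matches_oracle_and_bounds(self, ps):
        got = simes_combine(ps)
        assert got == pytest.approx(simes_oracle(ps), abs=1e-12)
        assert min(ps) <= got <= min(1.0, len(ps) * min(ps))


class TestClassifyDas:
    def _tables(self, dpsi_vals, p_vals, genes):
        idx = [f"i{k}" for k in range(len(p_vals))]
        dtu = pd.DataFrame(
            {"gene_id": genes, "log2FC": 0.0, "gene_log2FC": 0.0, "t": 0.0, "p": p_vals},
            index=pd.Index(idx, name="isoform_id"),
        )
        dpsi = pd.DataFrame(
            {"gene_id": genes, "delta_psi": dpsi_vals},
            index=pd.Index(idx, name="isoform_id"),
        )
        return dtu, dpsi

    def test_calls_and_boundaries(self):
        dtu, dpsi = self._tables(
            dpsi_vals=[0.06, 0.05, -0.30, 0.20],
            p_vals=[1e-4, 1e-6, 1e-5, 0.9],
            genes=["gA", "gB", "gC", "gC"],
        )
        iso, das = classify_das(dtu, dpsi)
        assert iso.loc["i0", "call"] == "DTU-up"
        assert iso.loc["i1", "call"] == "ns"  # delta_psi exactly at threshold
        assert iso.loc["i2", "call"] == "DTU-down"
        # gene with |delta_psi| 0.3 and tiny Simes p is DAS
        assert bool(das.loc["gC", "call"]) is True

    def test_das_requires_effect_size(self):
        dtu, dpsi = self._tables(
            dpsi_vals=[0.01, -0.02], p_vals=[1e-8, 1e-8], genes=["g", "g"]
        )
        _, das = classify_das(dtu, dpsi)
        assert bool(das.loc["g", "call"]) is False

    def test_untested_isoforms_stay_ns(self):
        dtu, dpsi = self._tables(
            dpsi_vals=[0.5, np.nan], p_vals=[np.nan, 1e-3], genes=["g1", "g2"]
        )
        iso, _ = classify_das(dtu, dpsi)
        assert (iso["call"] == "ns").all()
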