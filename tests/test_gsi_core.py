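import numpy as np
import pandas as pd
import pytest

from gsikit.genotype_io import BaselineCollection, build_allele_index, table_from_records
from gsikit.gsi_core import (
    McmcConfig,
    bootstrap_correct,
    fit_mixture,
    genotype_loglik,
    loglik_matrix,
    posterior_freqs,
    self_assign_loo,
)
from gsikit.popgen_stats import allele_counts


def _counts(records, loci, labels):
    t = table_from_records(records, loci=loci, labels=labels)
    cols = list(dict.fromkeys(labels))
    return allele_counts(BaselineCollection(t, cols, {c: c for c in cols}))


class TestPosteriorFreqs:
    def test_formula_with_counts(self):
        # P: x=(10,0), n=10, A=2, lambda=1/2 -> theta=(10.5/11, 0.5/11);
        # allele b is contributed by collection Q only
        recs = {f"f{i}": [("a", "a")] for i in range(5)}
        recs["h"] = [("b", "b")]
        labels = ["P"] * 5 + ["Q"]
        t = table_from_records(recs, loci=["L"], labels=labels)
        b = BaselineCollection(t, ["P", "Q"], {"P": "P", "Q": "Q"})
        model = posterior_freqs(allele_counts(b))
        assert np.allclose(model.theta[0][0], [10.5 / 11, 0.5 / 11])
        assert np.allclose(model.theta[0][1], [0.5 / 3, 2.5 / 3])

    def test_no_data_gives_prior_mean(self):
        recs = {"f": [("a", "b"), None], "g": [None, ("c", "d")]}
        t = table_from_records(recs, loci=["L0", "L1"], labels=["P", "Q"])
        b = BaselineCollection(t, ["P", "Q"], {"P": "P", "Q": "Q"})
        model = posterior_freqs(allele_counts(b))
        assert np.allclose(model.theta[0][1], [0.5, 0.5])  # Q untyped at L0
        assert np.allclose(model.theta[1][0], [0.5, 0.5])  # P untyped at L1

    def test_symmetric_counts_half(self):
        recs = {"f": [("a", "b")], "g": [("a", "b")]}
        t = table_from_records(recs, loci=["L"], labels=["P", "P"])
        b = BaselineCollection(t, ["P"], {"P": "P"})
        for lam in ("per_allele", 0.7, 2.0):
            model = posterior_freqs(allele_counts(b), lam)
            assert np.allclose(model.theta[0][0], [0.5, 0.5])

    def test_rows_sum_to_one(self, synth_small):
        model = posterior_freqs(allele_counts(synth_small.baseline))
        for th in model.theta:
            assert np.allclose(th.sum(axis=1), 1.0)
            assert (th > 0).all()

    def test_empty_locus_dropped_with_warning(self):
        recs = {"f": [("a", "b"), None], "g": [("a", "a"), None]}
        t = table_from_records(recs, loci=["L0", "Lempty"], labels=["P", "P"])
        b = BaselineCollection(t, ["P"], {"P": "P"})
        with pytest.warns(UserWarning, match="Lempty"):
            model = posterior_freqs(allele_counts(b))
        assert model.loci == ["L0"]


class TestGenotypeLoglik:
    def _model(self):
        recs = {
            "f1": [("a", "a"), ("x", "y")],
            "f2": [("a", "b"), ("y", "z")],
            "f3": [("b", "c")] + [("x", "z")],
        }
        t = table_from_records(recs, loci=["L0", "L1"], labels=["P"] * 3)
        b = BaselineCollection(t, ["P"], {"P": "P"})
        return posterior_freqs(allele_counts(b))

    def test_homozygote_and_heterozygote(self):
        model = self._model()
        th = model.theta[0][0]
        enc_hom = np.array([[0, 0], [-1, -1]], dtype=np.int32)  # a/a, L1 missing
        assert genotype_loglik(enc_hom, 0, model) == pytest.approx(2 * np.log(th[0]))
        enc_het = np.array([[0, 1], [-1, -1]], dtype=np.int32)
        assert genotype_loglik(enc_het, 0, model) == pytest.approx(
            np.log(2 * th[0] * th[1])
        )

    def test_all_missing_is_zero(self):
        model = self._model()
        enc = np.full((2, 2), -1, dtype=np.int32)
        assert genotype_loglik(enc, 0, model) == 0.0

    def test_invariant_to_locus_order_and_relabeling(self):
        recs = {
            "f1": [("120", "126"), ("7", "9")],
            "f2": [("120", "120"), ("9", "9")],
            "f3": [("126", "126"), ("7", "7")],
        }
        labels = ["P", "P", "Q"]

        def build(loci_order, rename):
            out = {}
            for k, v in recs.items():
                row = [tuple(sorted((rename(x), rename(y)))) for (x, y) in v]
                out[k] = [row[i] for i in loci_order]
            t = table_from_records(out, loci=[["LA", "LB"][i] for i in loci_order], labels=labels)
            b = BaselineCollection(t, ["P", "Q"], {"P": "P", "Q": "Q"})
            model = posterior_freqs(allele_counts(b))
            enc = model.index.encode(t)[:, model.kept_locus_idx, :]
            return loglik_matrix(enc, model)

        base = build([0, 1], lambda s: s)
        swapped = build([1, 0], lambda s: s)
        relabeled = build([0, 1], lambda s: "z" + s)
        assert np.allclose(base, swapped)
        assert np.allclose(base, relabeled)


class TestSelfAssignLoo:
    def test_single_collection_posterior_one(self):
        recs = {"f1": [("a", "b")], "f2": [("a", "a")], "f3": [("b", "b")]}
        t = table_from_records(recs, loci=["L"], labels=["P"] * 3)
        b = BaselineCollection(t, ["P"], {"P": "P"})
        post, ru = self_assign_loo(b)
        assert np.allclose(post.to_numpy(), 1.0)
        assert np.allclose(ru.to_numpy(), 1.0)

    def test_identical_collections_mean_half(self):
        rng = np.random.default_rng(3)
        recs = {}
        labels = []
        for pop in ("P", "Q"):
            for i in range(40):
                a, b = rng.choice(["x", "y", "z"], size=2)
                recs[f"{pop}{i}"] = [tuple(sorted((a, b)))]
                labels.append(pop)
        t = table_from_records(recs, loci=["L"], labels=labels)
        base = BaselineCollection(t, ["P", "Q"], {"P": "P", "Q": "Q"})
        post, _ = self_assign_loo(base)
        assert post["P"].mean() == pytest.approx(0.5, abs=0.05)

    def test_matches_manual_decrement_on_three_fish(self):
        """Leave-one-out equals rebuilding the baseline without the focal
        fish (same allele index) and scoring it as a mixture fish."""
        recs = {
            "a1": [("120", "123"), ("7", "7")],
            "a2": [("120", "120"), ("7", "9")],
            "b1": [("123", "123"), ("9", "9")],
        }
        labels = ["A", "A", "B"]
        t = table_from_records(recs, loci=["L0", "L1"], labels=labels)
        base = BaselineCollection(t, ["A", "B"], {"A": "A", "B": "B"})
        post, _ = self_assign_loo(base)

        idx = build_allele_index(t)
        for focal, lab in zip(recs, labels):
            keep = {k: v for k, v in recs.items() if k != focal}
            keep_labels = [l for k, l in zip(recs, labels) if k != focal]
            t_rest = table_from_records(keep, loci=["L0", "L1"], labels=keep_labels)
            # collection list kept identical so priors/columns align
            b_rest = BaselineCollection(t_rest, ["A", "B"], {"A": "A", "B": "B"})
            model = posterior_freqs(allele_counts(b_rest, idx))
            t_focal = table_from_records({focal: recs[focal]}, loci=["L0", "L1"])
            enc = idx.encode(t_focal)[:, model.kept_locus_idx, :]
            logl = loglik_matrix(enc, model)[0]
            manual = np.exp(logl - logl.max())
            manual /= manual.sum()
            assert np.allclose(post.loc[focal].to_numpy(), manual, atol=1e-12)


class TestFitMixture:
    def test_disjoint_baseline_mixture_from_one_unit(self, disjoint_baseline):
        mix = table_from_records(
            {f"m{i}": [("100", "100")] * 4 for i in range(200)},
            loci=disjoint_baseline.genotypes.loci,
        )
        cfg = McmcConfig(n_iter=1500, burn_in=200, n_boot=0, seed=1)
        res = fit_mixture(mix, disjoint_baseline, cfg, run_bootstrap=False)
        # flat Dirichlet prior caps the mean at (n+1)/(n+2) even for perfect data
        assert res.ru_pi_hat["A"] >= 0.99

    def test_identical_collections_prior_mean(self):
        recs = {}
        labels = []
        for pop in ("P", "Q"):
            for i in range(20):
                recs[f"{pop}{i}"] = [("x", "y")]
                labels.append(pop)
        t = table_from_records(recs, loci=["L"], labels=labels)
        base = BaselineCollection(t, ["P", "Q"], {"P": "P", "Q": "Q"})
        mix = table_from_records({f"m{i}": [("x", "x")] for i in range(10)}, loci=["L"])
        res = fit_mixture(mix, base, McmcConfig(n_iter=4000, burn_in=500, n_boot=0, seed=2),
                          run_bootstrap=False)
        assert res.pi_hat["P"] == pytest.approx(0.5, abs=0.05)

    def test_posterior_rows_and_trace_normalized(self, synth_small):
        from gsikit.synthetic_data import generate_mixture

        mix, _ = generate_mixture(
            synth_small.true_freqs, np.full(6, 1 / 6), 40, seed=9
        )
        res = fit_mixture(mix, synth_small.baseline,
                          McmcConfig(n_iter=1200, burn_in=200, n_boot=0, seed=10),
                          run_bootstrap=False)
        assert np.allclose(res.posterior.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(res.pi_trace.sum(axis=1), 1.0, atol=1e-9)
        assert (res.ci["low"] <= res.ru_pi_hat + 1e-9).all()
        assert (res.ru_pi_hat <= res.ci["high"] + 1e-9).all()

    def test_empty_mixture_rejected(self, disjoint_baseline):
        mix = table_from_records({}, loci=disjoint_baseline.genotypes.loci)
        with pytest.raises(ValueError, match="empty"):
            fit_mixture(mix, disjoint_baseline, McmcConfig(seed=0))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcConfig(n_boot=-1)

    def test_mixture_private_allele_handled(self, toy_baseline):
        mix = table_from_records({"m1": [("999", "999"), ("100", "103")]},
                                 loci=["L1", "L2"])
        res = fit_mixture(mix, toy_baseline,
                          McmcConfig(n_iter=500, burn_in=100, n_boot=0, seed=4),
                          run_bootstrap=False)
        assert np.isfinite(res.pi_trace).all()


class TestBootstrapCorrect:
    def test_zero_boot_is_identity(self, disjoint_baseline):
        mix = table_from_records(
            {f"m{i}": [("100", "100")] * 4 for i in range(20)},
            loci=disjoint_baseline.genotypes.loci,
        )
        cfg = McmcConfig(n_iter=800, burn_in=100, n_boot=0, seed=3)
        res = fit_mixture(mix, disjoint_baseline, cfg, run_bootstrap=False)
        corrected = bootstrap_correct(res, disjoint_baseline, cfg)
        assert np.allclose(corrected.to_numpy(), res.ru_pi_hat.to_numpy())

    def test_well_separated_correction_small(self, disjoint_baseline):
        mix = table_from_records(
            {f"m{i}": [("100", "100")] * 4 for i in range(15)}
            | {f"n{i}": [("200", "200")] * 4 for i in range(15)},
            loci=disjoint_baseline.genotypes.loci,
        )
        cfg = McmcConfig(n_iter=800, burn_in=100, n_boot=20, seed=6)
        res = fit_mixture(mix, disjoint_baseline, cfg)
        diff = (res.pi_corrected - res.ru_pi_hat).abs().max()
        assert diff < 0.02
        assert res.pi_corrected.sum() == pytest.approx(1.0)
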