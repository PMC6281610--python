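import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossmr.mr import (
    annotation_filter,
    filter_conserved,
    marina_activity,
    sample_activity_matrix,
    stouffer_integrate,
)
from crossmr.regulons import Interactome, Regulon
from crossmr.signatures import GeneSignature, OrthologMap


def _universe_sig(n, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    return GeneSignature.from_scores(genes, rng.normal(size=n))


def _single_regulon_interactome(regulon):
    return Interactome([regulon], {regulon.regulator, *regulon.targets} | {"spare"})


class TestMarinaActivity:
    def test_coherent_regulon_scores_active(self):
        # signed differential scores 9.5 .. -9.5; positive targets sit in
        # the overexpressed tail, negative targets in the underexpressed one
        sig = GeneSignature.from_scores(
            [f"g{i}" for i in range(20)], np.arange(20, 0, -1.0) - 10.5
        )
        reg = Regulon("r", {"g0": 1.0, "g1": 1.0, "g2": 1.0},
                      {"g17": 1.0, "g18": 1.0, "g19": 1.0})
        table = marina_activity(
            _single_regulon_interactome(reg), sig, n_perm=200, seed=1
        )
        assert table.loc["r", "nes"] > 0
        assert table.loc["r", "p"] < 0.05

    def test_mode_swap_negates_nes_exactly_for_equal_split(self):
        # symmetric score multiset: the mode-adjusted ranking reflects
        # exactly under a mode swap, so with an equal (n_pos, n_neg) split
        # and the same seed the NES negates bit-for-bit
        mags = np.arange(1.0, 21.0) / 2.0
        scores = np.concatenate([mags, -mags])
        sig = GeneSignature.from_scores([f"g{i}" for i in range(40)], scores)
        pos = {f"g{i}": 1.0 for i in range(0, 6)}
        neg = {f"g{i}": 1.0 for i in range(30, 36)}
        fwd = marina_activity(
            _single_regulon_interactome(Regulon("r", pos, neg)), sig,
            n_perm=300, seed=9,
        )
        rev = marina_activity(
            _single_regulon_interactome(Regulon("r", neg, pos)), sig,
            n_perm=300, seed=9,
        )
        assert rev.loc["r", "nes"] == pytest.approx(-fwd.loc["r", "nes"], abs=1e-12)
        assert rev.loc["r", "p"] == fwd.loc["r", "p"]

    def test_mode_swap_flips_sign_for_unequal_split(self):
        sig = _universe_sig(40, seed=3)
        pos = {f"g{i}": 1.0 for i in range(0, 8)}
        neg = {f"g{i}": 1.0 for i in range(30, 34)}
        fwd = marina_activity(
            _single_regulon_interactome(Regulon("r", pos, neg)), sig,
            n_perm=500, seed=9,
        )
        rev = marina_activity(
            _single_regulon_interactome(Regulon("r", neg, pos)), sig,
            n_perm=500, seed=9,
        )
        assert np.sign(rev.loc["r", "nes"]) == -np.sign(fwd.loc["r", "nes"])

    def test_exhaustive_null_matches_brute_force_oracle(self):
        """NES and p on a 10-gene universe equal an independent enumeration
        of every target placement and mode assignment."""
        n, n_pos, n_neg = 10, 2, 2
        sig = _universe_sig(n, seed=4)
        pos = {str(sig.genes[0]): 1.0, str(sig.genes[3]): 1.0}
        neg = {str(sig.genes[7]): 1.0, str(sig.genes[9]): 1.0}
        regulon = Regulon("r", pos, neg)
        table = marina_activity(
            _single_regulon_interactome(regulon), sig, null="exhaustive", seed=0
        )

        def brute_es(hit_scores_by_gene):
            # plain running-sum on the re-ranked adjusted signature
            adjusted = {
                g: hit_scores_by_gene.get(g, s)
                for g, s in zip(sig.genes, sig.scores)
            }
            order = sorted(adjusted, key=lambda g: (-adjusted[g], g))
            qs = set(hit_scores_by_gene)
            k = len(qs)
            run, best = 0.0, 0.0
            for g in order:
                if g in qs:
                    run += 1.0 / k  # unweighted default
                else:
                    run -= 1.0 / (n - k)
                if abs(run) > abs(best):
                    best = run
            return best

        obs = brute_es(
            {g: sig.score_of(g) for g in pos}
            | {g: -sig.score_of(g) for g in neg}
        )
        null = []
        for subset in itertools.combinations(sig.genes, n_pos + n_neg):
            for pos_idx in itertools.combinations(range(n_pos + n_neg), n_pos):
                hit = {}
                for j, g in enumerate(subset):
                    s = sig.score_of(g)
                    hit[g] = s if j in pos_idx else -s
                null.append(brute_es(hit))
        null = np.array(null)
        nes_ref = obs / np.sqrt(np.mean(null**2))
        p_ref = (1 + np.count_nonzero(np.abs(null) >= abs(obs))) / (null.size + 1)
        assert table.loc["r", "nes"] == pytest.approx(nes_ref, abs=1e-9)
        assert table.loc["r", "p"] == pytest.approx(p_ref, abs=1e-12)

    def test_deterministic(self, small_study):
        from crossmr.signatures import welch_t_signature

        sig = welch_t_signature(
            small_study.mouse_expression, small_study.mouse_labels,
            "groupA", "groupB",
        )
        a = marina_activity(small_study.mouse_interactome, sig, n_perm=100, seed=5)
        b = marina_activity(small_study.mouse_interactome, sig, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestSampleActivity:
    def test_cohort_mean_sample_has_near_null_activity(self, rng):
        genes = [f"g{i}" for i in range(100)]
        samples = [f"s{j}" for j in range(9)]
        X = rng.normal(size=(100, 9))
        X[:, 0] = X[:, 1:].mean(axis=1)  # sample 0 = cohort mean
        matrix = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
        regs = [
            Regulon(
                f"r{j}",
                {g: 1.0 for g in rng.choice(genes, 10, replace=False)},
                {},
            )
            for j in range(5)
        ]
        inter = Interactome(regs, set(genes) | {r.regulator for r in regs})
        act = sample_activity_matrix(inter, matrix, n_perm=100, seed=3)
        # the mean sample carries no ranking signal: activities centred on 0
        assert act["s0"].abs().mean() < 1.0
        assert act["s0"].abs().max() < 3.0

    def test_deterministic(self, small_study):
        planted = list(small_study.human_truth.planted_regulators)
        sub = Interactome(
            [small_study.human_interactome[r] for r in planted],
            small_study.human_interactome.universe,
        )
        a = sample_activity_matrix(
            sub, small_study.survival_expression.iloc[:, :10], n_perm=50, seed=2
        )
        b = sample_activity_matrix(
            sub, small_study.survival_expression.iloc[:, :10], n_perm=50, seed=2
        )
        pd.testing.assert_frame_equal(a, b)


def _mr_table(names, nes, p=None):
    nes = np.asarray(nes, float)
    return pd.DataFrame(
        {"nes": nes, "p": p if p is not None else np.full(nes.size, 0.01)},
        index=pd.Index(names, name="regulator"),
    )


class TestStouffer:
    def test_closed_form_grid(self):
        zs = np.linspace(-5, 5, 21)
        for zm in zs:
            for zh in zs:
                t = stouffer_integrate(_mr_table(["r"], [zm]), _mr_table(["r"], [zh]))
                z = (zm + zh) / np.sqrt(2)
                assert t.loc["r", "z_combined"] == pytest.approx(z, abs=1e-12)
                assert t.loc["r", "p_combined"] == pytest.approx(
                    2 * stats.norm.sf(abs(z)), abs=1e-12
                )

    def test_known_values(self):
        t = stouffer_integrate(_mr_table(["r"], [1.96]), _mr_table(["r"], [1.96]))
        assert t.loc["r", "z_combined"] == pytest.approx(2.7719, abs=1e-4)
        assert t.loc["r", "p_combined"] == pytest.approx(0.00556, abs=5e-5)
        t0 = stouffer_integrate(_mr_table(["r"], [0.0]), _mr_table(["r"], [0.0]))
        assert t0.loc["r", "z_combined"] == 0.0
        assert t0.loc["r", "p_combined"] == pytest.approx(1.0)

    def test_discordant_rows_flagged(self):
        t = stouffer_integrate(_mr_table(["r"], [3.0]), _mr_table(["r"], [-3.0]))
        assert t.loc["r", "z_combined"] == pytest.approx(0.0)
        assert not t.loc["r", "concordant"]

    def test_ortholog_translation_collapses_by_max_abs_nes(self):
        mouse = _mr_table(["m1", "m2"], [2.0, -4.0])
        human = _mr_table(["h1"], [1.0])
        omap = OrthologMap({"m1": ("h1",), "m2": ("h1",)})
        t = stouffer_integrate(mouse, human, omap)
        assert t.loc["h1", "nes_mouse"] == -4.0

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            stouffer_integrate(_mr_table(["a"], [1.0]), _mr_table(["b"], [1.0]))


class TestFilters:
    def test_filter_conserved_toy_table(self):
        table = pd.DataFrame(
            {
                "z_combined": [5.0, 4.5, -5.0, 4.2, 0.5, 4.8],
                "p_combined": [1e-7, 1e-6, 1e-7, 1e-5, 0.6, 2e-3],
                "concordant": [True, True, True, False, True, True],
            },
            index=pd.Index(list("abcdef"), name="regulator"),
        )
        out = filter_conserved(table)
        # a, b pass; c is repressed, d discordant, e/f above threshold
        assert list(out.index) == ["a", "b"]
        both = filter_conserved(table, direction="both")
        assert set(both.index) == {"a", "b", "c"}

    def test_annotation_filter(self):
        table = _mr_table(list("abcde"), np.ones(5))
        out = annotation_filter(table, {"b", "d", "zz"})
        assert list(out.index) == ["b", "d"]
        assert len(annotation_filter(table, {"zz"})) == 0
        with pytest.raises(ValueError):
            annotation_filter(table, set())
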