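"""Expression-impact statistics: correlations, FDR, shift tests, eQTLs."""

import numpy as np
import pandas as pd
import pytest

from lncevo.expression import (ExpressionMatrix, eqtl_density_compare,
                               filter_eqtls, pair_correlations,
                               random_pair_background,
                               representative_transcript, robust_expression,
                               tissue_shift_test)

from refimpl import bh_stepup


def make_matrix(values: dict, tissues: dict, genes: dict | None = None):
    tpm = pd.DataFrame(values).T
    st = pd.Series(tissues)
    tg = pd.Series(genes or {t: t.rsplit(".", 1)[0] for t in values})
    return ExpressionMatrix(tpm, st, tg)


@pytest.fixture
def two_tissue_matrix(rng):
    samples = [f"s{i}" for i in range(40)]
    tissues = {s: ("brain" if i < 20 else "liver") for i, s in enumerate(samples)}
    x = rng.normal(5, 1, 40)
    values = {
        "lnc.t1": x + rng.normal(0, 0.1, 40),
        "tgt.t1": x + rng.normal(0, 0.1, 40),
        "flat.t1": np.full(40, 2.0),
        "noise.t1": rng.normal(5, 1, 40),
    }
    values = {k: dict(zip(samples, np.clip(v, 0.01, None)))
              for k, v in values.items()}
    return make_matrix(values, tissues)


class TestRobustAndRepresentative:
    def test_median_strictly_above_point_one(self):
        samples = {"s1": 0.1, "s2": 0.1, "s3": 0.1}
        m = make_matrix({"t.t1": samples}, {s: "x" for s in samples})
        assert robust_expression(m, "t.t1", "x") is False
        m2 = make_matrix({"t.t1": {k: 0.1001 for k in samples}},
                         {s: "x" for s in samples})
        assert robust_expression(m2, "t.t1", "x") is True

    def test_all_zero_gene_not_robust_and_single_sample_counts(self):
        m = make_matrix({"a.t1": {"s1": 0.0}, "b.t1": {"s1": 5.0}}, {"s1": "x"})
        assert robust_expression(m, "a.t1", "x") is False
        assert robust_expression(m, "b.t1", "x") is True

    def test_dbd_requirement_beats_higher_tpm(self):
        m = make_matrix(
            {"g.t1": {"s1": 3.0}, "g.t2": {"s1": 9.0}},
            {"s1": "x"}, {"g.t1": "g", "g.t2": "g"})
        assert representative_transcript("g", m, {"g.t1"}) == "g.t1"

    def test_highest_tpm_among_dbd_transcripts(self):
        m = make_matrix(
            {"g.t1": {"s1": 3.0}, "g.t2": {"s1": 5.0}},
            {"s1": "x"}, {"g.t1": "g", "g.t2": "g"})
        assert representative_transcript("g", m, {"g.t1", "g.t2"}) == "g.t2"

    def test_no_dbd_transcript_is_an_error(self):
        m = make_matrix({"g.t1": {"s1": 3.0}}, {"s1": "x"}, {"g.t1": "g"})
        with pytest.raises(ValueError):
            representative_transcript("g", m, set())


class TestPairCorrelations:
    def test_perfectly_monotone_pair_rho_one(self, two_tissue_matrix):
        df = pair_correlations([("lnc.t1", "tgt.t1")], two_tissue_matrix,
                               min_samples=10)
        assert (df.rho > 0.95).all()
        assert df.significant.all()

    def test_constant_vector_pair_skipped(self, two_tissue_matrix):
        df = pair_correlations([("lnc.t1", "flat.t1")], two_tissue_matrix,
                               min_samples=10)
        assert len(df) == 0

    def test_null_pairs_rarely_significant(self):
        rng = np.random.default_rng(0)
        n = 50
        samples = [f"s{i}" for i in range(n)]
        tissues = {s: "t" for s in samples}
        values = {f"x{i}.t1": dict(zip(samples, rng.normal(5, 1, n)))
                  for i in range(60)}
        m = make_matrix(values, tissues)
        pairs = [(f"x{i}.t1", f"x{i+30}.t1") for i in range(30)]
        df = pair_correlations(pairs, m, min_samples=10)
        assert df.significant.mean() <= 0.05

    def test_bh_fdr_matches_independent_stepup(self):
        rng = np.random.default_rng(1)
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_stepup(p))

    def test_random_pair_background_is_deterministic_and_null(self):
        rng = np.random.default_rng(2)
        n = 50
        samples = [f"s{i}" for i in range(n)]
        tissues = {s: "t" for s in samples}
        values = {f"l{i}.t1": dict(zip(samples, rng.normal(5, 1, n)))
                  for i in range(20)}
        values |= {f"c{i}.t1": dict(zip(samples, rng.normal(5, 1, n)))
                   for i in range(60)}
        m = make_matrix(values, tissues)
        lncs = [k for k in values if k.startswith("l")]
        coding = [k for k in values if k.startswith("c")]
        f1, ci = random_pair_background(m, lncs, coding, n_pairs=500, seed=7,
                                        min_samples=10)
        f2, _ = random_pair_background(m, lncs, coding, n_pairs=500, seed=7,
                                       min_samples=10)
        assert f1 == f2
        assert f1 <= 0.05
        assert ci[0] <= f1 <= ci[1]

    def test_background_requires_enough_pairs(self, two_tissue_matrix):
        with pytest.raises(ValueError):
            random_pair_background(two_tissue_matrix, ["lnc.t1"], ["tgt.t1"],
                                   n_pairs=10)


class TestTissueShift:
    def _table(self, shifted_tissue=None, shift=0.0, n_per_tissue=200, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for genome in ("altai", "denisovan", "vindija"):
            for tissue in ("brain", "liver", "lung", "skin"):
                d = np.abs(rng.normal(0.01, 0.01, n_per_tissue))
                if tissue == shifted_tissue:
                    d = d + shift
                for v in d:
                    rows.append({"tissue": tissue, "genome": genome,
                                 "distance": v})
        return pd.DataFrame(rows)

    def test_identical_distributions_not_significant(self):
        df = self._table()
        summary, tests = tissue_shift_test(df)
        assert not tests.significant.any()
        assert (summary.epoch == "none").all()

    def test_shifted_tissue_flagged_with_adv_epoch(self):
        df = self._table("brain", shift=0.02)
        summary, tests = tissue_shift_test(df)
        brain = summary[summary.tissue == "brain"].iloc[0]
        assert brain.epoch == "ADV"
        others = tests[(tests.tissue != "brain")]
        assert not others.significant.any()

    def test_partial_epoch_labelling(self):
        # shift only the denisovan distances of one tissue
        df = self._table()
        mask = (df.tissue == "brain") & (df.genome == "denisovan")
        df.loc[mask, "distance"] += 0.03
        summary, _ = tissue_shift_test(df)
        assert summary[summary.tissue == "brain"].epoch.iloc[0] == "D"

    def test_small_tissue_samples_skipped(self):
        df = self._table(n_per_tissue=3)
        summary, tests = tissue_shift_test(df)
        assert len(tests) == 0


class TestEqtls:
    def _tables(self):
        eqtl = pd.DataFrame([
            {"snp_id": "s1", "position": 105, "gene": "g1", "tissue": "brain", "es": 0.6},
            {"snp_id": "s2", "position": 205, "gene": "g2", "tissue": "brain", "es": 0.4},
            {"snp_id": "s3", "position": 305, "gene": "g3", "tissue": "liver", "es": -0.8},
            {"snp_id": "s4", "position": 905, "gene": "g4", "tissue": "liver", "es": 0.9},
            {"snp_id": "s5", "position": 405, "gene": "g5", "tissue": "lung", "es": 0.7},
        ])
        maf = pd.DataFrame(
            [{"snp_id": s, "population": p, "maf": m}
             for s, pops in {
                 "s1": [0.05, 0.05, 0.2], "s2": [0.3, 0.3, 0.3],
                 "s3": [0.15, 0.0, 0.0], "s4": [0.3, 0.3, 0.3],
                 "s5": [0.05, 0.05, 0.05],
             }.items()
             for p, m in zip(("CEU", "CHB", "YRI"), pops)])
        dbs = pd.DataFrame([
            {"dbs_id": "d1", "start": 100, "end": 150,
             "present_altai": True, "present_denisovan": True, "present_vindija": True},
            {"dbs_id": "d2", "start": 200, "end": 250,
             "present_altai": True, "present_denisovan": True, "present_vindija": True},
            {"dbs_id": "d3", "start": 300, "end": 350,
             "present_altai": False, "present_denisovan": False,
             "present_vindija": False},
            {"dbs_id": "d4", "start": 400, "end": 450,
             "present_altai": True, "present_denisovan": False,
             "present_vindija": True},
        ])
        return eqtl, maf, dbs

    def test_filters_and_classes(self):
        eqtl, maf, dbs = self._tables()
        out = filter_eqtls(eqtl, maf, dbs).set_index("snp_id")
        # s1: any-population MAF rule qualifies; inside d1 with all archaic
        # counterparts -> conserved
        assert out.loc["s1", "eqtl_class"] == "conserved"
        # s2: |ES| below threshold
        # s4: qualifies but outside every DBS
        # s5: MAF below threshold in every population
        assert set(out.index) == {"s1", "s3"}
        # s3: inside d3 whose counterparts are all missing -> novel
        assert out.loc["s3", "eqtl_class"] == "novel"

    def test_partial_archaic_presence_is_other(self):
        eqtl, maf, dbs = self._tables()
        eqtl.loc[eqtl.snp_id == "s3", "position"] = 405  # move into d4
        out = filter_eqtls(eqtl, maf, dbs).set_index("snp_id")
        assert out.loc["s3", "eqtl_class"] == "other"

    def test_density_compare_planted_in_dbs_only(self):
        rng = np.random.default_rng(3)
        dbs = [(i * 1000, i * 1000 + 100) for i in range(100)]
        promoters = [(i * 1000 + 200, i * 1000 + 900) for i in range(100)]
        eqtls = [s + int(rng.integers(0, 100)) for s, _ in dbs]
        u, p = eqtl_density_compare(dbs, promoters, eqtls)
        assert p < 0.001
        # identical density lists: compare the set with itself
        u, p = eqtl_density_compare(dbs, dbs, eqtls)
        assert p >= 0.5
        # no eQTLs at all
        u, p = eqtl_density_compare(dbs, promoters, [])
        assert p >= 0.5
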