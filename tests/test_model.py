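"""Risk-score assembly, the interaction-lookup vs additive scoring paths,
serialization round-trips and the incremental SNP-addition AUC curve."""

import numpy as np
import pandas as pd
import pytest

import grskit as gk
from grskit.haplotypes import make_label
from grskit.interactions import canonical_pair
from grskit.model import GRSModel, incremental_auc, load_weight_tsv, score_cohort

H1 = make_label("01:01", "05:01")
H2 = make_label("03:02", "03:03")
H3 = make_label("05:01", "02:01")


def _random_model(rng):
    labels = [H1, H2, H3]
    dq = {h: float(rng.normal()) for h in labels}
    inter = {}
    if rng.random() < 0.7:
        a, b = rng.choice(labels, 2, replace=True)
        inter[canonical_pair(a, b)] = float(rng.normal())
    hla = {f"hla{i}": float(rng.normal()) for i in range(rng.integers(0, 4))}
    non = {f"snp{i}": float(rng.normal()) for i in range(rng.integers(0, 4))}
    return GRSModel(dq_additive=dq, dq_interactions=inter, hla_other=hla, non_hla=non)


def _random_individual(rng, model):
    pair = canonical_pair(*rng.choice([H1, H2, H3], 2, replace=True))
    doses = {s: float(rng.integers(0, 3)) for s in model.snp_terms}
    return pair, doses


class TestScoreIndividual:
    def test_empty_model_scores_zero(self):
        r = gk.score_individual(GRSModel(), (H1, H2), {})
        assert r.total == 0.0

    def test_hand_arithmetic_additive(self):
        model = GRSModel(non_hla={"snpX": 0.5})
        r = gk.score_individual(model, None, {"snpX": 2.0})
        assert r.total == pytest.approx(1.0)
        assert r.dq_path == "missing"

    def test_decomposition_identity_over_seeds(self):
        """Components sum exactly to the total for 100 random
        model/individual draws."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            model = _random_model(rng)
            pair, doses = _random_individual(rng, model)
            r = gk.score_individual(model, pair, doses)
            assert r.total == pytest.approx(r.dq + r.hla_other + r.non_hla, abs=1e-9)

    def test_interaction_lookup_replaces_additive(self):
        model = GRSModel(
            dq_additive={H1: 5.0, H2: 5.0},
            dq_interactions={canonical_pair(H1, H2): -1.25},
        )
        r = gk.score_individual(model, (H2, H1), {})
        assert r.dq == -1.25
        assert r.dq_path == "interaction_lookup"

    def test_empty_interaction_table_reduces_to_additive(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            model = _random_model(rng)
            stripped = GRSModel(
                dq_additive=dict(model.dq_additive),
                hla_other=dict(model.hla_other),
                non_hla=dict(model.non_hla),
            )
            pair, doses = _random_individual(rng, model)
            r = gk.score_individual(stripped, pair, doses)
            expected = (
                stripped.dq_additive.get(pair[0], 0.0)
                + stripped.dq_additive.get(pair[1], 0.0)
                + sum(b * doses.get(s, 0.0) for s, b in stripped.snp_terms.items())
            )
            assert r.total == pytest.approx(expected, abs=1e-9)
            assert r.dq_path == "additive"

    def test_missing_snp_scores_zero_and_counted(self):
        model = GRSModel(non_hla={"a": 1.0, "b": 2.0})
        r = gk.score_individual(model, None, {"a": 1.0, "b": np.nan})
        assert r.total == pytest.approx(1.0)
        assert r.n_missing_snps == 1


class TestBuildModel:
    def _res(self, id, or_, p, chrom="1"):
        return gk.AssociationResult(id, float(np.log(or_)), 0.1, p, 0.3, 1000, chrom=chrom)

    def test_beta_is_log_odds_ratio(self):
        model = gk.build_model({}, {}, [], [self._res("rs1", 2.804, 1e-10)])
        assert model.non_hla["rs1"] == pytest.approx(np.log(2.804), rel=1e-12)

    def test_or_one_gives_zero_beta(self):
        model = gk.build_model({}, {}, [self._res("x", 1.0, 1e-6, chrom="6")], [])
        assert model.hla_other["x"] == 0.0

    def test_thresholds_filter(self):
        non = [self._res("pass", 1.5, 1e-9), self._res("fail", 1.5, 1e-7)]
        hla = [self._res("h_pass", 1.5, 4e-4, "6"), self._res("h_fail", 1.5, 5e-4, "6")]
        model = gk.build_model({}, {}, hla, non)
        assert set(model.non_hla) == {"pass"}
        assert set(model.hla_other) == {"h_pass"}

    def test_nonpositive_or_rejected(self):
        bad = gk.AssociationResult("x", np.nan, 0.1, 1e-10, 0.3, 100)
        bad.beta = -np.inf
        with pytest.raises(ValueError):
            gk.build_model({}, {}, [], [bad])


class TestScoreCohort:
    def _setup(self, seed=0):
        snps = [gk.SnpSpec("rs1", 0.3, 0.9), gk.SnpSpec("rs2", 0.4, -0.5)]
        cfg = gk.SimulationConfig(
            n_cases=400, n_controls=400, nonhla_snps=snps, intercept=-0.5, seed=seed
        )
        coh = gk.simulate_cohort(cfg)
        model = GRSModel(non_hla={"rs1": 0.9, "rs2": -0.5})
        return coh, model

    def test_identical_individuals_identical_scores(self):
        coh, model = self._setup()
        dup = pd.DataFrame(
            [[1.0, 2.0], [1.0, 2.0]], index=["a", "b"], columns=["rs1", "rs2"]
        )
        scores = score_cohort(model, [None, None], dup)
        assert scores["total"].iloc[0] == scores["total"].iloc[1]

    def test_unit_dose_increase_adds_beta(self):
        coh, model = self._setup()
        base = pd.DataFrame([[1.0, 1.0]], index=["a"], columns=["rs1", "rs2"])
        bumped = base.copy()
        bumped["rs1"] += 1.0
        s0 = score_cohort(model, [None], base)["total"].iloc[0]
        s1 = score_cohort(model, [None], bumped)["total"].iloc[0]
        assert s1 - s0 == pytest.approx(0.9, abs=1e-12)

    def test_cases_score_above_controls_with_strong_effects(self):
        coh, model = self._setup(seed=5)
        scores = score_cohort(model, [None] * 800, coh.genotypes)
        med_case = scores["total"][coh.phenotype == 1].median()
        med_ctrl = scores["total"][coh.phenotype == 0].median()
        assert med_case > med_ctrl

    def test_snp_order_invariance(self):
        coh, model = self._setup()
        flipped = GRSModel(non_hla={"rs2": -0.5, "rs1": 0.9})
        a = score_cohort(model, [None] * 800, coh.genotypes)["total"]
        b = score_cohort(flipped, [None] * 800, coh.genotypes)["total"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_score_matches_true_linear_predictor_discrimination(self):
        """Scoring a cohort with its own generating weights attains the
        same AUC as the true genetic linear predictor (same ranking)."""
        coh, model = self._setup(seed=9)
        scores = score_cohort(model, [None] * 800, coh.genotypes)
        eta = coh.genotypes.dosages @ np.array([0.9, -0.5])
        auc_score = gk.roc_auc(scores["total"].to_numpy(), coh.phenotype).auc
        auc_eta = gk.roc_auc(eta, coh.phenotype).auc
        assert auc_score == pytest.approx(auc_eta, abs=1e-12)


class TestIncrementalAuc:
    def _fixture(self, seed=0, betas=(0.8, 0.8, 0.8, 0.0, 0.0)):
        snps = [gk.SnpSpec(f"s{i}", 0.3, b) for i, b in enumerate(betas)]
        cfg = gk.SimulationConfig(
            n_cases=800, n_controls=800, nonhla_snps=snps, intercept=-0.6, seed=seed
        )
        coh = gk.simulate_cohort(cfg)
        model = GRSModel(
            non_hla={s.id: (s.beta if s.beta else 1e-6) for s in snps},
            metadata={"p_values": {s.id: 1e-12 * (i + 1) if s.beta else 0.5 + i * 0.01
                                   for i, s in enumerate(snps)}},
        )
        scores = score_cohort(model, [None] * 1600, coh.genotypes)
        return coh, model, scores

    def test_zero_added_snps_equals_dq_auc(self):
        coh, model, scores = self._fixture()
        curve = incremental_auc(model, scores, coh.genotypes, coh.phenotype)
        base_auc = gk.roc_auc(scores["dq"].to_numpy(), coh.phenotype).auc
        assert curve.loc[0, "auc"] == pytest.approx(base_auc)

    def test_zero_beta_snp_leaves_auc_unchanged(self):
        coh, model, scores = self._fixture()
        model.non_hla["s3"] = 0.0
        curve = incremental_auc(model, scores, coh.genotypes, coh.phenotype)
        row = curve[curve["snp"] == "s3"].index[0]
        assert curve.loc[row, "auc"] == pytest.approx(curve.loc[row - 1, "auc"], abs=1e-12)

    def test_plateau_after_informative_snps(self):
        hits = 0
        for seed in range(10):
            coh, model, scores = self._fixture(seed=seed)
            curve = incremental_auc(model, scores, coh.genotypes, coh.phenotype)
            if curve.attrs["plateau"] in (3, 4, 5):
                hits += 1
        assert hits >= 9


class TestSerialization:
    def _model(self):
        return GRSModel(
            dq_additive={H1: 0.5, H2: -0.25},
            dq_interactions={canonical_pair(H1, H2): 1.5},
            hla_other={"hla1": 0.3},
            non_hla={"rs1": -0.7},
            effect_allele={"hla1": "T", "rs1": "A"},
            metadata={"p_values": {"rs1": 1e-9}},
        )

    def test_json_round_trip(self, tmp_path):
        m = self._model()
        path = tmp_path / "model.json"
        gk.save_model(m, str(path))
        assert gk.load_model(str(path)) == m

    def test_unknown_field_preserved_with_warning(self, tmp_path):
        import json

        m = self._model()
        path = tmp_path / "model.json"
        gk.save_model(m, str(path))
        doc = json.loads(path.read_text())
        doc["mystery"] = {"a": 1}
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="mystery"):
            back = gk.load_model(str(path))
        assert back.metadata["extra_fields"]["mystery"] == {"a": 1}

    def test_schema_version_mismatch_rejected(self, tmp_path):
        import json

        path = tmp_path / "model.json"
        gk.save_model(self._model(), str(path))
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            gk.load_model(str(path))

    def test_weight_tsv_reimport(self, tmp_path):
        m = self._model()
        gk.save_model(m, str(tmp_path / "m.json"), weight_tsv=str(tmp_path / "w.tsv"))
        back = load_weight_tsv(str(tmp_path / "w.tsv"))
        assert back.dq_additive == m.dq_additive
        assert back.dq_interactions == m.dq_interactions
        assert back.hla_other == m.hla_other
        assert back.non_hla == m.non_hla
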