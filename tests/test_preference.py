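"""DPO preference pairs, loss/LoRA reference math, synthetic augmentation."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trialdnf.backends import FlakyBackend, OracleBackend, ScriptedBackend
from trialdnf.dnf import serialize
from trialdnf.preference import (
    DPOLossInputs,
    LoRAFactors,
    build_preference_pairs,
    dpo_loss,
    dpo_loss_from_margin,
    export_dpo_dataset,
    generate_synthetic_annotated,
    load_finetune_config,
    lora_apply,
    read_dpo_dataset,
)
from trialdnf.synth import TrialGenConfig, generate_corpus


class TestDpoLoss:
    @pytest.mark.parametrize("beta", [0.01, 0.1, 1.0, 10.0])
    def test_zero_margin_is_ln2(self, beta):
        inputs = DPOLossInputs(-5.0, -5.0, -3.0, -3.0, beta=beta)
        assert inputs.margin == 0.0
        assert dpo_loss(inputs) == pytest.approx(math.log(2), abs=1e-12)

    def test_worked_example(self):
        # beta 0.1, chosen delta 1.5, rejected delta -0.5 -> margin 2.0,
        # loss = ln(1 + e^(-0.2))
        inputs = DPOLossInputs(-1.0, -2.5, -3.0, -2.5, beta=0.1)
        assert inputs.margin == pytest.approx(2.0)
        assert dpo_loss(inputs) == pytest.approx(math.log(1 + math.exp(-0.2)), abs=1e-12)
        assert dpo_loss(inputs) == pytest.approx(0.5981, abs=5e-5)

    def test_limits(self):
        assert dpo_loss_from_margin(50.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        assert dpo_loss_from_margin(-50.0, 1.0) == pytest.approx(50.0, rel=1e-9)

    def test_monotone_decreasing_in_margin(self):
        grid = np.linspace(-10, 10, 100)
        losses = [dpo_loss_from_margin(m, 0.1) for m in grid]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    @given(
        margin=st.floats(-30, 30), beta=st.floats(0.01, 10)
    )
    @settings(max_examples=200, deadline=None)
    def test_beta_scaling_identity(self, margin, beta):
        assert dpo_loss_from_margin(margin, beta) == pytest.approx(
            dpo_loss_from_margin(beta * margin, 1.0), rel=1e-12, abs=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dpo_loss_from_margin(0.0, 0.0)
        with pytest.raises(ValueError):
            DPOLossInputs(0.5, -1.0, -1.0, -1.0)  # positive log-probability


class TestLoraApply:
    def test_zero_b_returns_base(self):
        w0 = np.arange(12.0).reshape(4, 3)
        factors = LoRAFactors(w0, np.zeros((4, 2)), np.ones((2, 3)), alpha=4, r=2)
        assert np.array_equal(lora_apply(factors), w0)

    def test_alpha_equals_rank_is_unscaled(self):
        rng = np.random.default_rng(0)
        w0, b, a = rng.normal(size=(4, 3)), rng.normal(size=(4, 2)), rng.normal(size=(2, 3))
        factors = LoRAFactors(w0, b, a, alpha=2, r=2)
        assert np.allclose(lora_apply(factors), w0 + b @ a, rtol=0, atol=1e-15)

    def test_against_triple_loop_oracle(self):
        # brute-force dense product, 200 random small shapes
        rng = np.random.default_rng(42)
        for _ in range(200):
            d, k = rng.integers(2, 9, size=2)
            r = int(rng.integers(1, min(d, k) + 1))
            alpha = float(rng.uniform(0.5, 8))
            w0 = rng.normal(size=(d, k))
            b = rng.normal(size=(d, r))
            a = rng.normal(size=(r, k))
            expected = w0.copy()
            for i in range(d):
                for j in range(k):
                    acc = 0.0
                    for t in range(r):
                        acc += b[i, t] * a[t, j]
                    expected[i, j] += (alpha / r) * acc
            got = lora_apply(LoRAFactors(w0, b, a, alpha=alpha, r=r))
            assert np.allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            LoRAFactors(np.zeros((4, 3)), np.zeros((4, 2)), np.zeros((3, 3)), alpha=4, r=2)

    def test_rank_bound(self):
        with pytest.raises(ValueError, match="rank"):
            LoRAFactors(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((3, 2)), alpha=1, r=3)


@pytest.fixture(scope="module")
def dpo_corpus():
    return generate_corpus(TrialGenConfig(n_trials=115, seed=21))


class TestBuildPreferencePairs:
    def test_one_pair_per_trial(self, dpo_corpus):
        build = build_preference_pairs(dpo_corpus, OracleBackend(dpo_corpus))
        assert len(build.pairs) == 115 and not build.skipped

    def test_oracle_rejections_flagged_identical(self, dpo_corpus):
        build = build_preference_pairs(dpo_corpus[:3], OracleBackend(dpo_corpus))
        assert all(p.identical for p in build.pairs)

    def test_backend_failure_skips_with_reason(self, dpo_corpus):
        backend = FlakyBackend(
            OracleBackend(dpo_corpus), fail_ids=frozenset({dpo_corpus[0].trial_id})
        )
        build = build_preference_pairs(dpo_corpus, backend)
        assert len(build.pairs) == 114
        assert [t for t, _ in build.skipped] == [dpo_corpus[0].trial_id]

    def test_chosen_is_serialized_gold(self, dpo_corpus):
        build = build_preference_pairs(dpo_corpus[:2], OracleBackend(dpo_corpus))
        for pair, item in zip(build.pairs, dpo_corpus[:2]):
            assert pair.chosen == serialize(item.gold)
            assert item.document.eligibility_text in pair.prompt


class TestExportDpoDataset:
    @pytest.mark.parametrize("n, n_train, n_val", [(115, 92, 23), (195, 156, 39)])
    def test_split_sizes(self, tmp_path, n, n_train, n_val):
        corpus = generate_corpus(TrialGenConfig(n_trials=n, seed=3))
        build = build_preference_pairs(corpus, OracleBackend(corpus))
        export_dpo_dataset(build.pairs, tmp_path, seed=7)
        train = read_dpo_dataset(tmp_path / "train.jsonl")
        val = read_dpo_dataset(tmp_path / "validation.jsonl")
        assert (len(train), len(val)) == (n_train, n_val)

    def test_round_trip_reproduces_pairs(self, tmp_path, dpo_corpus):
        build = build_preference_pairs(dpo_corpus[:10], OracleBackend(dpo_corpus))
        export_dpo_dataset(build.pairs, tmp_path, seed=0)
        back = read_dpo_dataset(tmp_path / "train.jsonl") + read_dpo_dataset(
            tmp_path / "validation.jsonl"
        )
        assert sorted(back, key=lambda p: p.trial_id) == sorted(
            build.pairs, key=lambda p: p.trial_id
        )

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_dpo_dataset([], tmp_path)


def _candidate_block(trial_id, text, gold_json):
    return f"Trial ID: {trial_id}\n{text}\nOutput:\n{gold_json}"


class TestGenerateSyntheticAnnotated:
    def _seed_examples(self):
        return generate_corpus(TrialGenConfig(n_trials=4, seed=8))

    def test_scripted_generator_accepts_valid_candidates(self):
        corpus = generate_corpus(TrialGenConfig(n_trials=80, seed=30))
        blocks = [
            _candidate_block(
                f"GEN{i:03d}", a.document.text, serialize(a.gold)
            )
            for i, a in enumerate(corpus)
        ]
        accepted, rejected = generate_synthetic_annotated(
            ScriptedBackend(blocks), self._seed_examples(), n=80
        )
        assert len(accepted) == 80 and not rejected

    def test_term_absent_from_text_rejected(self):
        block = _candidate_block(
            "GEN001",
            "Inclusion Criteria: adults with solid tumors",
            '{"inclusion_biomarker": [["KRAS G12C"]], "exclusion_biomarker": []}',
        )
        accepted, rejected = generate_synthetic_annotated(
            ScriptedBackend([block]), self._seed_examples(), n=1
        )
        assert not accepted
        assert "KRAS G12C" in rejected[0].reason

    def test_duplicate_id_rejected(self):
        block = _candidate_block(
            "GEN001",
            "Requires ER+ disease",
            '{"inclusion_biomarker": [["ER+"]], "exclusion_biomarker": []}',
        )
        accepted, rejected = generate_synthetic_annotated(
            ScriptedBackend([block, block]), self._seed_examples(), n=2
        )
        assert len(accepted) == 1
        assert "duplicate" in rejected[0].reason

    def test_unparseable_candidate_reported(self):
        accepted, rejected = generate_synthetic_annotated(
            ScriptedBackend(["no structure here"]), self._seed_examples(), n=1
        )
        assert not accepted and rejected[0].reason.startswith("schema")


def test_finetune_config_carries_training_hyperparameters():
    cfg = load_finetune_config()
    assert cfg["lora"]["rank"] == 2 and cfg["lora"]["alpha"] == 4
    assert cfg["dpo"]["beta"] == 0.1
    assert cfg["training"]["max_steps"] == 200
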