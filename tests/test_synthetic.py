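"""Synthetic corpus generator and simulated backend."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from tg263harm import (
    BackendConfig,
    CorruptionConfig,
    ErrorType,
    MockBackend,
    SimulatedBackend,
    SimulatedBackendConfig,
    classify_error,
    deduplicate,
    evaluate,
    generate_corpus,
    rename_batch,
)
from tg263harm.errors import ConfigurationError
from tg263harm.nomenclature import NO_MATCH
from tg263harm.synthetic import apply_operator


class TestGenerateCorpus:
    def test_seed_reproducibility(self, lexicon):
        config = CorruptionConfig(seed=13)
        assert generate_corpus(lexicon, 100, config) == generate_corpus(lexicon, 100, config)

    def test_noop_corpus_is_identity(self, lexicon):
        config = CorruptionConfig(seed=1, operator_rates={"noop": 1.0})
        for record in generate_corpus(lexicon, 200, config):
            assert record.raw_name == record.ground_truth
            assert record.operators == ("noop",)

    def test_translate_plus_abbreviate_reaches_table_style_german_form(self, lexicon):
        entry = lexicon.get("Glnd_Lacrimal_L")
        raw, trace = apply_operator(entry, "abbreviate", "de", lexicon, np.random.default_rng(0))
        assert raw == "Traenendruese li."
        assert trace == ("abbreviate", "lang:de")

    def test_every_record_is_labeled_and_traced(self, lexicon):
        for record in generate_corpus(lexicon, 150, CorruptionConfig(seed=4)):
            assert record.ground_truth in lexicon
            assert record.operators and record.operators[0] in {
                "noop", "translate", "abbreviate", "laterality",
                "plurality", "misspell", "case",
            }

    def test_requested_size_is_met_and_multiplicities_heavy_tailed(self, lexicon):
        records = generate_corpus(lexicon, 600, CorruptionConfig(seed=6))
        assert len(records) == 600
        uniques = deduplicate(records)
        assert sum(u.multiplicity for u in uniques) == 600
        assert max(u.multiplicity for u in uniques) > 1

    def test_unsupported_language_raises(self, lexicon):
        config = CorruptionConfig(seed=0, language_mix={"en": 0.5, "fr": 0.5})
        with pytest.raises((ConfigurationError, KeyError)):
            generate_corpus(lexicon, 50, config)

    def test_operator_frequencies_match_configured_rates(self, lexicon):
        """Chi-square goodness of fit over the primary-operator draws is not
        rejected at alpha = 0.01 for n = 10,000 (one record per draw)."""
        rates = {
            "noop": 0.10, "translate": 0.25, "abbreviate": 0.20,
            "laterality": 0.15, "plurality": 0.10, "misspell": 0.10, "case": 0.10,
        }
        config = CorruptionConfig(seed=42, operator_rates=rates, mult_kind="fixed")
        records = generate_corpus(lexicon, 10_000, config)
        observed = Counter(r.operators[0] for r in records)
        ops = sorted(rates)
        obs = [observed.get(op, 0) for op in ops]
        expected = [rates[op] * len(records) for op in ops]
        result = stats.chisquare(obs, expected)
        assert result.pvalue > 0.01


class TestSimulatedBackend:
    def _items(self, lexicon, n, tag=""):
        names = lexicon.standard_names
        return {f"item{tag}{i}": names[i % len(names)] for i in range(n)}

    def test_perfect_backend_gives_full_accuracy(self, lexicon, det_config):
        from tg263harm import UniqueName

        gt = self._items(lexicon, 50)
        backend = SimulatedBackend(gt, lexicon, SimulatedBackendConfig(error_rate=0.0, seed=1))
        uniques = [UniqueName(k, 1, ground_truth=v) for k, v in gt.items()]
        predictions = rename_batch(uniques, backend, det_config)
        _, report = evaluate(uniques, predictions, lexicon)
        assert report.unique_accuracy == 1.0

    def test_all_no_match_backend(self, lexicon, det_config):
        from tg263harm import UniqueName

        gt = self._items(lexicon, 30)
        backend = SimulatedBackend(
            gt, lexicon,
            SimulatedBackendConfig(error_rate=1.0, category_mix={"no_match": 1.0}, seed=2),
        )
        uniques = [UniqueName(k, 1, ground_truth=v) for k, v in gt.items()]
        predictions = rename_batch(uniques, backend, det_config)
        records, report = evaluate(uniques, predictions, lexicon)
        assert report.unique_accuracy == 0.0
        assert report.error_histogram == {ErrorType.NO_MATCH: len(records)}
        assert all(p.predicted_name == NO_MATCH for p in predictions)

    def test_error_frequency_within_three_binomial_se(self, lexicon, det_config):
        epsilon, n = 0.3, 10_000
        gt = self._items(lexicon, n)
        backend = SimulatedBackend(
            gt, lexicon, SimulatedBackendConfig(error_rate=epsilon, seed=3)
        )
        wrong = sum(1 for name, truth in gt.items() if backend.modal_answer(name)[0] != truth)
        se = math.sqrt(epsilon * (1 - epsilon) / n)
        assert abs(wrong / n - epsilon) <= 3 * se

    def test_injected_category_is_recovered_by_classifier(self, lexicon):
        """Exhaustive generator/classifier consistency: single-category
        backends produce errors the cascade classifies back into that
        category for every lexicon entry."""
        for category in ["laterality_or_locality", "plurality", "no_match",
                         "wrong_oar", "misspelling"]:
            gt = {f"x{i}": name for i, name in enumerate(lexicon.standard_names)}
            backend = SimulatedBackend(
                gt, lexicon,
                SimulatedBackendConfig(error_rate=1.0, category_mix={category: 1.0}, seed=9),
            )
            for name, truth in gt.items():
                label, _ = backend.modal_answer(name)
                assert classify_error(label, truth, lexicon).value == category

    def test_sampling_variability_only_affects_wrong_items(self, lexicon):
        gt = self._items(lexicon, 40)
        backend = SimulatedBackend(
            gt, lexicon,
            SimulatedBackendConfig(
                error_rate=0.5, variability_wrong=0.8, variability_correct=0.0, seed=5
            ),
        )
        sample_config = BackendConfig(temperature=1.0, top_p=0.95, seed=5)
        for name, truth in gt.items():
            modal, _ = backend.modal_answer(name)
            labels = [backend.predict(name, sample_config).predicted_name for _ in range(10)]
            if modal == truth:
                assert labels == [modal] * 10

    def test_seeded_determinism_of_sampling(self, lexicon):
        gt = self._items(lexicon, 5)
        config = SimulatedBackendConfig(error_rate=0.5, seed=7)
        sample_config = BackendConfig(temperature=1.0, seed=7)
        runs = []
        for _ in range(2):
            backend = SimulatedBackend(gt, lexicon, config)
            runs.append(
                [backend.predict(n, sample_config).predicted_name for n in gt for _ in range(5)]
            )
        assert runs[0] == runs[1]


def test_mock_accuracy_degrades_smoothly_with_misspelling_rate(lexicon, det_config):
    """The corruption operators form a difficulty dial for the mock backend:
    heavier misspelling lowers accuracy but clean operators stay invertible."""
    accuracies = []
    for misspell_rate in (0.0, 1.0):
        rates = {"noop": 1.0 - misspell_rate, "misspell": misspell_rate}
        corpus = generate_corpus(
            lexicon, 300, CorruptionConfig(seed=21, operator_rates=rates, mult_kind="fixed")
        )
        uniques = deduplicate(corpus)
        backend = MockBackend(lexicon)
        predictions = rename_batch(uniques, backend, det_config)
        _, report = evaluate(uniques, predictions, lexicon)
        accuracies.append(report.unique_accuracy)
    assert accuracies[0] == 1.0
    assert accuracies[1] < accuracies[0]
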