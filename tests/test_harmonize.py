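"""Prompt construction, reply-grammar parsing, and the mock backend."""

import pytest

from tg263harm import (
    BackendConfig,
    Confidence,
    MockBackend,
    RemoteChatBackend,
    build_prompt,
    parse_response,
    rename_batch,
    render_response,
)
from tg263harm.errors import BackendError, TemplateError
from tg263harm.nomenclature import NO_MATCH


class TestBuildPrompt:
    def test_contains_input_once_and_every_standard_name(self, lexicon):
        spec, text = build_prompt("Niere bds", lexicon)
        assert text.count("Niere bds") == 1
        assert all(name in text for name in lexicon.standard_names)
        assert spec.input_name == "Niere bds"

    def test_five_parts_appear_in_order(self, lexicon):
        spec, text = build_prompt("Herz", lexicon)
        positions = [
            text.index(spec.instructions),
            text.index(spec.language_rules),
            text.index(spec.output_format_rules),
            text.index("Examples:"),
            text.index("TG-263 structure names:"),
        ]
        assert positions == sorted(positions)

    def test_byte_identical_for_identical_inputs(self, lexicon):
        _, first = build_prompt("Herz", lexicon)
        _, second = build_prompt("Herz", lexicon)
        assert first == second

    def test_missing_placeholder_is_named(self, lexicon):
        template = "{instructions} {language_rules} {output_format_rules} {fewshot_examples} {input_name}"
        with pytest.raises(TemplateError, match="tg263_names"):
            build_prompt("Herz", lexicon, template=template)


class TestParseResponse:
    @pytest.mark.parametrize(
        "raw, name, confidence",
        [
            ("name: No match | confidence: high", NO_MATCH, Confidence.HIGH),
            ("name: Kidneys | confidence: high", "Kidneys", Confidence.HIGH),
            ("Name: SpinalCord | Confidence: LOW", "SpinalCord", Confidence.LOW),
            ("name: Heart", "Heart", Confidence.MISSING),
        ],
    )
    def test_grammar_examples(self, raw, name, confidence):
        prediction = parse_response(raw)
        assert prediction.predicted_name == name
        assert prediction.confidence is confidence
        assert not prediction.parse_failed

    def test_unstructured_reply_flags_parse_failure(self):
        prediction = parse_response("I think it is a kidney")
        assert prediction.parse_failed
        assert prediction.confidence is Confidence.MISSING

    def test_chain_of_thought_preamble_is_skipped(self):
        raw = (
            "Let me think. The name 'Niere' is German for kidney.\n"
            "A preliminary guess: name: Kidney_L | confidence: low\n"
            "But 'bds' means bilateral, so:\n"
            "name: Kidneys | confidence: high"
        )
        prediction = parse_response(raw)
        assert prediction.predicted_name == "Kidneys"
        assert prediction.confidence is Confidence.HIGH

    @pytest.mark.parametrize("name", ["Kidneys", "Glnd_Lacrimal_L", NO_MATCH])
    @pytest.mark.parametrize("confidence", [Confidence.LOW, Confidence.MEDIUM, Confidence.HIGH])
    def test_roundtrip_through_reply_grammar(self, name, confidence):
        prediction = parse_response(render_response(name, confidence))
        assert prediction.predicted_name == name
        assert prediction.confidence is confidence


class TestMockBackend:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Niere bds", "Kidneys"),
            ("SpinalCord", "SpinalCord"),
            ("zzzz", NO_MATCH),
            ("Traenendruese li.", "Glnd_Lacrimal_L"),
            ("CervMyelum", "SpinalCord_Cerv"),
            ("nier links", "Kidney_L"),
            ("long re", "Lung_R"),
            ("slokdarm", "Esophagus"),
        ],
    )
    def test_multilingual_examples(self, mock_backend, det_config, raw, expected):
        assert mock_backend.predict(raw, det_config).predicted_name == expected

    def test_identity_on_every_standard_name_with_high_confidence(
        self, mock_backend, det_config, lexicon
    ):
        for name in lexicon.standard_names:
            prediction = mock_backend.predict(name, det_config)
            assert prediction.predicted_name == name
            assert prediction.confidence is Confidence.HIGH

    def test_deterministic_at_temperature_zero(self, lexicon, det_config):
        names = ["Niere bds", "Traenendruese li.", "qqq", "hersenstam"]
        runs = []
        for _ in range(2):
            backend = MockBackend(lexicon)
            runs.append(
                [
                    (p.predicted_name, p.confidence)
                    for p in rename_batch(names, backend, det_config)
                ]
            )
        assert runs[0] == runs[1]

    def test_small_top_p_recovers_the_deterministic_output(self, lexicon, det_config):
        names = ["Niere li", "lange lever", "oog links"]
        backend_det = MockBackend(lexicon)
        backend_sampled = MockBackend(lexicon)
        config = BackendConfig(temperature=1.0, top_p=1e-9, seed=5)
        for name in names:
            det = backend_det.predict(name, det_config).predicted_name
            sampled = backend_sampled.predict(name, config).predicted_name
            assert sampled == det

    def test_sampling_is_seed_reproducible(self, lexicon):
        config = BackendConfig(temperature=1.0, top_p=0.95, seed=11)
        samples = []
        for _ in range(2):
            backend = MockBackend(lexicon)
            samples.append(
                [backend.predict("nier", config).predicted_name for _ in range(10)]
            )
        assert samples[0] == samples[1]


class _FailingBackend:
    backend_id = "failing"

    def predict(self, name, config):
        raise BackendError("endpoint down")


class TestRenameBatch:
    def test_empty_input(self, mock_backend, det_config):
        assert rename_batch([], mock_backend, det_config) == []

    def test_order_preserving(self, mock_backend, det_config):
        names = ["Herz", "Leber", "Milz"]
        predictions = rename_batch(names, mock_backend, det_config)
        assert [p.predicted_name for p in predictions] == ["Heart", "Liver", "Spleen"]

    def test_backend_failures_are_recorded_not_fatal(self, det_config):
        predictions = rename_batch(["Herz", "Leber"], _FailingBackend(), det_config)
        assert len(predictions) == 2
        assert all(p.error and p.parse_failed for p in predictions)


class _FakeResponse:
    def __init__(self, content):
        self._content = content

    def raise_for_status(self):
        pass

    def json(self):
        return {"choices": [{"message": {"content": self._content}}]}


def test_remote_backend_posts_sampling_parameters_verbatim(lexicon):
    seen = {}

    def transport(url, json=None, timeout=None):
        seen.update(json)
        return _FakeResponse("name: Heart | confidence: high")

    backend = RemoteChatBackend(lexicon, transport=transport)
    config = BackendConfig(temperature=0.7, top_p=0.9, endpoint="http://x/v1/chat")
    prediction = backend.predict("Herz", config)
    assert prediction.predicted_name == "Heart"
    assert seen["temperature"] == 0.7 and seen["top_p"] == 0.9
    assert "Herz" in seen["messages"][0]["content"]
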