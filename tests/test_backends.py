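"""Prompt rendering, reply parsing, the keyword-rule mock, and the cached
remote backend."""

import json

import pytest

from stagescore import (
    BackendConfig,
    DEFAULT_PROMPTS,
    LLMBackend,
    MockBackend,
    PromptSet,
    mock_classify,
    parse_category,
    render_prompt,
)
from stagescore.errors import (
    BackendUnavailableError,
    InvalidInputError,
    InvalidParameterError,
    UnparsableResponseError,
)


class TestRenderPrompt:
    def test_templates_carry_the_protocol_instructions(self):
        assert "Classify the following sentence as (1) Concrete, (2) Subtle, or (3) MetAware" \
            in render_prompt(1, "The car is red")
        assert "Classify the following sentence as (1) Individual, (2) Collective" \
            in render_prompt(2, "x")
        assert "Classify the following sentence as (1) Passive, (2) Active" \
            in render_prompt(3, "x")

    def test_sentence_is_inserted_once(self):
        rendered = render_prompt(1, "A perfectly unique sentence")
        assert rendered.count("A perfectly unique sentence") == 1
        assert "{sentence}" not in rendered

    @pytest.mark.parametrize("bad", ["", "   ", None])
    def test_empty_sentence_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            render_prompt(1, bad)

    def test_custom_template_requires_exactly_one_slot(self):
        with pytest.raises(InvalidParameterError):
            PromptSet(q1_prompt="no slot", q2_prompt="{sentence}", q3_prompt="{sentence}")
        with pytest.raises(InvalidParameterError):
            PromptSet(q1_prompt="{sentence} and {sentence}",
                      q2_prompt="{sentence}", q3_prompt="{sentence}")


class TestParseCategory:
    @pytest.mark.parametrize("raw, qid, expected", [
        ("(2) Subtle", 1, 2),
        ("2", 1, 2),
        ("Answer: 3.", 1, 3),
        ("MetAware", 1, 3),
        ("the sentence is clearly subtle", 1, 2),
        ("(1) Passive", 3, 1),
        ("ACTIVE", 3, 2),
        ("Collective", 2, 2),
    ])
    def test_codes_and_names(self, raw, qid, expected):
        assert parse_category(raw, qid) == expected

    @pytest.mark.parametrize("raw, qid", [
        ("maybe", 1),          # no category at all
        ("7", 2),              # digit out of range
        ("(3) MetAware", 2),   # out of range for a binary question
        ("", 1),
    ])
    def test_unparsable_replies_raise(self, raw, qid):
        with pytest.raises(UnparsableResponseError):
            parse_category(raw, qid)


# every example sentence the prompts themselves list, with its category
PROMPT_EXAMPLES = [
    # Q1 Concrete
    ("The car is red", 1, 1),
    ("I heard a melody", 1, 1),
    ("She followed the rules", 1, 1),
    # Q1 Subtle
    ("I strive to find balance in my life", 1, 2),
    ("Values guide our decisions", 1, 2),
    ("The environment is crucial for peace", 1, 2),
    # Q1 MetAware
    ("Time is a construct shaping experience", 1, 3),
    ("Examining awareness reveals hidden biases", 1, 3),
    ("Reality is shaped by our perceptions", 1, 3),
    # Q2 Individual
    ("I went for a walk", 2, 1),
    ("The cat is sleeping", 2, 1),
    ("She wrote an essay", 2, 1),
    ("the person listens", 2, 1),
    # Q2 Collective
    ("The team won the game", 2, 2),
    ("Families gathered for the reunion", 2, 2),
    ("The town’s economy is growing", 2, 2),
    ("Ecosystems rely on biodiversity", 2, 2),
    ("Cultural narratives shape our understanding of history", 2, 2),
    ("Religions provide moral frameworks", 2, 2),
    ("Imagining another’s pain can foster empathy", 2, 2),
    ("Helping others strengthens community bonds", 2, 2),
    ("Global warming affects ecosystems worldwide", 2, 2),
    ("Family dynamics influence individual behavior", 2, 2),
]


class TestMockBackend:
    @pytest.mark.parametrize("sentence, qid, expected", PROMPT_EXAMPLES)
    def test_prompt_examples_classify_as_the_prompt_says(self, sentence, qid, expected):
        assert mock_classify(sentence, qid) == expected

    def test_pure_function(self):
        for _ in range(3):
            assert mock_classify("The team builds an awareness of hidden assumptions", 1) == 3
            assert mock_classify("The team builds an awareness of hidden assumptions", 2) == 2
            assert mock_classify("The team builds an awareness of hidden assumptions", 3) == 2

    def test_defaults_without_markers(self):
        # no tier/collective/agentive markers at all
        assert mock_classify("The stone lay on the path", 1) == 1
        assert mock_classify("The stone lay on the path", 2) == 1
        assert mock_classify("The stone lay on the path", 3) == 1

    def test_empty_sentence_rejected(self):
        with pytest.raises(InvalidInputError):
            mock_classify("", 1)

    def test_backend_object_delegates(self):
        assert MockBackend().classify("The car is red", 1) == 1


class CountingTransport:
    def __init__(self, replies):
        self.replies = list(replies)
        self.calls = 0

    def __call__(self, prompt):
        self.calls += 1
        return self.replies[(self.calls - 1) % len(self.replies)]


class TestLLMBackend:
    def test_classify_parses_and_caches(self, tmp_path):
        cache = tmp_path / "cache.jsonl"
        transport = CountingTransport(["(2) Subtle"])
        backend = LLMBackend(
            config=BackendConfig(backend="remote", cache_path=str(cache)),
            transport=transport)
        assert backend.classify("Values guide our decisions", 1) == 2
        assert transport.calls == 1
        # in-memory cache short-circuits
        assert backend.classify("Values guide our decisions", 1) == 2
        assert transport.calls == 1
        rec = json.loads(cache.read_text().splitlines()[0])
        assert rec["code"] == 2 and rec["question"] == 1
        assert rec["sentence"] == "Values guide our decisions"

    def test_populated_cache_needs_no_network(self, tmp_path):
        cache = tmp_path / "cache.jsonl"
        warm = LLMBackend(config=BackendConfig(backend="remote", cache_path=str(cache)),
                          transport=CountingTransport(["(1) Passive"]))
        assert warm.classify("x y z", 3) == 1
        cold_transport = CountingTransport(["never used"])
        cold = LLMBackend(config=BackendConfig(backend="remote", cache_path=str(cache)),
                          transport=cold_transport)
        assert cold.classify("x y z", 3) == 1
        assert cold_transport.calls == 0

    def test_no_transport_and_no_cache_raises(self):
        backend = LLMBackend(config=BackendConfig(backend="remote"))
        with pytest.raises(BackendUnavailableError):
            backend.classify("anything", 1)

    def test_unparsable_replies_retry_then_raise(self):
        transport = CountingTransport(["gibberish"])
        backend = LLMBackend(config=BackendConfig(backend="remote", retries=2),
                             transport=transport)
        with pytest.raises(UnparsableResponseError):
            backend.classify("anything", 2)
        assert transport.calls == 3  # initial try + 2 retries

    def test_retry_recovers_from_one_bad_reply(self):
        transport = CountingTransport(["??", "(2) Active"])
        backend = LLMBackend(config=BackendConfig(backend="remote", retries=1),
                             transport=transport)
        assert backend.classify("anything", 3) == 2

    def test_transport_failure_is_backend_unavailable(self):
        def broken(prompt):
            raise ConnectionError("boom")
        backend = LLMBackend(config=BackendConfig(backend="remote"), transport=broken)
        with pytest.raises(BackendUnavailableError):
            backend.classify("anything", 1)


class TestBackendConfig:
    def test_defaults_are_deterministic(self):
        cfg = BackendConfig()
        assert cfg.temperature == 0.0
        assert 0 < cfg.top_p <= 1

    @pytest.mark.parametrize("kwargs", [
        {"backend": "other"}, {"temperature": -1}, {"top_p": 0}, {"top_p": 1.5},
        {"retries": -1},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            BackendConfig(**kwargs)

    def test_from_file_roundtrip(self, tmp_path):
        path = tmp_path / "backend.cfg"
        path.write_text(
            "backend = remote\nmodel = test-model\ntemperature = 0\n"
            "top_p = 0.5  # near-greedy\nmax_tokens = 8\nretries = 1\n")
        cfg = BackendConfig.from_file(path)
        assert cfg.backend == "remote" and cfg.model == "test-model"
        assert cfg.top_p == 0.5 and cfg.max_tokens == 8 and cfg.retries == 1
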