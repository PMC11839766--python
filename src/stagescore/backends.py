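"""Classifier backends: prompt templates, reply parsing, and two
interchangeable classifiers behind one contract.

A backend is anything with a ``classify(sentence, question_id) -> int``
method returning the category code for one of the three STAGES questions.
Two implementations ship here:

* :class:`MockBackend` — a deterministic keyword-rule classifier whose rules
  are transcribed from the classification prompts' own criteria and example
  lists.  It makes the whole pipeline testable offline and is the ground
  truth for the synthetic sentence generator.
* :class:`LLMBackend` — a remote-model client over a pluggable transport
  callable (``prompt -> reply text``), with retries, reply parsing, and an
  append-only JSON-lines cache keyed by (model, question, sentence,
  temperature, top_p).  With a populated cache a scoring run performs zero
  network calls and is bit-reproducible; the cache, not the remote API, is
  the reproducibility boundary.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from ._prompt_text import Q1_PROMPT_BODY, Q2_PROMPT_BODY, Q3_PROMPT_BODY
from .errors import (
    BackendUnavailableError,
    InvalidInputError,
    InvalidParameterError,
    UnparsableResponseError,
)
from .stages_model import QUESTION_RANGES

logger = logging.getLogger(__name__)

_SLOT = "{sentence}"


@dataclass(frozen=True)
class PromptSet:
    """The three question templates; each contains exactly one ``{sentence}``
    insertion slot.  Defaults reproduce the protocol's final prompts."""

    q1_prompt: str
    q2_prompt: str
    q3_prompt: str

    def __post_init__(self) -> None:
        for qid, tpl in ((1, self.q1_prompt), (2, self.q2_prompt), (3, self.q3_prompt)):
            if tpl.count(_SLOT) != 1:
                raise InvalidParameterError(
                    f"Q{qid} template must contain exactly one {_SLOT!r} slot"
                )

    def template(self, question_id: int) -> str:
        try:
            return {1: self.q1_prompt, 2: self.q2_prompt, 3: self.q3_prompt}[question_id]
        except KeyError:
            raise InvalidParameterError(f"question_id must be 1, 2 or 3, got {question_id!r}")


DEFAULT_PROMPTS = PromptSet(
    q1_prompt=Q1_PROMPT_BODY + "\n\nSentence: {sentence}",
    q2_prompt=Q2_PROMPT_BODY + "\n\nSentence: {sentence}",
    q3_prompt=Q3_PROMPT_BODY + "\n\nSentence: {sentence}",
)


def render_prompt(question_id: int, sentence: str, prompts: PromptSet = DEFAULT_PROMPTS) -> str:
    """Insert ``sentence`` into the question's template."""
    if not isinstance(sentence, str) or not sentence.strip():
        raise InvalidInputError("sentence must be a non-empty string")
    return prompts.template(question_id).replace(_SLOT, sentence)


#: Category names per question, name -> code (matched case-insensitively).
CATEGORY_NAMES: dict[int, dict[str, int]] = {
    1: {"concrete": 1, "subtle": 2, "metaware": 3},
    2: {"individual": 1, "collective": 2},
    3: {"passive": 1, "active": 2},
}


def parse_category(raw: str, question_id: int) -> int:
    """Extract the category code from a backend reply.

    The first digit found in the reply wins if it lies in the question's
    valid range (covers '(2) Subtle', '2', 'Answer: 2.').  If the reply
    carries no digit, a case-insensitive category-name match is attempted.
    """
    if question_id not in QUESTION_RANGES:
        raise InvalidParameterError(f"question_id must be 1, 2 or 3, got {question_id!r}")
    lo, hi = QUESTION_RANGES[question_id]
    m = re.search(r"\d", raw)
    if m:
        code = int(m.group())
        if lo <= code <= hi:
            return code
        raise UnparsableResponseError(
            f"digit {code} out of range [{lo}, {hi}] for Q{question_id} in reply {raw!r}"
        )
    lowered = raw.lower()
    hits = [(lowered.find(name), code) for name, code in CATEGORY_NAMES[question_id].items()
            if name in lowered]
    if hits:
        return min(hits)[1]
    raise UnparsableResponseError(f"no category code or name for Q{question_id} in reply {raw!r}")


# ---------------------------------------------------------------------------
# Mock backend: keyword rules transcribed from the prompts' own criteria.
# ---------------------------------------------------------------------------

#: MetAware markers — awareness / construct / reality / perception terms.
METAWARE_MARKERS = frozenset({
    "aware", "awareness", "metaware", "consciousness", "construct", "constructs",
    "reality", "realities", "perception", "perceptions", "assumption", "assumptions",
    "bias", "biases", "transcendent", "transcend", "paradigm", "paradigms",
})

#: Subtle markers — values / abstract / reflective / uncertainty terms.
SUBTLE_MARKERS = frozenset({
    "value", "values", "balance", "strive", "strives", "striving", "peace",
    "crucial", "abstract", "belief", "beliefs", "moral", "morals", "ethics",
    "ethical", "future", "possibility", "possibilities", "uncertainty",
    "uncertain", "meaning", "ideal", "ideals", "principle", "principles",
    "wisdom", "development", "insight", "insights", "hope", "hopes",
    "potential", "theory", "theoretical", "reflection", "purpose", "growth",
    "harmony", "freedom",
})

#: Collective words, seeded from the Q2 prompt's own list and examples.
COLLECTIVE_MARKERS = frozenset({
    "team", "teams", "group", "groups", "bus", "train", "family", "families",
    "community", "communities", "people", "peoples", "others", "collective",
    "collectivity", "peers", "world", "they", "them", "their", "humanity",
    "organization", "organizations", "parties", "society", "societies",
    "social", "societal", "cultural", "culture", "cultures", "religion",
    "religions", "ecosystem", "ecosystems", "economy", "town", "nation",
    "nations", "we", "us", "our", "ours", "everyone", "together", "another",
    "empathy", "global", "crowd", "public", "population",
})

#: Agentive main verbs — the subject initiates action.
ACTIVE_MARKERS = frozenset({
    "build", "builds", "built", "create", "creates", "created", "lead",
    "leads", "led", "initiate", "initiates", "drive", "drives", "shape",
    "shapes", "shaped", "make", "makes", "made", "guide", "guides", "win",
    "wins", "won", "act", "acts", "choose", "chooses", "chose", "decide",
    "decides", "pursue", "pursues", "transform", "transforms", "organize",
    "organizes", "strengthen", "strengthens", "help", "helps", "write",
    "writes", "wrote", "foster", "fosters",
})

_WORD_RE = re.compile(r"[a-z]+")


def _tokens(sentence: str) -> list[str]:
    return _WORD_RE.findall(sentence.lower())


def mock_classify(sentence: str, question_id: int) -> int:
    """Deterministic keyword-rule classification of one question.

    Q1 applies marker precedence MetAware > Subtle > Concrete (mirroring the
    prompt's 'identify the primary focus'); Q2 fires on the prompt's
    collective word list, defaulting to Individual; Q3 fires on an agentive
    main-verb list, defaulting to Passive.  Pure function of its arguments.
    """
    if not isinstance(sentence, str) or not sentence.strip():
        raise InvalidInputError("sentence must be a non-empty string")
    if question_id not in QUESTION_RANGES:
        raise InvalidParameterError(f"question_id must be 1, 2 or 3, got {question_id!r}")
    words = set(_tokens(sentence))
    if question_id == 1:
        if words & METAWARE_MARKERS:
            return 3
        if words & SUBTLE_MARKERS:
            return 2
        return 1
    if question_id == 2:
        return 2 if words & COLLECTIVE_MARKERS else 1
    return 2 if words & ACTIVE_MARKERS else 1


class MockBackend:
    """Deterministic offline classifier; see :func:`mock_classify`."""

    def classify(self, sentence: str, question_id: int) -> int:
        return mock_classify(sentence, question_id)


# ---------------------------------------------------------------------------
# Remote backend with cache.
# ---------------------------------------------------------------------------


@dataclass
class BackendConfig:
    """Configuration for a classifier backend.

    temperature defaults to 0 and top_p to a near-greedy 0.01 so the remote
    model is as deterministic as its API allows; max_tokens is small because
    only a category code is expected back.
    """

    backend: str = "mock"
    model: str = "gpt-4o"
    temperature: float = 0.0
    top_p: float = 0.01
    max_tokens: int = 16
    retries: int = 2
    cache_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.backend not in ("mock", "remote"):
            raise InvalidParameterError(f"backend must be 'mock' or 'remote', got {self.backend!r}")
        if self.temperature < 0:
            raise InvalidParameterError("temperature must be >= 0")
        if not 0 < self.top_p <= 1:
            raise InvalidParameterError("top_p must lie in (0, 1]")
        if self.retries < 0:
            raise InvalidParameterError("retries must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "BackendConfig":
        """Read a ``key = value`` configuration file (one pair per line,
        '#' comments allowed)."""
        kwargs: dict = {}
        casts = {"temperature": float, "top_p": float, "max_tokens": int, "retries": int}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InvalidParameterError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            kwargs[key] = casts.get(key, str)(value)
        return cls(**kwargs)


@dataclass
class LLMBackend:
    """Remote-model classifier over a pluggable transport.

    ``transport`` is any callable mapping a rendered prompt to the model's
    reply text (an API client wrapper, a recorded stub, ...).  Every
    successful exchange is appended to the JSON-lines cache; cache hits
    short-circuit the transport entirely, so a populated cache makes runs
    reproducible without network access.
    """

    config: BackendConfig = field(default_factory=lambda: BackendConfig(backend="remote"))
    transport: Optional[Callable[[str], str]] = None
    prompts: PromptSet = DEFAULT_PROMPTS

    def __post_init__(self) -> None:
        self._cache: dict[tuple, int] = {}
        if self.config.cache_path and Path(self.config.cache_path).exists():
            with open(self.config.cache_path, encoding="utf-8") as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    rec = json.loads(line)
                    self._cache[self._key(rec["sentence"], rec["question"])] = rec["code"]
            logger.info("loaded %d cached classifications from %s",
                        len(self._cache), self.config.cache_path)

    def _key(self, sentence: str, question_id: int) -> tuple:
        cfg = self.config
        return (cfg.model, question_id, sentence, cfg.temperature, cfg.top_p)

    def classify(self, sentence: str, question_id: int) -> int:
        key = self._key(sentence, question_id)
        if key in self._cache:
            return self._cache[key]
        if self.transport is None:
            raise BackendUnavailableError(
                "no transport configured and no cache entry for this request"
            )
        prompt = render_prompt(question_id, sentence, self.prompts)
        last_error: Exception | None = None
        for attempt in range(self.config.retries + 1):
            try:
                reply = self.transport(prompt)
                code = parse_category(reply, question_id)
            except UnparsableResponseError as exc:
                last_error = exc
                logger.warning("unparsable reply for Q%d (attempt %d/%d): %s",
                               question_id, attempt + 1, self.config.retries + 1, exc)
                continue
            except Exception as exc:  # transport failure
                raise BackendUnavailableError(f"transport failed: {exc}") from exc
            self._record(sentence, question_id, reply, code)
            self._cache[key] = code
            return code
        raise UnparsableResponseError(
            f"no parsable reply for Q{question_id} after {self.config.retries + 1} attempts"
        ) from last_error

    def _record(self, sentence: str, question_id: int, reply: str, code: int) -> None:
        if not self.config.cache_path:
            return
        rec = {
            "model": self.config.model,
            "question": question_id,
            "sentence": sentence,
            "temperature": self.config.temperature,
            "top_p": self.config.top_p,
            "reply": reply,
            "code": code,
            "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        }
        with open(self.config.cache_path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def make_backend(config: BackendConfig,
                 transport: Optional[Callable[[str], str]] = None,
                 prompts: PromptSet = DEFAULT_PROMPTS):
    """Instantiate the backend named by ``config.backend``."""
    if config.backend == "mock":
        return MockBackend()
    return LLMBackend(config=config, transport=transport, prompts=prompts)
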