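"""Rule-based dialog engine: intents, contexts, slot filling, events.

The engine mimics the constructs of commercial conversational platforms —
intents with training phrases, a LIFO stack of lifespan-limited contexts,
mandatory-parameter slot filling, fulfillment dispatch to in-process
services, and named events that trigger intents without user input — but
the matching logic is deliberately transparent: an utterance is tagged with
ontology entities and intents are scored by shared entity types (with a
token-overlap fallback for entity-free phrasings like "I have several
issues"), never by an opaque text classifier.
"""

from __future__ import annotations

import re
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import yaml

from .ontology import Ontology

DEFAULT_CONTEXT_LIFESPAN = 5
#: Cue words that promote an issue in the handling queue ("... but would
#: prefer a job first", "I am mostly concerned about food").
PRIORITY_CUES = ("prefer", "first", "mostly concerned", "most concerned", "priority")
#: Characters after a cue within which a mention counts as prioritized.
PRIORITY_WINDOW = 40

FALLBACK_RESPONSE = "I'm sorry, I didn't catch that. Could you rephrase?"
SERVICE_ERROR_RESPONSE = (
    "I'm having trouble reaching that service right now; let's continue."
)


class DialogConfigurationError(Exception):
    """The intent registry or service wiring is invalid."""


class EventAmbiguityError(DialogConfigurationError):
    """An event is registered on more than one intent."""


@dataclass
class SlotSpec:
    """A required parameter an intent must collect before fulfillment."""

    name: str
    entity_type: str
    prompt: str
    order: int = 0
    mandatory: bool = True


@dataclass
class Intent:
    name: str
    parent: Optional[str] = None
    training_phrases: list[str] = field(default_factory=list)
    required_params: list[SlotSpec] = field(default_factory=list)
    input_contexts: list[str] = field(default_factory=list)
    output_contexts: list[tuple[str, int]] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    fulfillment: Optional[str] = None

    @property
    def context_name(self) -> str:
        return f"{self.name}_ctx"


@dataclass
class Context:
    """An activation record on the conversation stack."""

    name: str
    lifespan: int = DEFAULT_CONTEXT_LIFESPAN
    params: dict = field(default_factory=dict)


@dataclass
class Turn:
    timestamp: float
    utterance: str
    intent: Optional[str]
    response: str
    latency: float
    mismatch: bool = False
    error: bool = False


@dataclass
class ConversationState:
    session_id: str
    stack: list[Context] = field(default_factory=list)
    collected_params: dict[str, tuple[str, str]] = field(default_factory=dict)
    pending_slots: list[SlotSpec] = field(default_factory=list)
    active_intent: Optional[str] = None
    history: list[Turn] = field(default_factory=list)
    issue_queue: list[str] = field(default_factory=list)

    def active_context_names(self) -> set[str]:
        return {c.name for c in self.stack}

    def push_context(self, name: str, lifespan: int = DEFAULT_CONTEXT_LIFESPAN) -> None:
        """Push a context; re-activation resets lifespan and moves it to top."""
        self.stack = [c for c in self.stack if c.name != name]
        self.stack.append(Context(name=name, lifespan=lifespan))

    def drop_context(self, name: str) -> None:
        self.stack = [c for c in self.stack if c.name != name]

    def tick_contexts(self) -> None:
        for c in self.stack:
            c.lifespan -= 1
        self.stack = [c for c in self.stack if c.lifespan > 0]


@dataclass
class AgentResponse:
    text: str
    intent: Optional[str] = None
    payload: Optional[dict] = None
    event: Optional[str] = None
    mismatch: bool = False
    error: bool = False


@dataclass
class FulfillmentRequest:
    intent: str
    params: dict[str, tuple[str, str]]
    action: Optional[str] = None


@dataclass
class FulfillmentResponse:
    text: str
    event: Optional[str] = None
    payload: Optional[dict] = None


Services = Mapping[str, Callable[[FulfillmentRequest], FulfillmentResponse]]


class IntentRegistry:
    """Validated collection of intents.

    Structural invariant checked at load: a follow-up intent's parent
    default output context is among the child's input contexts, so parent
    activation is what makes the child matchable.
    """

    def __init__(self, intents: Sequence[Intent], autowire: bool = True):
        names = [i.name for i in intents]
        if len(names) != len(set(names)):
            raise DialogConfigurationError("duplicate intent names")
        self._by_name = {i.name: i for i in intents}
        for intent in intents:
            if intent.parent is not None and intent.parent not in self._by_name:
                raise DialogConfigurationError(
                    f"intent {intent.name!r}: unknown parent {intent.parent!r}"
                )
            pnames = [p.name for p in intent.required_params]
            if len(pnames) != len(set(pnames)):
                raise DialogConfigurationError(
                    f"intent {intent.name!r}: duplicate required param names"
                )
        for intent in intents:
            parent = self._by_name.get(intent.parent) if intent.parent else None
            if parent is None:
                continue
            if autowire:
                if not intent.input_contexts:
                    intent.input_contexts = [parent.context_name]
                if parent.context_name not in {n for n, _ in parent.output_contexts}:
                    parent.output_contexts.append(
                        (parent.context_name, DEFAULT_CONTEXT_LIFESPAN)
                    )
            if parent.context_name not in intent.input_contexts or parent.context_name not in {
                n for n, _ in parent.output_contexts
            }:
                raise DialogConfigurationError(
                    f"intent {intent.name!r}: parent output context must be an "
                    "input context of the follow-up intent"
                )
        self._profile_cache: dict[str, frozenset[str]] = {}

    def __iter__(self):
        return iter(self._by_name.values())

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Intent:
        return self._by_name[name]

    def depth(self, name: str) -> int:
        d, cur = 0, self._by_name[name]
        while cur.parent is not None:
            d, cur = d + 1, self._by_name[cur.parent]
        return d

    def entity_profile(self, intent: Intent, ont: Ontology) -> frozenset[str]:
        """Entity types appearing in the intent's training phrases."""
        if intent.name not in self._profile_cache:
            types: set[str] = set()
            for phrase in intent.training_phrases:
                types.update(m.entity_type for m in ont.tag_entities(phrase))
            self._profile_cache[intent.name] = frozenset(types)
        return self._profile_cache[intent.name]

    def intents_for_event(self, event: str) -> list[Intent]:
        return [i for i in self if event in i.events]

    # -- config round-trip ------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = [
            {
                "name": i.name,
                "parent": i.parent,
                "training_phrases": i.training_phrases,
                "required_params": [
                    {
                        "name": p.name,
                        "entity_type": p.entity_type,
                        "prompt": p.prompt,
                        "order": p.order,
                        "mandatory": p.mandatory,
                    }
                    for p in i.required_params
                ],
                "input_contexts": i.input_contexts,
                "output_contexts": [list(t) for t in i.output_contexts],
                "events": i.events,
                "fulfillment": i.fulfillment,
            }
            for i in self
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "IntentRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or []
        intents = [
            Intent(
                name=d["name"],
                parent=d.get("parent"),
                training_phrases=d.get("training_phrases", []),
                required_params=[SlotSpec(**p) for p in d.get("required_params", [])],
                input_contexts=d.get("input_contexts", []),
                output_contexts=[tuple(t) for t in d.get("output_contexts", [])],
                events=d.get("events", []),
                fulfillment=d.get("fulfillment"),
            )
            for d in doc
        ]
        return cls(intents)


# ---------------------------------------------------------------------- #
# matching

_TOKEN_RE = re.compile(r"[a-z0-9']+")


def _tokens(text: str) -> frozenset[str]:
    return frozenset(_TOKEN_RE.findall(text.lower()))


def match_intent(
    registry: IntentRegistry,
    state: ConversationState,
    utterance: str,
    ont: Ontology,
) -> Optional[tuple[Intent, list[tuple[str, str]]]]:
    """Match an utterance to an intent, returning extracted parameters.

    Candidates are restricted to follow-ups of active contexts when any are
    active (falling back to top-level intents), scored by the number of
    tagged entity types shared with the intent's training phrases, with a
    token-overlap fallback for entity-free utterances. Ties break toward
    the deepest intent, then lexicographic name order. ``None`` means
    no-match; the caller records it for analytics.
    """
    matches = ont.tag_entities(utterance)
    utter_types = {m.entity_type for m in matches}
    params = [(m.entity_type, m.value) for m in matches]

    active = state.active_context_names()
    top_level = [i for i in registry if not i.input_contexts]
    if active:
        candidates = [i for i in registry if set(i.input_contexts) & active]
        if not candidates:
            candidates = top_level
    else:
        candidates = top_level

    def score(intent: Intent) -> tuple[int, float]:
        entity_score = len(utter_types & registry.entity_profile(intent, ont))
        utok = _tokens(utterance)
        token_score = 0.0
        for phrase in intent.training_phrases:
            ptok = _tokens(phrase)
            if not ptok or not utok:
                continue
            token_score = max(token_score, len(ptok & utok) / len(ptok | utok))
        return entity_score, token_score

    scored = []
    for intent in candidates:
        es, ts = score(intent)
        if es > 0 or ts >= 0.5:
            scored.append((es, ts, registry.depth(intent.name), intent))
    if not scored:
        # second chance: ignore the context restriction entirely
        if active and candidates is not top_level:
            relaxed = ConversationState(session_id=state.session_id)
            return match_intent(registry, relaxed, utterance, ont)
        return None
    scored.sort(key=lambda t: (-t[0], -t[1], -t[2], t[3].name))
    return scored[0][3], params


# ---------------------------------------------------------------------- #
# turn processing

def _merge_params(state: ConversationState, params: Sequence[tuple[str, str]]) -> None:
    # keyed by entity type: repeating an already-collected param is a no-op
    for etype, value in params:
        state.collected_params.setdefault(etype, (value, etype))


def _slotfill_context(intent: Intent) -> str:
    return f"{intent.name}_slotfill"


def dispatch_fulfillment(
    intent: Intent,
    params: dict[str, tuple[str, str]],
    services: Services,
) -> FulfillmentResponse:
    """Build a fulfillment request and invoke the named in-process service."""
    if intent.fulfillment is None:
        return FulfillmentResponse(text="Noted.")
    if intent.fulfillment not in services:
        raise DialogConfigurationError(
            f"intent {intent.name!r}: unknown fulfillment service {intent.fulfillment!r}"
        )
    request = FulfillmentRequest(intent=intent.name, params=dict(params))
    return services[intent.fulfillment](request)


def handle_event(
    registry: IntentRegistry,
    state: ConversationState,
    event: str,
    services: Services,
    ont: Ontology,
) -> AgentResponse:
    """Trigger the intent registered for ``event`` without user input."""
    intents = registry.intents_for_event(event)
    if not intents:
        raise DialogConfigurationError(f"event {event!r} is not registered on any intent")
    if len(intents) > 1:
        raise EventAmbiguityError(
            f"event {event!r} registered on multiple intents: "
            f"{sorted(i.name for i in intents)}"
        )
    return _activate(registry, state, intents[0], [], services, ont)


def _activate(
    registry: IntentRegistry,
    state: ConversationState,
    intent: Intent,
    params: Sequence[tuple[str, str]],
    services: Services,
    ont: Ontology,
) -> AgentResponse:
    _merge_params(state, params)
    outputs = intent.output_contexts or [(intent.context_name, DEFAULT_CONTEXT_LIFESPAN)]
    for name, lifespan in outputs:
        state.push_context(name, lifespan)
    state.active_intent = intent.name
    pending = [
        p
        for p in sorted(intent.required_params, key=lambda p: p.order)
        if p.mandatory and p.name not in state.collected_params
    ]
    if pending:
        state.pending_slots = pending
        state.push_context(_slotfill_context(intent))
        return AgentResponse(text=pending[0].prompt, intent=intent.name)
    return _fulfill(registry, state, intent, services, ont)


def _fulfill(
    registry: IntentRegistry,
    state: ConversationState,
    intent: Intent,
    services: Services,
    ont: Ontology,
) -> AgentResponse:
    try:
        resp = dispatch_fulfillment(intent, state.collected_params, services)
    except DialogConfigurationError:
        raise
    except Exception:
        return AgentResponse(
            text=SERVICE_ERROR_RESPONSE, intent=intent.name, error=True
        )
    if resp.event:
        follow = handle_event(registry, state, resp.event, services, ont)
        text = resp.text + ("\n" + follow.text if follow.text else "")
        return AgentResponse(
            text=text,
            intent=follow.intent,
            payload=follow.payload or resp.payload,
            error=follow.error,
        )
    return AgentResponse(text=resp.text, intent=intent.name, payload=resp.payload)


def process_turn(
    state: ConversationState,
    registry: IntentRegistry,
    services: Services,
    utterance: str,
    ont: Ontology,
    clock: Callable[[], float] = time.time,
) -> AgentResponse:
    """Run one full conversation turn and append it to the history.

    A pending mandatory slot consumes the utterance as its value; otherwise
    the utterance is matched to an intent, slot filling starts or
    fulfillment fires, and finally every active context ages by one turn.
    """
    t0 = clock()
    if state.pending_slots:
        slot = state.pending_slots.pop(0)
        tagged = [m for m in ont.tag_entities(utterance) if m.entity_type == slot.entity_type]
        value = tagged[0].value if tagged else utterance.strip()
        state.collected_params[slot.name] = (value, slot.entity_type)
        intent = registry[state.active_intent]
        if state.pending_slots:
            resp = AgentResponse(text=state.pending_slots[0].prompt, intent=intent.name)
        else:
            state.drop_context(_slotfill_context(intent))
            resp = _fulfill(registry, state, intent, services, ont)
    else:
        matched = match_intent(registry, state, utterance, ont)
        if matched is None:
            resp = AgentResponse(text=FALLBACK_RESPONSE, mismatch=True)
        else:
            intent, params = matched
            resp = _activate(registry, state, intent, params, services, ont)
    state.tick_contexts()
    t1 = clock()
    state.history.append(
        Turn(
            timestamp=t0,
            utterance=utterance,
            intent=resp.intent,
            response=resp.text,
            latency=t1 - t0,
            mismatch=resp.mismatch,
            error=resp.error,
        )
    )
    return resp


# ---------------------------------------------------------------------- #
# issue ordering

def order_issues(
    issues: Sequence[tuple[str, int]],
    utterance: str,
    cues: Sequence[str] = PRIORITY_CUES,
    window: int = PRIORITY_WINDOW,
) -> list[str]:
    """Order detected issues for one-at-a-time handling.

    ``issues`` are ``(concept id, mention offset)`` pairs. An issue
    mentioned within ``window`` characters after a priority cue is
    promoted; otherwise mention order is preserved (stable).
    """
    low = utterance.lower()
    cue_positions = [m.end() for cue in cues for m in re.finditer(re.escape(cue), low)]

    def promoted(pos: int) -> bool:
        return any(0 <= pos - cp <= window for cp in cue_positions)

    ranked = sorted(
        enumerate(issues), key=lambda t: (not promoted(t[1][1]), t[0])
    )
    seen: set[str] = set()
    out: list[str] = []
    for _i, (concept, _pos) in ranked:
        if concept not in seen:
            seen.add(concept)
            out.append(concept)
    return out


class FakeClock:
    """Deterministic injectable clock: each call advances by ``step``."""

    def __init__(self, start: float = 1_700_000_000.0, step: float = 0.05):
        self.now = start
        self.step = step

    def __call__(self) -> float:
        t = self.now
        self.now += self.step
        return t
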