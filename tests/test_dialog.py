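"""Dialog engine: matching, slot filling, contexts, events, issue order."""

import pytest

from acescreen.dialog import (
    ConversationState,
    DialogConfigurationError,
    EventAmbiguityError,
    FakeClock,
    FulfillmentResponse,
    Intent,
    IntentRegistry,
    SlotSpec,
    handle_event,
    match_intent,
    order_issues,
    process_turn,
)


def _echo_services():
    calls = []

    def svc(req):
        calls.append(req)
        return FulfillmentResponse(text=f"handled {req.intent}")

    return {"recommendation": svc, "sdoh_surveillance": svc,
            "aces_surveillance": svc, "appointment": svc}, calls


# ---------------------------------------------------------------------- #
# registry structure

def test_duplicate_intent_names_rejected():
    with pytest.raises(DialogConfigurationError):
        IntentRegistry([Intent(name="A"), Intent(name="A")])


def test_parent_output_context_feeds_child_input_context(registry):
    child = registry["SDoH_Surveillance"]
    parent = registry["FRI_Assessment"]
    assert parent.context_name in child.input_contexts
    assert parent.context_name in {n for n, _ in parent.output_contexts}


def test_registry_yaml_round_trip(tmp_path, registry):
    p = tmp_path / "intents.yaml"
    registry.to_yaml(p)
    reloaded = IntentRegistry.from_yaml(p)
    assert {i.name for i in reloaded} == {i.name for i in registry}
    orig = registry["FRI_followup_activity"]
    again = reloaded["FRI_followup_activity"]
    assert [s.name for s in again.required_params] == [s.name for s in orig.required_params]
    assert again.events == orig.events


# ---------------------------------------------------------------------- #
# matching

def test_detailed_utterance_matches_assessment_with_params(ont, registry):
    state = ConversationState(session_id="s")
    matched = match_intent(
        registry, state,
        "I am an African American female and I have housing issues", ont,
    )
    assert matched is not None
    intent, params = matched
    assert intent.name == "FRI_Assessment"
    types = {t for t, _v in params}
    assert {"ethnicity", "gender", "housing_circumstance"} <= types


def test_vague_utterance_still_matches_via_token_overlap(ont, registry):
    state = ConversationState(session_id="s")
    matched = match_intent(registry, state, "I have several issues", ont)
    assert matched is not None
    intent, params = matched
    assert intent.name == "FRI_Assessment"
    assert params == []


def test_gibberish_is_a_no_match(ont, registry):
    state = ConversationState(session_id="s")
    assert match_intent(registry, state, "flurble wombat xyzzy", ont) is None


def test_no_match_turn_is_recorded_for_analytics(ont, registry):
    state = ConversationState(session_id="s")
    services, _ = _echo_services()
    resp = process_turn(state, registry, services, "flurble xyzzy", ont, clock=FakeClock())
    assert resp.mismatch
    assert state.history[-1].mismatch and state.history[-1].intent is None


# ---------------------------------------------------------------------- #
# slot filling

def test_cooperative_user_reaches_fulfillment_in_exactly_k_prompts(ont):
    k_slots = [
        SlotSpec(name=f"p{i}", entity_type="zip_code", prompt=f"prompt {i}", order=i)
        for i in range(3)
    ]
    registry = IntentRegistry([
        Intent(name="Needy", training_phrases=["I have housing issues"],
               required_params=k_slots, fulfillment="recommendation"),
    ])
    services, calls = _echo_services()
    state = ConversationState(session_id="s")
    clock = FakeClock()
    resp = process_turn(state, registry, services, "I have housing issues", ont, clock=clock)
    prompts = 1  # first prompt returned by the match turn
    assert resp.text == "prompt 0"
    while not calls:
        resp = process_turn(state, registry, services, "10001", ont, clock=clock)
        if not calls:
            assert resp.text.startswith("prompt")
            prompts += 1
    assert prompts == len(k_slots)
    assert resp.text == "handled Needy"
    assert len(state.collected_params) >= len(k_slots)


def test_repeated_param_is_merged_idempotently(ont, registry):
    services, _ = _echo_services()
    state = ConversationState(session_id="s")
    clock = FakeClock()
    process_turn(state, registry, services, "I have housing issues", ont, clock=clock)
    before = dict(state.collected_params)
    process_turn(state, registry, services, "38103", ont, clock=clock)  # zip slot
    process_turn(state, registry, services, "as I said, housing issues", ont, clock=clock)
    after = state.collected_params
    assert after["housing_circumstance"] == before["housing_circumstance"]
    assert list(after).count("housing_circumstance") == 1


# ---------------------------------------------------------------------- #
# context stack semantics

def test_context_stack_is_lifo_and_expiry_restores_previous_top():
    state = ConversationState(session_id="s")
    state.push_context("A", lifespan=5)
    state.push_context("B", lifespan=1)
    assert state.stack[-1].name == "B"
    state.tick_contexts()  # B expires, A survives
    assert [c.name for c in state.stack] == ["A"]
    assert state.stack[-1].lifespan == 4


def test_active_contexts_always_have_positive_lifespan(ont, registry):
    services, _ = _echo_services()
    state = ConversationState(session_id="s")
    clock = FakeClock()
    for utterance in ["I have housing issues", "38103", "more housing issues"]:
        process_turn(state, registry, services, utterance, ont, clock=clock)
        assert all(c.lifespan >= 1 for c in state.stack)


def test_reactivation_resets_context_lifespan():
    state = ConversationState(session_id="s")
    state.push_context("A", lifespan=5)
    state.tick_contexts()
    state.tick_contexts()
    assert state.stack[0].lifespan == 3
    state.push_context("A", lifespan=5)
    assert state.stack[0].lifespan == 5 and len(state.stack) == 1


# ---------------------------------------------------------------------- #
# events

def test_event_triggers_registered_intent_with_its_slots(ont, registry):
    services, _ = _echo_services()
    state = ConversationState(session_id="s")
    resp = handle_event(registry, state, "schedule an appointment", services, ont)
    assert resp.intent == "FRI_followup_activity"
    assert resp.text == "What date works for you?"  # first mandatory slot
    assert [s.name for s in state.pending_slots] == [
        "date", "duration", "time", "appointment_type"
    ]


def test_unregistered_event_is_a_configuration_error(ont, registry):
    services, _ = _echo_services()
    with pytest.raises(DialogConfigurationError):
        handle_event(registry, ConversationState(session_id="s"),
                     "nonexistent event", services, ont)


def test_event_on_two_intents_is_ambiguous(ont):
    registry = IntentRegistry([
        Intent(name="A", events=["go"]),
        Intent(name="B", events=["go"]),
    ])
    with pytest.raises(EventAmbiguityError):
        handle_event(registry, ConversationState(session_id="s"), "go", {}, ont)


def test_fulfillment_event_chains_into_follow_up_intent(ont):
    """A service response carrying an event triggers the configured intent
    without user input, exactly as if the user had matched it."""
    registry = IntentRegistry([
        Intent(name="Assess", training_phrases=["I have housing issues"],
               fulfillment="recommendation"),
        Intent(name="Scheduler", events=["schedule an appointment"],
               required_params=[SlotSpec(name="date", entity_type="date",
                                         prompt="What date works for you?")],
               fulfillment="appointment"),
    ])
    services = {
        "recommendation": lambda req: FulfillmentResponse(
            text="Let's schedule a visit.", event="schedule an appointment"),
        "appointment": lambda req: FulfillmentResponse(text="booked"),
    }
    state = ConversationState(session_id="s")
    resp = process_turn(state, registry, services, "I have housing issues", ont,
                        clock=FakeClock())
    assert resp.intent == "Scheduler"
    assert "What date works for you?" in resp.text
    assert [s.name for s in state.pending_slots] == ["date"]
    # the slot prompt is live: answering it completes the chained intent
    resp2 = process_turn(state, registry, services, "next Tuesday", ont, clock=FakeClock())
    assert resp2.text == "booked"


def test_unknown_fulfillment_service_is_a_configuration_error(ont):
    registry = IntentRegistry([
        Intent(name="A", training_phrases=["I have housing issues"],
               fulfillment="missing_service"),
    ])
    with pytest.raises(DialogConfigurationError):
        process_turn(ConversationState(session_id="s"), registry, {},
                     "I have housing issues", ont, clock=FakeClock())


def test_failing_service_yields_fallback_with_error_flag(ont):
    registry = IntentRegistry([
        Intent(name="A", training_phrases=["I have housing issues"],
               fulfillment="svc"),
    ])

    def boom(req):
        raise RuntimeError("backend down")

    state = ConversationState(session_id="s")
    resp = process_turn(state, registry, {"svc": boom}, "I have housing issues",
                        ont, clock=FakeClock())
    assert resp.error and not resp.mismatch
    assert state.history[-1].error


# ---------------------------------------------------------------------- #
# deterministic replay

def test_replaying_a_script_yields_identical_transcripts(ont, registry, scenarios):
    def run():
        services, _ = _echo_services()
        state = ConversationState(session_id="s")
        clock = FakeClock()
        out = []
        for turn in scenarios[1].turns:
            resp = process_turn(state, registry, services, turn, ont, clock=clock)
            out.append((resp.text, resp.intent, state.history[-1].timestamp,
                        state.history[-1].latency))
        return out

    assert run() == run()


# ---------------------------------------------------------------------- #
# issue ordering

@pytest.mark.parametrize(
    "issues, utterance, expected",
    [
        # a job preference promotes employment over earlier mentions
        ([("education_issue", 30), ("employment_issue", 75)],
         "I am interested in furthering my education, but would prefer a job first",
         ["employment_issue", "education_issue"]),
        # concern cue promotes food over the earlier developmental issue
        ([("developmental_delay", 10), ("food_insecurity", 95)],
         "My son is developmentally delayed. But I am mostly concerned about food.",
         ["food_insecurity", "developmental_delay"]),
        # no cue: stable mention order
        ([("legal_issue", 5), ("education_issue", 40)],
         "legal trouble and also some education trouble",
         ["legal_issue", "education_issue"]),
        ([("food_insecurity", 3)], "food problems", ["food_insecurity"]),
    ],
)
def test_order_issues(issues, utterance, expected):
    assert order_issues(issues, utterance) == expected
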