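import pandas as pd
import pytest

from acescreen import ChatSession, NeighborhoodProvider, Resource
from acescreen import fixtures as fx


@pytest.fixture(scope="session")
def ont():
    return fx.build_aceso_lite()


@pytest.fixture()
def registry():
    # function-scoped: IntentRegistry autowires contexts in place
    return fx.default_intent_registry()


@pytest.fixture(scope="session")
def provider():
    return NeighborhoodProvider(fx.neighborhood_table())


def _directory_objects(df: pd.DataFrame) -> list[Resource]:
    return [
        Resource(
            id=r["id"], kind=r["kind"], name=r["name"], zip=str(r["zip"]),
            lat=float(r["lat"]), lon=float(r["lon"]),
            languages=tuple(str(r["languages"]).split(";")),
            specialty=r["specialty"],
        )
        for _, r in df.iterrows()
    ]


@pytest.fixture(scope="session")
def directory():
    df, _ = fx.resource_directory(seed=1)
    return _directory_objects(df)


@pytest.fixture(scope="session")
def centroids():
    _, cdf = fx.resource_directory(seed=1)
    return {str(r["zip"]): (float(r["lat"]), float(r["lon"])) for _, r in cdf.iterrows()}


@pytest.fixture(scope="session")
def evidence():
    return fx.evidence_table()


@pytest.fixture()
def make_session(ont, provider, directory, centroids, evidence):
    def _make(session_id="test-session", **kwargs):
        return ChatSession(
            ont,
            fx.default_intent_registry(),
            provider=provider,
            directory=directory,
            centroids=centroids,
            evidence=evidence,
            session_id=session_id,
            **kwargs,
        )

    return _make


@pytest.fixture(scope="session")
def scenarios():
    return {s.scenario_id: s for s in fx.scenario_scripts()}
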