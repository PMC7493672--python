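import pytest

from carejourney import build_t2d_fixture, model_from_dict


@pytest.fixture(scope="session")
def t2d():
    """The bundled T2D case-study model (treat as read-only; deep-copy
    before mutating)."""
    return build_t2d_fixture()


@pytest.fixture()
def toy_chain_model():
    """A 2-segment feed-forward chain with single-phase schedules and
    hand-set costs, small enough for closed-form oracles: A (€10.00/year,
    leaves 0.2 to B, 0.1 to exit) -> B (€4.00/year, leaves 0.25 to exit)."""
    return model_from_dict(
        {
            "metadata": {"name": "toy", "entry_segment": "A"},
            "resources": [
                {"id": "ra", "kind": "human", "cost_basis": "per_minute", "unit_cost": 1.00},
                {"id": "rb", "kind": "human", "cost_basis": "per_minute", "unit_cost": 0.50},
            ],
            "elements": [
                {"id": "ea", "requires": [{"resource": "ra", "quantity": 10}]},
                {"id": "eb", "requires": [{"resource": "rb", "quantity": 8}]},
            ],
            "services": [
                {"id": "SA", "usages": [{"element": "ea", "frequency": 1, "utilization": 100}]},
                {"id": "SB", "usages": [{"element": "eb", "frequency": 1, "utilization": 100}]},
            ],
            "segments": [
                {
                    "id": "A",
                    "schedule": {"phases": [{"service": "SA"}], "expected_total_duration": 3},
                    "outcomes": {"score": 0.8},
                },
                {
                    "id": "B",
                    "schedule": {"phases": [{"service": "SB"}], "expected_total_duration": 4},
                    "outcomes": {"score": 0.3},
                },
            ],
            "transitions": {
                "absorbing": ["exit"],
                "rows": {"A": {"B": 0.2, "exit": 0.1}, "B": {"exit": 0.25}},
            },
        }
    )
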