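"""Activity-based costing: worked tariff values, modes, conservation and
monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carejourney import (
    ResourceRequirement,
    ServiceElement,
    ServiceElementUsage,
    element_annual_cost,
    expected_annual_quantity,
    journey_cost,
    random_model,
    region_annual_cost,
    segment_annual_cost,
    service_annual_cost,
)


def _usage(model, service, element):
    for u in model.service(service).usages:
        if u.element == element:
            return u
    raise KeyError(element)


class TestExpectedAnnualQuantity:
    # (service, element, resource, rounded minutes): frequency x utilization
    # x per-delivery minutes, rounded half-up to whole minutes
    @pytest.mark.parametrize(
        "service,element,resource,expected",
        [
            ("S3", "SE7", "gp_nurse", 64),   # 4 x 0.8 x 20
            ("S3", "SE8", "dietician", 5),   # 1 x 0.1 x 45 = 4.5 -> 5
            ("S3", "SE10", "practice_nurse", 1),  # 0.5 -> 1
            ("S3", "SE9", "optometrist", 2),
            ("S2", "SE16", "lifestyle_consultant", 240),
            ("S2", "SE6", "gp", 60),
        ],
    )
    def test_tariff_minutes(self, t2d, service, element, resource, expected):
        u = _usage(t2d, service, element)
        assert expected_annual_quantity(u, t2d.element(element), resource) == expected

    def test_zero_utilization_gives_zero(self, t2d):
        u = _usage(t2d, "S3", "SE7").model_copy(update={"utilization": 0.0})
        assert expected_annual_quantity(u, t2d.element("SE7"), "gp_nurse") == 0

    def test_unrounded_form_is_the_raw_product(self, t2d):
        u = _usage(t2d, "S3", "SE8")
        q = expected_annual_quantity(u, t2d.element("SE8"), "dietician", round_quantities=False)
        assert q == pytest.approx(4.5)

    def test_unknown_resource_is_an_error(self, t2d):
        u = _usage(t2d, "S3", "SE8")
        with pytest.raises(KeyError):
            expected_annual_quantity(u, t2d.element("SE8"), "gp")


class TestElementAndServiceCosts:
    @pytest.mark.parametrize(
        "service,element,eur",
        [
            ("S2", "SE16", 139.20),
            ("S3", "SE7", 45.44),
            ("S3", "SE8", 2.65),
            ("S3", "SE10", 0.29),
            ("S2", "SE14", 46.40),
        ],
    )
    def test_worked_element_costs(self, t2d, service, element, eur):
        bd = element_annual_cost(_usage(t2d, service, element), t2d)
        assert bd.cost_eur == eur
        assert not bd.partial

    def test_uncosted_resource_yields_zero_cost_with_partial_flag(self, t2d):
        bd = element_annual_cost(_usage(t2d, "S5", "SE13"), t2d)
        assert bd.cost == 0
        assert bd.partial

    @pytest.mark.parametrize("service,eur", [("S2", 276.12), ("S3", 53.10)])
    def test_service_annual_totals(self, t2d, service, eur):
        bd = service_annual_cost(service, t2d)
        assert bd.cost_eur == eur
        assert not bd.partial
        assert len(bd.children) == 6

    def test_unrounded_s3_total(self, t2d):
        assert service_annual_cost("S3", t2d, round_quantities=False).cost_eur == 52.69

    def test_empty_service_costs_nothing(self, t2d):
        bd = service_annual_cost("S7", t2d)
        assert bd.cost == 0.0

    def test_full_utilization_unrounded_equals_closed_form(self, t2d):
        # with all utilizations at 100% and rounding off, the cost is
        # exactly sum(freq x minutes x unit_cost)
        m = t2d.model_copy(deep=True)
        for s in m.services:
            for u in s.usages:
                u.utilization = 1.0
        for sid in ("S2", "S3"):
            expected = 0.0
            for u in m.service(sid).usages:
                for req in m.element(u.element).requirements:
                    res = m.resource(req.resource)
                    if not res.uncosted:
                        expected += u.frequency * req.quantity * res.unit_cost_cents
            got = service_annual_cost(sid, m, round_quantities=False).cost
            assert got == pytest.approx(expected)


class TestSegmentAndJourney:
    def test_ds2_deterministic_segment_cost(self, t2d):
        # one diagnosis year at 276.12 then two chronic years at 53.10
        bd = segment_annual_cost("DS2", t2d, "deterministic")
        assert bd.cost_eur == 127.44

    def test_single_phase_segment_equals_its_service(self, toy_chain_model):
        seg = segment_annual_cost("B", toy_chain_model)
        svc = service_annual_cost("SB", toy_chain_model)
        assert seg.cost == pytest.approx(svc.cost)

    def test_ds2_markov_weights_are_the_leave_probability(self, t2d):
        # geometric sojourn with leave 0.375: the diagnosis year carries
        # weight 1/2.667 = 0.375
        bd = segment_annual_cost("DS2", t2d, "markov")
        expected = 0.375 * 27612 + 0.625 * 5310
        assert bd.cost == pytest.approx(expected)

    def test_toy_journey_is_sojourn_times_annual_cost(self, toy_chain_model):
        # single-segment journey: 4 years x 4.00/year
        m = toy_chain_model.model_copy(deep=True)
        m.transitions.rows["B"] = {"exit": 0.25}
        bd = journey_cost(m, "B", "deterministic")
        assert bd.cost_eur == pytest.approx(16.00)

    def test_ds2_contribution_to_deterministic_journey(self, t2d):
        bd = journey_cost(t2d, "DS2", "deterministic")
        ds2 = next(c for c in bd.children if c.id == "DS2")
        assert ds2.cost_eur == pytest.approx(382.32)  # 3 x 127.44

    def test_markov_journey_matches_truncated_expansion_oracle(self, toy_chain_model):
        # independent oracle: per-year state probabilities from the scalar
        # recurrence of the feed-forward chain, summed over 200 years
        ca, cb = 1000.0, 400.0  # cents per year
        pa, pb, horizon = 1.0, 0.0, 200
        expected = 0.0
        for _ in range(horizon):
            expected += pa * ca + pb * cb
            pa, pb = pa * 0.7, pa * 0.2 + pb * 0.75
        got = journey_cost(toy_chain_model, "A", "markov").cost
        assert abs(got - expected) < 1.0  # within 0.01 EUR

    def test_region_cost_is_the_straight_product(self, t2d):
        assert region_annual_cost(t2d, 911, service="S2").cost_eur == 251545.32
        assert region_annual_cost(t2d, 100, service="S3").cost_eur == 5310.00
        assert region_annual_cost(t2d, 0, service="S2").cost == 0.0


class TestQuantityProperties:
    @given(
        freq=st.integers(0, 400),
        util_pct=st.integers(0, 100),
        minutes=st.integers(1, 240),
    )
    @settings(deadline=None, max_examples=200)
    def test_rounding_stays_within_half_a_unit_and_is_monotone(
        self, freq, util_pct, minutes
    ):
        element = ServiceElement(
            id="e", requirements=[ResourceRequirement(resource="r", quantity=minutes)]
        )

        def qty(pct):
            u = ServiceElementUsage(element="e", frequency=freq, utilization=pct / 100)
            return expected_annual_quantity(u, element, "r")

        raw = freq * (util_pct / 100) * minutes
        q = qty(util_pct)
        assert abs(q - raw) <= 0.5
        assert q == int(q) >= 0
        if util_pct < 100:
            assert qty(util_pct + 1) >= q


class TestStructuralProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_cost_conservation_at_every_level(self, t2d, seed):
        """Every internal node's cost equals the sum of its children's."""
        models = [t2d, random_model(seed)]
        for m in models:
            bd = journey_cost(m, m.entry_segment, "markov")
            for node in bd.walk():
                if node.children:
                    assert node.cost == sum(c.cost for c in node.children)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotonicity_in_utilization_frequency_and_cost(self, seed):
        m = random_model(seed)
        base = journey_cost(m, m.entry_segment, "deterministic").cost
        rng = np.random.default_rng(seed)
        m2 = m.model_copy(deep=True)
        svc = m2.services[int(rng.integers(len(m2.services)))]
        u = svc.usages[int(rng.integers(len(svc.usages)))]
        u.utilization = min(1.0, u.utilization + 0.3)
        u.frequency += 2
        r = m2.resources[int(rng.integers(len(m2.resources)))]
        r.unit_cost_cents += 50
        assert journey_cost(m2, m2.entry_segment, "deterministic").cost >= base

    def test_partial_flag_propagates_to_every_enclosing_level(self, t2d):
        bd = journey_cost(t2d, "DS2", "deterministic")
        assert bd.partial  # DS3/DS4 medication is uncosted
        ds3 = next(c for c in bd.children if c.id == "DS3")
        assert ds3.partial
        ds2 = next(c for c in bd.children if c.id == "DS2")
        assert not ds2.partial
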