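import math

import numpy as np
import pandas as pd
import pytest

from carekit.core_io import GroupMembership, Individual, ValidationError
from carekit.predictors import (
    affiliation_evenness,
    available_partner_pool,
    build_predictor_table,
    mean_focal_rank,
    mean_male_affiliation,
    mean_paternal_affiliation,
    rank_weighted_affiliation,
)


def _events(rows):
    return pd.DataFrame(rows, columns=["day", "protocol_id", "focal_id", "partner_id"])


def _protocols(focal, days):
    return pd.DataFrame(
        [(f"{focal}-{d}", focal, d, 20.0) for d in days],
        columns=["protocol_id", "focal_id", "day", "duration_min"],
    )


def _ranks(rows, hierarchy):
    df = pd.DataFrame(rows, columns=["id", "day", "rank"])
    df["hierarchy"] = hierarchy
    return df[["id", "day", "hierarchy", "rank"]]


class TestMeanMaleAffiliation:
    def test_ten_events_five_days(self):
        ev = _events([(d, f"f-{d}", "f", "M1") for d in range(5) for _ in range(2)])
        assert mean_male_affiliation(ev, _protocols("f", range(5)), "f", (0, 100)) == 2.0

    def test_zero_events(self):
        ev = _events([])
        assert mean_male_affiliation(ev, _protocols("f", range(8)), "f", (0, 100)) == 0.0

    def test_no_protocol_days_warns_absent(self):
        with pytest.warns(UserWarning, match="no protocol days"):
            out = mean_male_affiliation(_events([]), _protocols("f", [200]), "f", (0, 100))
        assert out is None

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(42)
        lam, days = 1.78, 60
        counts = rng.poisson(lam, days)
        rows = [(d, f"f-{d}", "f", "M1") for d in range(days) for _ in range(counts[d])]
        got = mean_male_affiliation(_events(rows), _protocols("f", range(days)), "f", (0, days))
        se = math.sqrt(lam / days)
        assert abs(got - lam) < 3 * se


class TestPaternal:
    def test_all_with_sire(self):
        ev = _events([(d, f"f-{d}", "f", "DAD") for d in range(3) for _ in range(2)])
        assert mean_paternal_affiliation(ev, _protocols("f", range(3)), "f", "DAD", (0, 10)) == 2.0

    def test_none_with_sire(self):
        ev = _events([(0, "f-0", "f", "M1")])
        assert mean_paternal_affiliation(ev, _protocols("f", range(3)), "f", "DAD", (0, 10)) == 0.0

    def test_unknown_sire_absent(self):
        assert mean_paternal_affiliation(_events([]), _protocols("f", [0]), "f", None, (0, 10)) is None

    def test_subset_monotonicity(self):
        rng = np.random.default_rng(0)
        rows = [(int(d), f"f-{d}", "f", f"M{rng.integers(4)}")
                for d in rng.integers(0, 20, 50)]
        ev = _events(rows)
        pr = _protocols("f", range(20))
        total = mean_male_affiliation(ev, pr, "f", (0, 20))
        for sire in ["M0", "M1", "M2", "M3"]:
            assert mean_paternal_affiliation(ev, pr, "f", sire, (0, 20)) <= total


class TestFocalRank:
    def test_constant(self):
        r = _ranks([("f", d, 0.7) for d in range(10)], "female_immature")
        assert mean_focal_rank(r, "f", (0, 10)) == pytest.approx(0.7)

    def test_half(self):
        rows = [("f", d, 0.0) for d in range(5)] + [("f", d, 1.0) for d in range(5, 10)]
        assert mean_focal_rank(_ranks(rows, "female_immature"), "f", (0, 10)) == pytest.approx(0.5)

    def test_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        days = list(range(3, 40))
        vals = rng.random(len(days))
        r = _ranks(list(zip(["f"] * len(days), days, vals)), "female_immature")
        lo, hi = 10, 30
        expected = np.mean([v for d, v in zip(days, vals) if lo <= d < hi])
        assert mean_focal_rank(r, "f", (lo, hi)) == pytest.approx(expected, abs=1e-12)

    def test_absent(self):
        assert mean_focal_rank(_ranks([], "female_immature"), "f", (0, 10)) is None


class TestWeighted:
    def test_hand_sum(self):
        ev = _events([(0, "f-0", "f", "A"), (0, "f-0", "f", "A"), (1, "f-1", "f", "B")])
        ranks = _ranks([("A", 0, 0.9), ("B", 1, 0.1)], "male")
        got = rank_weighted_affiliation(ev, _protocols("f", [0, 1]), ranks, "f", (0, 10))
        assert got == pytest.approx((0.9 + 0.9 + 0.1) / 2)

    def test_all_rank_zero(self):
        ev = _events([(0, "f-0", "f", "A")] * 5)
        ranks = _ranks([("A", 0, 0.0)], "male")
        assert rank_weighted_affiliation(ev, _protocols("f", [0]), ranks, "f", (0, 10)) == 0.0

    def test_identity_when_all_rank_one(self):
        rng = np.random.default_rng(7)
        rows = [(int(d), f"f-{d}", "f", f"M{rng.integers(3)}") for d in rng.integers(0, 15, 40)]
        ev = _events(rows)
        pr = _protocols("f", range(15))
        ranks = _ranks([(f"M{k}", d, 1.0) for k in range(3) for d in range(15)], "male")
        assert rank_weighted_affiliation(ev, pr, ranks, "f", (0, 15)) == pytest.approx(
            mean_male_affiliation(ev, pr, "f", (0, 15))
        )

    def test_missing_partner_rank_names_event(self):
        ev = _events([(0, "f-0", "f", "A")])
        with pytest.raises(ValidationError, match="A"):
            rank_weighted_affiliation(ev, _protocols("f", [0]), _ranks([], "male"), "f", (0, 10))


class TestEvenness:
    def test_uniform(self):
        ev = _events([(0, "p", "f", m) for m in ("A", "B", "C") for _ in range(5)])
        assert affiliation_evenness(ev, "f", (0, 10), {"A", "B", "C"}) == pytest.approx(1.0)

    def test_single_partner_skew(self):
        ev = _events([(0, "p", "f", "A")] * 7)
        assert affiliation_evenness(ev, "f", (0, 10), {"A", "B", "C", "D"}) == 0.0

    def test_hand_shannon(self):
        ev = _events([(0, "p", "f", "A")] * 9 + [(0, "p", "f", "B")])
        h = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1))
        got = affiliation_evenness(ev, "f", (0, 10), {"A", "B", "C", "D"})
        assert got == pytest.approx(h / math.log(4), abs=1e-12)

    def test_zero_events_absent(self):
        assert affiliation_evenness(_events([]), "f", (0, 10), {"A", "B"}) is None

    def test_partner_outside_pool(self):
        ev = _events([(0, "p", "f", "X")])
        with pytest.raises(ValidationError, match="X"):
            affiliation_evenness(ev, "f", (0, 10), {"A"})

    def test_relabel_and_scale_invariance(self):
        counts = {"A": 4, "B": 2, "C": 9}
        def build(mapping, scale):
            return _events(
                [(0, "p", "f", mapping[m]) for m, c in counts.items() for _ in range(c * scale)]
            )
        pool1 = {"A", "B", "C", "D", "E"}
        base = affiliation_evenness(build({m: m for m in counts}, 1), "f", (0, 10), pool1)
        relabeled = affiliation_evenness(
            build({"A": "Z", "B": "Y", "C": "X"}, 1), "f", (0, 10), {"Z", "Y", "X", "W", "V"}
        )
        scaled = affiliation_evenness(build({m: m for m in counts}, 3), "f", (0, 10), pool1)
        assert base == pytest.approx(relabeled, abs=1e-12)
        assert base == pytest.approx(scaled, abs=1e-12)


class TestBuildTable:
    def _cohort(self):
        inds = [Individual(f"F{k}", "female", -3000) for k in range(10)]
        inds += [Individual(f"M{k}", "male", -3000) for k in range(4)]
        inds += [
            Individual(f"I{k}", "female" if k % 2 else "male", 0,
                       mother_id=f"F{k}", sire_id="M0")
            for k in range(10)
        ]
        mem = [GroupMembership(i.id, "R", -3000, 10_000) for i in inds]
        return inds, mem

    def _full_inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        inds, mem = self._cohort()
        focals = [f"I{k}" for k in range(10)]
        ev_rows, pr_rows = [], []
        for f in focals:
            for d in range(0, 100, 5):
                pr_rows.append((f"{f}-{d}", f, d, 20.0))
                for _ in range(rng.poisson(2.0)):
                    ev_rows.append((d, f"{f}-{d}", f, f"M{rng.integers(4)}"))
        events = _events(ev_rows)
        protocols = pd.DataFrame(pr_rows, columns=["protocol_id", "focal_id", "day", "duration_min"])
        rank_rows = [(f"M{k}", d, (k + 1) / 4, "male") for k in range(4) for d in range(100)]
        rank_rows += [(f, d, 0.5, "female_immature") for f in focals for d in range(100)]
        ranks = pd.DataFrame(rank_rows, columns=["id", "day", "rank", "hierarchy"])
        return events, protocols, ranks, inds, mem, focals

    def test_complete_rows(self):
        events, protocols, ranks, inds, mem, focals = self._full_inputs()
        table = build_predictor_table(events, protocols, ranks, inds, mem, "R",
                                      focals, window=(0, 100))
        assert len(table) == 10
        assert table[["mean_male_affil", "mean_paternal_affil", "focal_rank",
                      "weighted_affil", "evenness"]].notna().all().all()

    def test_truncation_matches_manual_subset(self):
        events, protocols, ranks, inds, mem, focals = self._full_inputs()
        # removal at day 50: drop the focal's records from day 50 onward
        f = focals[0]
        cut_ev = events[~((events["focal_id"] == f) & (events["day"] >= 50))]
        cut_pr = protocols[~((protocols["focal_id"] == f) & (protocols["day"] >= 50))]
        truncated = build_predictor_table(cut_ev, cut_pr, ranks, inds, mem, "R",
                                          [f], window=(0, 100))
        manual = build_predictor_table(events, protocols, ranks, inds, mem, "R",
                                       [f], window=(0, 50))
        for col in ("mean_male_affil", "mean_paternal_affil", "weighted_affil",
                    "n_protocol_days"):
            assert truncated[col].item() == pytest.approx(manual[col].item())

    def test_row_order_invariance(self):
        events, protocols, ranks, inds, mem, focals = self._full_inputs()
        shuffled = events.sample(frac=1.0, random_state=9).reset_index(drop=True)
        t1 = build_predictor_table(events, protocols, ranks, inds, mem, "R",
                                   focals, window=(0, 100))
        t2 = build_predictor_table(shuffled, protocols, ranks, inds, mem, "R",
                                   focals, window=(0, 100))
        pd.testing.assert_frame_equal(t1, t2)

    def test_weight_bounds_property(self):
        events, protocols, ranks, inds, mem, focals = self._full_inputs()
        t = build_predictor_table(events, protocols, ranks, inds, mem, "R",
                                  focals, window=(0, 100))
        assert (t["weighted_affil"] <= t["mean_male_affil"] + 1e-12).all()
        assert (t["mean_paternal_affil"] <= t["mean_male_affil"] + 1e-12).all()
        assert (t["weighted_affil"] >= 0).all()


def test_simulated_partner_counts_in_range(default_sim):
    """Infancy-window partner pools behave like the field descriptives."""
    t = default_sim.predictor_truth[(0, 365)]
    assert t["n_partners"].between(5, 40).all()
    assert t["evenness"].dropna().between(0, 1).all()


def test_available_partner_pool_respects_presence():
    inds = [Individual("M1", "male", -3000), Individual("M2", "male", -3000)]
    mem = [
        GroupMembership("M1", "R", -3000, 50),
        GroupMembership("M2", "R", 200, 400),
    ]
    assert available_partner_pool(inds, mem, "R", (0, 100)) == {"M1"}
    assert available_partner_pool(inds, mem, "R", (0, 365)) == {"M1", "M2"}
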