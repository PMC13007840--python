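import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seegwm.crossing import (
    CrossingRecord,
    TractAtlas,
    contact_tract_probability,
    decide_crossings,
    overlap_census,
    plan_stimulation,
)
from seegwm.electrodes import Contact
from seegwm.volumes import ContactMask, Volume, contact_mask

WINDOW = frozenset({(0, 0, 0), (0, 1, 0), (1, 0, 0), (1, 1, 0)})


def tract_from_values(flat4, name="t", hemisphere="left"):
    data = np.zeros((4, 4, 2), dtype=np.float32)
    data[0, 0, 0], data[0, 1, 0], data[1, 0, 0], data[1, 1, 0] = flat4
    return TractAtlas(name, hemisphere, Volume(data, np.eye(4)))


class TestTractAtlas:
    def test_values_above_one_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            tract_from_values([0.5, 50.0, 0.1, 0.2])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            tract_from_values([-0.1, 0.5, 0.1, 0.2])

    def test_hemisphere_vocabulary(self):
        with pytest.raises(ValueError, match="hemisphere"):
            tract_from_values([0, 0, 0, 0], hemisphere="bilateral")
        assert tract_from_values([0, 0, 0, 0], hemisphere="commissural").is_commissural
        assert not tract_from_values([0, 0, 0, 0], hemisphere="left").is_commissural


class TestProbability:
    def test_max_over_window(self):
        atlas = tract_from_values([0.2, 0.6, 0.4, 0.1])
        assert contact_tract_probability(atlas, ContactMask("c", WINDOW, True)) == pytest.approx(0.6)

    def test_mean_aggregation_option(self):
        atlas = tract_from_values([0.2, 0.6, 0.4, 0.1])
        p = contact_tract_probability(atlas, ContactMask("c", WINDOW, True), "mean")
        assert p == pytest.approx(0.325)

    def test_zero_field_scores_zero(self):
        atlas = tract_from_values([0, 0, 0, 0])
        assert contact_tract_probability(atlas, ContactMask("c", WINDOW, True)) == 0.0

    def test_saturated_voxel_dominates(self):
        atlas = tract_from_values([0.0, 1.0, 0.0, 0.0])
        assert contact_tract_probability(atlas, ContactMask("c", WINDOW, True)) == 1.0

    def test_empty_mask_scores_zero(self):
        atlas = tract_from_values([1, 1, 1, 1])
        assert contact_tract_probability(atlas, ContactMask("c", frozenset(), False)) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(values=st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_max_dominates_mean(self, values):
        atlas = tract_from_values(values)
        mask = ContactMask("c", WINDOW, True)
        assert contact_tract_probability(atlas, mask, "max") >= contact_tract_probability(
            atlas, mask, "mean"
        )


class TestDecideCrossings:
    def make(self, p):
        return tract_from_values([p, 0, 0, 0])

    def test_inclusive_boundary_at_chance(self):
        recs = decide_crossings([self.make(0.5)], [ContactMask("c", WINDOW, True)])
        assert recs[0].crossed

    def test_below_threshold_not_crossed(self):
        recs = decide_crossings([self.make(0.49)], [ContactMask("c", WINDOW, True)])
        assert not recs[0].crossed

    def test_strict_mode_excludes_boundary(self):
        recs = decide_crossings(
            [self.make(0.5)], [ContactMask("c", WINDOW, True)], inclusive=False
        )
        assert not recs[0].crossed

    def test_all_pairs_retained_and_ordered(self):
        atlases = [tract_from_values([0.9, 0, 0, 0], name=n) for n in ("b", "a")]
        masks = [ContactMask(c, WINDOW, True) for c in ("c2", "c1")]
        recs = decide_crossings(atlases, masks)
        assert [(r.contact_id, r.tract_name) for r in recs] == [
            ("c1", "a"), ("c1", "b"), ("c2", "a"), ("c2", "b"),
        ]

    def test_no_atlases_rejected(self):
        with pytest.raises(ValueError, match="no tract atlases"):
            decide_crossings([], [ContactMask("c", WINDOW, True)])

    @pytest.mark.parametrize("thr", [0.0, -0.2, 1.5])
    def test_threshold_domain(self, thr):
        with pytest.raises(ValueError, match="threshold"):
            decide_crossings([self.make(0.5)], [], threshold=thr)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        atlases = [
            tract_from_values(rng.random(4), name=f"t{i}") for i in range(3)
        ]
        masks = [ContactMask(f"c{i}", WINDOW, True) for i in range(5)]
        counts = [
            sum(r.crossed for r in decide_crossings(atlases, masks, threshold=t))
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)


class TestOverlapCensus:
    def recs(self, contact, tracts):
        return [CrossingRecord(contact, t, 0.9, True) for t in tracts]

    def test_set_cardinality_with_commissural_exclusion(self):
        records = self.recs("c1", ["corpus_callosum", "ifof", "slf2"])
        full = overlap_census(records)
        assert (full.n_ge2, full.n_ge3) == (1, 1)
        excl = overlap_census(
            records, exclude_commissural=True, commissural_tracts={"corpus_callosum"}
        )
        assert (excl.n_ge2, excl.n_ge3) == (1, 0)

    def test_published_style_overlap_shares(self):
        # 1356 and 865 of 1826 white-matter contacts
        from seegwm.crossing import OverlapCensus

        oc = OverlapCensus(n_contacts=1826, n_ge2=1356, n_ge3=865, commissural_excluded=True)
        assert oc.pct_ge2 == 74
        assert oc.pct_ge3 == 47

    def test_explicit_denominator(self):
        records = self.recs("c1", ["a", "b"])
        oc = overlap_census(records, contact_ids={"c1", "c2", "c3", "c4"})
        assert oc.n_contacts == 4
        assert oc.n_ge2 == 1

    def test_empty_input_gives_zeros(self):
        oc = overlap_census([])
        assert (oc.n_contacts, oc.n_ge2, oc.n_ge3, oc.pct_ge2) == (0, 0, 0, 0)


class TestStimulationPlan:
    def test_targets_adjacent_and_distance_ordering(self, small_phantom):
        # electrode along z through the left tube (centerline x=-12, z=0, radius 8)
        tube = next(
            t for t in small_phantom.tract_atlases if t.tract_name == "left_tube"
        )
        centers = {1: (-12.0, 0.0, 0.0), 2: (-12.0, 0.0, 3.0),
                   3: (-12.0, 0.0, 6.0), 4: (-12.0, 0.0, 14.0)}
        contacts = [Contact(f"E{i}", i, c) for i, c in centers.items()]
        masks = {
            c.contact_id: contact_mask(tube.volume, c) for c in contacts
        }
        plan = plan_stimulation(tube, {"E": contacts}, masks)
        assert plan.status == "ok"
        assert plan.targets == ("E1", "E2")
        assert plan.adjacent == ("E3",)
        d = plan.distance_mm
        assert d["E1"] == 0.0  # on the centerline, at a supra-threshold voxel center
        assert d["E1"] < d["E3"] < d["E4"]

    def test_tract_without_suprathreshold_voxels(self):
        empty = TractAtlas("t", "left", Volume(np.zeros((4, 4, 4), dtype=np.float32), np.eye(4)))
        contacts = [Contact("E1", 1, (1.0, 1.0, 1.0))]
        masks = {"E1": contact_mask(empty.volume, contacts[0])}
        plan = plan_stimulation(empty, {"E": contacts}, masks)
        assert plan.status == "no_suprathreshold_voxels"
        assert plan.targets == () and plan.adjacent == ()

    def test_requires_an_electrode(self):
        empty = TractAtlas("t", "left", Volume(np.zeros((4, 4, 4), dtype=np.float32), np.eye(4)))
        with pytest.raises(ValueError, match="electrode"):
            plan_stimulation(empty, {}, {})

    def test_plan_rows_are_disjoint(self, small_phantom):
        tube = small_phantom.tract_atlases[0]
        contacts = [Contact(f"E{i}", i, (-12.0, 0.0, float(3 * i))) for i in range(1, 5)]
        masks = {c.contact_id: contact_mask(tube.volume, c) for c in contacts}
        plan = plan_stimulation(tube, {"E": contacts}, masks)
        assert not (set(plan.targets) & set(plan.adjacent))
        roles = [r["role"] for r in plan.to_rows()]
        assert roles.count("target") == len(plan.targets)
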