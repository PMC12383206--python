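"""Label screening: rule verdicts, fixture set, idempotence, monotonicity."""

import numpy as np
import pytest

from cardiacdiff.filtering import (FilterConfig, filter_labels,
                                   rule1_connectivity, rule2_topology,
                                   rule3_min_area, rule4_background_speckle,
                                   screen_mask)
from cardiacdiff.phantoms import PhantomSpec, generate_malformed_mask, generate_phantom


@pytest.fixture(scope="module")
def fixture_set(canonical_masks):
    """4 canonical + 1 malformed per rule, the standard screening fixture."""
    malformed = [generate_malformed_mask(r, seed=10 + r) for r in (1, 2, 3, 4)]
    return canonical_masks + malformed


class TestRules:
    def test_rule1_canonical_counts(self, canonical_masks):
        ok, counts = rule1_connectivity(canonical_masks[0])
        assert ok and counts == {"LV": 1, "MYO": 1, "RV": 1}

    def test_rule1_fragmented(self):
        ok, counts = rule1_connectivity(generate_malformed_mask(1, seed=2))
        assert not ok and counts["LV"] == 2

    def test_rule1_empty_mask_vacuously_passes(self):
        ok, counts = rule1_connectivity(np.zeros((16, 16), dtype=np.uint8))
        assert ok and counts == {"LV": 0, "MYO": 0, "RV": 0}

    def test_rule2_canonical_passes(self, canonical_masks):
        assert rule2_topology(canonical_masks[0])

    def test_rule2_gap_in_ring_fails(self):
        assert not rule2_topology(generate_malformed_mask(2, seed=4))  # slit variant

    def test_rule2_detached_rv_fails(self):
        assert not rule2_topology(generate_malformed_mask(2, seed=5))  # detached variant

    def test_rule2_missing_structures_fail(self):
        assert not rule2_topology(np.zeros((16, 16), dtype=np.uint8))
        lv_only = np.zeros((16, 16), dtype=np.uint8)
        lv_only[4:8, 4:8] = 1
        assert not rule2_topology(lv_only)

    def test_rule3_examples(self):
        ok, frac = rule3_min_area(np.zeros((8, 8), dtype=np.uint8))
        assert not ok and frac == 0.0
        half = np.zeros((8, 8), dtype=np.uint8)
        half[:4] = 1
        ok, frac = rule3_min_area(half)
        assert ok and frac == 0.5

    def test_rule3_just_below_threshold(self):
        """10 foreground pixels on 32x32 give 10/1024 < 1%: reject."""
        m = np.zeros((32, 32), dtype=np.uint8)
        m[0, :10] = 1
        ok, frac = rule3_min_area(m)
        assert frac == pytest.approx(10 / 1024) and not ok

    def test_rule3_at_threshold_passes(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[0, 0] = 1  # exactly 1%
        ok, _ = rule3_min_area(m)
        assert ok

    def test_rule4_canonical_no_strays(self, canonical_masks):
        ok, strays = rule4_background_speckle(canonical_masks[0])
        assert ok and strays == 0

    def test_rule4_speckled(self):
        ok, strays = rule4_background_speckle(generate_malformed_mask(4, seed=1))
        assert not ok and strays == 25

    def test_rule4_boundary_convention(self, canonical_masks):
        """Exactly max_background_components strays still passes."""
        mask = canonical_masks[0].copy()
        spots = [(1, 1), (1, 5), (1, 9), (1, 13), (1, 17)]
        for y, x in spots:
            mask[y, x] = 1
        ok, strays = rule4_background_speckle(mask)
        assert strays == 5 and ok


class TestFilterLabels:
    def test_fixture_set_screening(self, fixture_set):
        """Exactly the 4 canonical masks survive; each malformed report
        fails exactly its constructed rule."""
        accepted, reports = filter_labels(fixture_set)
        assert len(accepted) == 4
        for i, r in enumerate(reports[:4]):
            assert r.accepted, i
        for rule, r in zip((1, 2, 3, 4), reports[4:]):
            assert r.failed_rules() == [rule]

    def test_empty_input(self):
        accepted, reports = filter_labels([])
        assert accepted == [] and reports == []

    def test_all_canonical_accepted(self):
        masks = [generate_phantom(PhantomSpec(grid_size=32, seed=s)).mask
                 for s in range(100)]
        accepted, _ = filter_labels(masks)
        assert len(accepted) == 100

    def test_order_preserved(self, fixture_set):
        accepted, _ = filter_labels(fixture_set)
        for a, b in zip(accepted, fixture_set[:4]):
            assert np.array_equal(a, b)

    def test_deterministic_reports(self, fixture_set):
        _, r1 = filter_labels(fixture_set)
        _, r2 = filter_labels(fixture_set)
        assert [r.verdicts for r in r1] == [r.verdicts for r in r2]

    def test_idempotent(self, fixture_set):
        accepted, _ = filter_labels(fixture_set)
        again, _ = filter_labels(accepted)
        assert len(again) == len(accepted)
        for a, b in zip(again, accepted):
            assert np.array_equal(a, b)

    def test_threshold_monotonicity(self):
        """Relaxing rule-3/rule-4 thresholds never shrinks the accepted set."""
        rng = np.random.default_rng(0)
        masks = []
        for i in range(300):
            kind = i % 3
            if kind == 0:
                masks.append(generate_phantom(PhantomSpec(grid_size=32, seed=i)).mask)
            else:
                masks.append(generate_malformed_mask((i % 4) + 1, seed=i))
        base = FilterConfig()
        loose = FilterConfig(min_foreground_fraction=0.001,
                             max_background_components=50)
        acc_base, _ = filter_labels(masks, base)
        acc_loose, _ = filter_labels(masks, loose)
        ids_base = {id(m) for m in acc_base}
        ids_loose = {id(m) for m in acc_loose}
        assert ids_base <= ids_loose

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FilterConfig(connectivity=6)
        with pytest.raises(ValueError):
            FilterConfig(min_foreground_fraction=0.0)
        with pytest.raises(ValueError):
            FilterConfig(max_background_components=-1)

    def test_invalid_mask_values_rejected(self):
        with pytest.raises(ValueError):
            screen_mask(np.full((8, 8), 7, dtype=np.uint8))
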