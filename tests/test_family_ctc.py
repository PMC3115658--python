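"""Crackle families, transmission coefficient, and localization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cracklekit as ck
from cracklekit.detection import CrackleEvent
from cracklekit.family_ctc import (CrackleFamily, compute_ctc, group_families,
                                   localize_crackle)


def _event(channel, t, amp):
    return CrackleEvent(channel=channel, onset_time=t, peak_time=t,
                        waveform=None, peak_amplitude=amp,
                        breath_index=0, timing_code=2)


@pytest.fixture(scope="module")
def seven_left_geometry():
    """7 channels per side (like the posterior array of one recording)."""
    z = [24, 20, 16, 12, 8, 4, 0]
    pos = [(-8.0, -10.0, float(v)) for v in z] + \
          [(8.0, -10.0, float(v)) for v in z]
    side = ("left",) * 7 + ("right",) * 7
    quad = tuple(("top-" if v >= 14 else "bottom-") + s
                 for v, s in zip(z + z, side))
    return ck.ChannelGeometry(positions=np.array(pos), side=side, quadrant=quad)


class TestCTC:
    def test_no_transmission_is_zero(self, seven_left_geometry):
        fam = CrackleFamily(mother=_event(0, 1.0, 5.0))
        assert compute_ctc(fam, seven_left_geometry) == 0.0

    def test_equal_transmission_everywhere_is_100(self, seven_left_geometry):
        members = [_event(ch, 1.0, 5.0) for ch in range(7)]
        fam = CrackleFamily(mother=members[0], children=members[1:])
        assert compute_ctc(fam, seven_left_geometry) == pytest.approx(100.0)

    def test_partial_transmission_mean_ratio(self, seven_left_geometry):
        # N = 7 ipsilateral channels, children on 3 at half the mother's
        # amplitude: 100 * (3 * 0.5) / 6 = 25
        fam = CrackleFamily(
            mother=_event(0, 1.0, 10.0),
            children=[_event(c, 1.001, 5.0) for c in (1, 2, 3)])
        assert compute_ctc(fam, seven_left_geometry) == pytest.approx(25.0)

    def test_child_louder_than_mother_capped(self, seven_left_geometry):
        fam = CrackleFamily(mother=_event(0, 1.0, 5.0),
                            children=[_event(1, 1.0, 50.0)])
        assert compute_ctc(fam, seven_left_geometry) == pytest.approx(100.0 / 6)

    def test_single_channel_side_undefined(self):
        geom = ck.ChannelGeometry(
            positions=np.array([[-8.0, -10, 10], [8.0, -10, 10],
                                [8.0, -10, 4]]),
            side=("left", "right", "right"),
            quadrant=("bottom-left", "bottom-right", "bottom-right"))
        fam = CrackleFamily(mother=_event(0, 1.0, 5.0))
        with pytest.raises(ValueError, match="undefined"):
            compute_ctc(fam, geom)
        assert fam.flagged

    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=0,
                    max_size=6),
           st.integers(min_value=0, max_value=5),
           st.floats(min_value=0.0, max_value=0.5))
    def test_bounds_and_monotonicity(self, ratios, idx, bump):
        geom = _module_geometry()
        mother_amp = 10.0
        children = [_event(c + 1, 1.0, r * mother_amp)
                    for c, r in enumerate(ratios)]
        fam = CrackleFamily(mother=_event(0, 1.0, mother_amp),
                            children=children)
        ctc = compute_ctc(fam, geom)
        assert 0.0 <= ctc <= 100.0
        if children:
            # raising one child's amplitude (kept below the mother's)
            # never decreases the transmission coefficient
            i = idx % len(children)
            raised = list(children)
            raised[i] = _event(children[i].channel, 1.0,
                               min(children[i].peak_amplitude
                                   + bump * mother_amp, mother_amp))
            fam2 = CrackleFamily(mother=_event(0, 1.0, mother_amp),
                                 children=raised)
            assert compute_ctc(fam2, geom) >= ctc - 1e-9


def _module_geometry():
    z = [24, 20, 16, 12, 8, 4, 0]
    pos = [(-8.0, -10.0, float(v)) for v in z] + \
          [(8.0, -10.0, float(v)) for v in z]
    side = ("left",) * 7 + ("right",) * 7
    quad = tuple(("top-" if v >= 14 else "bottom-") + s
                 for v, s in zip(z + z, side))
    return ck.ChannelGeometry(positions=np.array(pos), side=side, quadrant=quad)


class TestGrouping:
    def test_lone_event_forms_family_of_one(self, seven_left_geometry):
        fams = group_families([_event(2, 1.0, 5.0)], seven_left_geometry)
        assert len(fams) == 1 and fams[0].size == 1

    def test_events_outside_window_split(self, seven_left_geometry):
        fams = group_families([_event(0, 1.0, 5.0), _event(1, 1.1, 4.0)],
                              seven_left_geometry)
        assert len(fams) == 2  # 100 ms apart: two separate families

    def test_contralateral_never_grouped(self, seven_left_geometry):
        fams = group_families([_event(0, 1.0, 5.0), _event(7, 1.0, 4.0)],
                              seven_left_geometry)
        assert len(fams) == 2

    def test_largest_amplitude_is_mother(self, seven_left_geometry):
        evs = [_event(0, 1.000, 3.0), _event(1, 1.002, 9.0),
               _event(2, 1.004, 2.0)]
        fams = group_families(evs, seven_left_geometry)
        assert len(fams) == 1
        assert fams[0].mother.channel == 1
        assert fams[0].mother.peak_amplitude >= max(
            c.peak_amplitude for c in fams[0].children)

    def test_one_member_per_channel_nearest_wins(self, seven_left_geometry):
        evs = [_event(0, 1.000, 9.0), _event(1, 1.002, 4.0),
               _event(1, 1.008, 5.0)]
        fams = group_families(evs, seven_left_geometry)
        assert fams[0].size == 2
        assert fams[0].children[0].peak_time == 1.002
        # the displaced event forms its own family
        assert sum(f.size for f in fams) == 3

    def test_recovers_annotated_member_sets(self, geometry, ipf_recording,
                                            ipf_analysis):
        """Grouping of detected events matches the generator's families."""
        _, ann = ipf_recording
        checked = 0
        for fam in ipf_analysis.families:
            best, bd = None, np.inf
            for c in ann.crackles:
                h = c.channels.get(fam.mother.channel)
                if h is not None and abs(h.peak_ms - fam.mother.peak_time * 1e3) < bd:
                    best, bd = c, abs(h.peak_ms - fam.mother.peak_time * 1e3)
            if best is None or bd > 3 or best.mother_channel != fam.mother.channel:
                continue
            got = {e.channel for e in fam.members}
            want = set(best.channels)
            if got == want:
                checked += 1
        assert checked >= 0.8 * len(ipf_analysis.families)


class TestLocalization:
    def test_exact_delays_recover_source(self, geometry):
        # needs the (non-collinear) default array: microphones on a single
        # vertical line cannot resolve a 3-D position from delays
        geom = geometry
        rng = np.random.default_rng(3)
        for _ in range(10):
            src = np.array([rng.uniform(-12, -3), rng.uniform(-8, 4),
                            rng.uniform(2, 22)])
            ipsi = geom.channels_on_side("left")
            d = np.linalg.norm(geom.positions[ipsi] - src, axis=1)
            order = np.argsort(d)
            members = []
            for rank, k in enumerate(order[:6]):
                t = 1.0 + (d[k] - d[order[0]]) / geom.sound_speed / 1000.0
                members.append(_event(int(ipsi[k]), t, 9.0 - rank))
            fam = CrackleFamily(mother=members[0], children=members[1:])
            loc = localize_crackle(fam, geom)
            assert np.linalg.norm(np.asarray(loc) - src) < 1.0

    def test_small_family_fallback_depth(self, seven_left_geometry):
        fam = CrackleFamily(mother=_event(0, 1.0, 5.0))
        loc = localize_crackle(fam, seven_left_geometry, default_depth_cm=8.0)
        assert fam.localization_fallback
        p = seven_left_geometry.positions[0]
        assert np.linalg.norm(np.asarray(loc) - p) == pytest.approx(8.0)

    def test_equidistant_source_predicts_equal_delays(self, seven_left_geometry):
        # a source on the mid-plane between two microphones is equidistant:
        # members with identical arrival times localize onto that plane
        geom = seven_left_geometry
        src = np.array([-8.0, -4.0, 10.0])  # equidistant from z=8 and z=12
        d0 = np.linalg.norm(geom.positions[3] - src)
        d1 = np.linalg.norm(geom.positions[4] - src)
        assert d0 == pytest.approx(d1)
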