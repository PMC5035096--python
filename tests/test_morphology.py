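"""Morphology: SWC parsing, discretization geometry, morphometrics."""

import math

import numpy as np
import pytest

from is3screen.biophysics import PassiveParams, RegionPassiveMap
from is3screen.fixtures import FixtureMorphologySpec, TreeRecipe, make_fixture_morphology
from is3screen.morphology import (Morphology, MorphPoint, MorphologyError, Section,
                                  SWCParseError, compartmentalize, path_distance,
                                  read_swc, tree_stats, trim_axon, write_swc)

PASSIVE = RegionPassiveMap()


def cylinder_morph(length=100.0, diam=2.0, soma_diam=10.0):
    soma = Section(0, "soma", "soma",
                   [MorphPoint(0, 0, 0, soma_diam), MorphPoint(soma_diam, 0, 0, soma_diam)])
    dend = Section(1, "dendrite", "1",
                   [MorphPoint(soma_diam, 0, 0, diam), MorphPoint(soma_diam + length, 0, 0, diam)],
                   (0, 1.0))
    return Morphology([soma, dend], "cyl")


class TestReadSWC:
    def test_minimal_three_point_file(self, tmp_path):
        p = tmp_path / "m.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 1\n3 3 110 0 0 1 2\n")
        m = read_swc(p)
        regions = sorted(s.region for s in m.sections)
        assert regions == ["dendrite", "soma"]
        assert m.root.region == "soma"

    def test_orphan_parent_is_structural_error(self, tmp_path):
        p = tmp_path / "m.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 99\n")
        with pytest.raises(MorphologyError, match="parent"):
            read_swc(p)

    @pytest.mark.parametrize("content, match", [
        ("", "empty"),
        ("1 1 0 0 0 5\n", "7 columns"),
        ("1 1 0 0 x 5 -1\n", "line 1"),
        ("1 1 0 0 0 0 -1\n", "radius"),
    ])
    def test_malformed_content_reports_line(self, tmp_path, content, match):
        p = tmp_path / "m.swc"
        p.write_text(content)
        with pytest.raises(SWCParseError, match=match):
            read_swc(p)

    def test_roundtrip_preserves_geometry(self, tmp_path, fixture_morph):
        p = tmp_path / "fx.swc"
        write_swc(fixture_morph, p)
        back = read_swc(p)
        assert back.total_surface_area() == pytest.approx(
            fixture_morph.total_surface_area(), rel=1e-6)
        orig = tree_stats(fixture_morph)
        rt = tree_stats(back)
        assert [t.n_branch_points for t in rt] == [t.n_branch_points for t in orig]
        for a, b in zip(orig, rt):
            assert b.surface_area == pytest.approx(a.surface_area, rel=1e-5)
            assert b.summed_length == pytest.approx(a.summed_length, rel=1e-5)


class TestCompartmentalize:
    def test_single_compartment_cylinder_area(self):
        m = cylinder_morph(length=100.0, diam=2.0)
        cm = compartmentalize(m, "fixed", max_length=1000.0, passive=PASSIVE)
        dend = [c for c in cm.compartments if c.region == "dendrite"]
        assert len(dend) == 1
        assert dend[0].a == 0.0 and dend[0].b == 1.0
        assert dend[0].surface_area == pytest.approx(math.pi * 2.0 * 100.0, rel=1e-9)

    def test_tapered_section_matches_fine_frustum_integration(self):
        soma = Section(0, "soma", "soma",
                       [MorphPoint(0, 0, 0, 10), MorphPoint(10, 0, 0, 10)])
        dend = Section(1, "dendrite", "1",
                       [MorphPoint(10, 0, 0, 3.0), MorphPoint(210, 0, 0, 0.5)],
                       (0, 1.0))
        m = Morphology([soma, dend], "taper")
        cm = compartmentalize(m, "fixed", max_length=7.0, passive=PASSIVE)
        got = sum(c.surface_area for c in cm.compartments if c.region == "dendrite")
        # oracle: 10^4-slice numerical frustum integration
        n = 10_000
        x = np.linspace(0, 200, n + 1)
        d = 3.0 + (0.5 - 3.0) * x / 200.0
        slices = math.pi * 0.5 * (d[:-1] + d[1:]) * np.diff(x)
        assert got == pytest.approx(float(slices.sum()), rel=5e-3)

    def test_area_invariant_under_resolution(self, fixture_morph):
        areas = []
        for max_len in (5.0, 11.0, 40.0):
            cm = compartmentalize(fixture_morph, "fixed", max_length=max_len,
                                  passive=PASSIVE)
            areas.append(cm.total_surface_area())
        assert max(areas) / min(areas) - 1 < 5e-3
        assert areas[0] == pytest.approx(fixture_morph.total_surface_area(), rel=5e-3)

    def test_compartments_tile_each_section(self, comp_model):
        by_sec = {}
        for c in comp_model.compartments:
            by_sec.setdefault(c.section_id, []).append(c)
        for comps in by_sec.values():
            comps.sort(key=lambda c: c.a)
            assert comps[0].a == 0.0 and comps[-1].b == 1.0
            assert len(comps) % 2 == 1
            for left, right in zip(comps[:-1], comps[1:]):
                assert left.b == pytest.approx(right.a)

    def test_odd_compartment_counts(self, comp_model):
        by_sec = {}
        for c in comp_model.compartments:
            by_sec.setdefault(c.section_id, []).append(c)
        assert all(len(v) % 2 == 1 for v in by_sec.values())


class TestTrimAxon:
    def test_truncates_to_requested_length(self):
        soma = Section(0, "soma", "soma",
                       [MorphPoint(0, 0, 0, 10), MorphPoint(10, 0, 0, 10)])
        axon = Section(1, "axon", "axon",
                       [MorphPoint(0, 0, 0, 1), MorphPoint(-200, 0, 0, 1)], (0, 0.0))
        m = Morphology([soma, axon], "ax")
        trimmed = trim_axon(m, 20.0)
        ax = [s for s in trimmed.sections if s.region == "axon"]
        assert sum(s.length for s in ax) == pytest.approx(20.0)

    def test_no_axon_is_noop(self):
        m = cylinder_morph()
        out = trim_axon(m, 20.0)
        assert out.total_surface_area() == pytest.approx(m.total_surface_area())

    def test_area_strictly_decreases_and_dendrites_untouched(self, fixture_morph):
        trimmed = trim_axon(fixture_morph, 10.0)
        assert trimmed.total_surface_area() < fixture_morph.total_surface_area()
        before = [t for t in tree_stats(fixture_morph) if t.tree_label != "axon"]
        after = [t for t in tree_stats(trimmed) if t.tree_label != "axon"]
        for a, b in zip(before, after):
            assert a == b

    def test_zero_keep_length_removes_axon_with_warning(self, fixture_morph):
        with pytest.warns(UserWarning):
            out = trim_axon(fixture_morph, 0.0)
        assert all(s.region != "axon" for s in out.sections)


class TestPathDistance:
    def test_soma_center_is_zero(self, fixture_morph):
        assert path_distance(fixture_morph, (0, 0.5)) == 0.0

    def test_first_order_dendrite_end(self):
        m = cylinder_morph(length=100.0, soma_diam=10.0)
        # soma half-length (5 um) is included by convention
        assert path_distance(m, (1, 1.0)) == pytest.approx(105.0)

    def test_grandchild_matches_brute_force_walk(self, fixture_morph):
        # deepest section of tree 2A: sum segment lengths by hand
        secs = [s for s in fixture_morph.sections if s.tree_label == "2A"]
        tip = max(secs, key=lambda s: path_distance(fixture_morph, (s.id, 1.0)))
        expected = 0.6 * tip.length
        cur = tip
        while cur.parent is not None:
            pid, pfrac = cur.parent
            parent = fixture_morph.section(pid)
            if parent.parent is None:
                expected += abs(pfrac * parent.length - 0.5 * parent.length)
                break
            expected += pfrac * parent.length
            cur = parent
        assert path_distance(fixture_morph, (tip.id, 0.6)) == pytest.approx(expected)

    def test_monotone_along_root_to_tip_walk(self, fixture_morph):
        for sec in fixture_morph.sections:
            if sec.parent is None:
                continue
            d = [path_distance(fixture_morph, (sec.id, f)) for f in np.linspace(0, 1, 7)]
            assert all(b >= a - 1e-9 for a, b in zip(d[:-1], d[1:]))

    def test_fraction_out_of_range_raises(self, fixture_morph):
        with pytest.raises(MorphologyError):
            path_distance(fixture_morph, (0, 1.5))


class TestTreeStats:
    def test_unbranched_dendrite(self):
        m = cylinder_morph(length=100.0)
        (t,) = tree_stats(m)
        assert t.n_branch_points == 0
        assert t.summed_length == pytest.approx(t.max_distal_length)

    def test_branch_point_counts_follow_recipe(self):
        spec = FixtureMorphologySpec(trees=(
            TreeRecipe("1", 100.0, (50.0, 30.0)),
            TreeRecipe("2A", 60.0, (40.0, 30.0, 20.0), azimuth_deg=-60.0),
            TreeRecipe("2B", 60.0, (40.0, 30.0, 20.0), azimuth_deg=-120.0),
        ))
        m = make_fixture_morphology(spec)
        stats = {t.tree_label: t for t in tree_stats(m)}
        assert stats["1"].n_branch_points == 3   # depth 2: 2^2 - 1
        assert stats["2A"].n_branch_points == 7  # depth 3: 2^3 - 1
        assert stats["2B"].n_branch_points == 7
        for label, recipe in (("1", spec.trees[0]), ("2A", spec.trees[1])):
            assert stats[label].summed_length == pytest.approx(recipe.total_length)
            assert stats[label].max_distal_length == pytest.approx(recipe.max_distal_length)
            assert stats[label].summed_length >= stats[label].max_distal_length


class TestStructuralValidation:
    def test_two_roots_rejected(self):
        a = Section(0, "soma", "soma", [MorphPoint(0, 0, 0, 5), MorphPoint(5, 0, 0, 5)])
        b = Section(1, "soma", "soma", [MorphPoint(9, 0, 0, 5), MorphPoint(14, 0, 0, 5)])
        with pytest.raises(MorphologyError, match="root"):
            Morphology([a, b])

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(MorphologyError, match="diameter"):
            MorphPoint(0, 0, 0, 0.0)
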