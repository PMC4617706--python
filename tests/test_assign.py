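"""EPD scoring, consensus profiles, threshold calibration, assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epasis as ep

STEPS = ["s1", "s2", "s3", "s4", "s5"]


def pset_from(profiles: dict[str, list[float]], steps=None) -> ep.ElutionProfileSet:
    steps = steps if steps is not None else STEPS[: len(next(iter(profiles.values())))]
    return ep.ElutionProfileSet(
        profiles=pd.DataFrame.from_dict(profiles, orient="index", columns=steps),
        steps=steps,
    )


@st.composite
def cumulative_profiles(draw, n_steps=5):
    """Random valid cumulative profiles: monotone in [0,1], ending at 1."""
    raw = draw(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0), min_size=n_steps, max_size=n_steps
        ).filter(lambda v: sum(v) > 0)
    )
    v = np.asarray(raw)
    return np.cumsum(v) / v.sum()


class TestConsensus:
    def test_identical_members_give_their_profile(self):
        p = [0.1, 0.4, 0.8, 0.9, 1.0]
        pset = pset_from({"A": p, "B": p})
        mod = ep.build_consensus(pset, ["A", "B"], "M")
        np.testing.assert_allclose(mod.consensus_profile, p)

    def test_mean_of_two(self):
        pset = pset_from({"A": [0.0, 1.0], "B": [1.0, 1.0]})
        mod = ep.build_consensus(pset, ["A", "B"], "M")
        np.testing.assert_allclose(mod.consensus_profile, [0.5, 1.0])

    def test_empty_member_list_rejected(self):
        pset = pset_from({"A": [0.0, 1.0]})
        with pytest.raises(ValueError):
            ep.build_consensus(pset, [], "M")

    def test_missing_members_reported_not_dropped(self):
        pset = pset_from({"A": [0.0, 1.0]})
        mod = ep.build_consensus(pset, ["A", "GHOST"], "M")
        assert mod.missing_members == ["GHOST"]
        with pytest.raises(ValueError):
            ep.build_consensus(pset, ["GHOST"], "M")


class TestComputeEPD:
    def test_identity_and_unit_difference(self):
        p = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
        assert ep.compute_epd(p, p) == 0.0
        assert ep.compute_epd(np.array([0.0, 1.0]), np.array([1.0, 1.0])) == pytest.approx(1.0)

    def test_normalized_dialect_scales_by_sqrt_steps(self):
        p, c = np.array([0.0, 1.0]), np.array([1.0, 1.0])
        assert ep.compute_epd(p, c, normalized=True) == pytest.approx(1 / np.sqrt(2))

    def test_mismatched_axes_rejected(self):
        with pytest.raises(ValueError):
            ep.compute_epd(np.zeros(5), np.zeros(4))

    @settings(max_examples=100, deadline=None)
    @given(cumulative_profiles(), cumulative_profiles(), cumulative_profiles())
    def test_metric_axioms(self, p, q, r):
        """Non-negativity, identity, symmetry, triangle inequality."""
        dpq = ep.compute_epd(p, q)
        assert dpq >= 0
        assert ep.compute_epd(p, p) == 0.0
        assert dpq == pytest.approx(ep.compute_epd(q, p))
        assert dpq <= ep.compute_epd(p, r) + ep.compute_epd(r, q) + 1e-9


class TestEPDTable:
    def test_single_protein_equal_to_consensus(self):
        p = [0.1, 0.5, 1.0]
        pset = pset_from({"A": p}, steps=["s1", "s2", "s3"])
        mod = ep.build_consensus(pset, ["A"], "M")
        t = ep.epd_table(pset, [mod])
        assert t.epd.at["A", "M"] == 0.0
        assert t.nearest["A"] == "M"

    def test_tie_breaks_to_lexicographically_smaller_module(self):
        pset = pset_from({"X": [0.5, 1.0], "a": [0.0, 1.0], "b": [1.0, 1.0]})
        ma = ep.build_consensus(pset, ["a"], "B")
        mb = ep.build_consensus(pset, ["b"], "A")
        t = ep.epd_table(pset, [ma, mb])
        assert t.epd.at["X", "A"] == pytest.approx(t.epd.at["X", "B"])
        assert t.nearest["X"] == "A"

    def test_matches_entrywise_oracle(self, noisy_default):
        """Brute-force oracle: compute_epd called per (protein, module)."""
        _, matrix, truth = noisy_default
        pset = ep.build_profiles(ep.presence_filter(matrix))
        mods = [ep.build_consensus(pset, mem, name) for name, mem in truth.members().items()]
        t = ep.epd_table(pset, mods)
        for acc in t.accessions:
            for mod in mods:
                assert t.epd.at[acc, mod.name] == pytest.approx(
                    ep.compute_epd(pset.vector(acc), mod), abs=1e-12
                )

    def test_leave_one_out_dialect_excludes_self(self):
        pset = pset_from({"A": [0.0, 1.0], "B": [1.0, 1.0]})
        mod = ep.build_consensus(pset, ["A", "B"], "M")
        t = ep.epd_table(pset, [mod], leave_one_out=True)
        # A scored against consensus built from B alone
        assert t.epd.at["A", "M"] == pytest.approx(1.0)


class TestThresholdSearch:
    def test_perfectly_separated_data(self, noise_free):
        """Zero-noise members sit on their consensus; the other module is far."""
        _, matrix, truth = noise_free
        pset = ep.build_profiles(ep.presence_filter(matrix))
        mods = [ep.build_consensus(pset, mem, name) for name, mem in truth.members().items()]
        t = ep.epd_table(pset, mods)
        res = ep.threshold_search(t, mods, n_steps=1000)
        inside = (res.grid > 0.01) & (res.grid < 0.5)
        assert inside.any()
        assert np.all(res.sensitivity[inside] == 1.0)
        assert np.all(res.specificity[inside] == 1.0)
        assert 0.0 < res.selected_threshold < 0.5

    def test_sensitivity_monotone_specificity_antitone(self, noisy_default):
        _, matrix, truth = noisy_default
        pset = ep.build_profiles(ep.presence_filter(matrix))
        mods = [ep.build_consensus(pset, mem, name) for name, mem in truth.members().items()]
        res = ep.threshold_search(ep.epd_table(pset, mods), mods, n_steps=1000)
        assert np.all(np.diff(res.sensitivity) >= 0)
        assert np.all(np.diff(res.specificity) <= 0)
        assert np.all(np.diff(res.grid) > 0)

    def test_single_module_without_negatives_rejected(self):
        pset = pset_from({"A": [0.0, 1.0], "B": [0.5, 1.0]})
        mod = ep.build_consensus(pset, ["A", "B"], "M")
        with pytest.raises(ValueError):
            ep.threshold_search(ep.epd_table(pset, [mod]), [mod])

    def test_counts_match_assignment_at_selected_threshold(self, noisy_default):
        _, matrix, truth = noisy_default
        pset = ep.build_profiles(ep.presence_filter(matrix))
        mods = [ep.build_consensus(pset, mem, name) for name, mem in truth.members().items()]
        t = ep.epd_table(pset, mods)
        res = ep.threshold_search(t, mods)
        a = ep.assign_modules(t, mods, res.selected_threshold)
        assert (res.n_reference, res.n_candidates) == (a.n_reference, a.n_candidates)


class TestAssignModules:
    @pytest.fixture
    def scored(self, noisy_default):
        _, matrix, truth = noisy_default
        pset = ep.build_profiles(ep.presence_filter(matrix))
        mods = [ep.build_consensus(pset, mem, name) for name, mem in truth.members().items()]
        return ep.epd_table(pset, mods), mods

    def test_threshold_zero_assigns_only_exact_matches(self, scored):
        t, mods = scored
        a = ep.assign_modules(t, mods, 0.0)
        assigned = a.table[a.table["category"] != "unknown"]
        assert (assigned["epd_min"] == 0.0).all()

    def test_threshold_at_max_leaves_nothing_unknown(self, scored):
        t, mods = scored
        a = ep.assign_modules(t, mods, float(t.epd.to_numpy().max()))
        assert (a.table["category"] != "unknown").all()

    def test_monotone_in_threshold(self, scored):
        """Raising the threshold never un-assigns a protein."""
        t, mods = scored
        lo = ep.assign_modules(t, mods, 0.05).table["category"]
        hi = ep.assign_modules(t, mods, 0.15).table["category"]
        moved_to_unknown = (lo != "unknown") & (hi == "unknown")
        assert not moved_to_unknown.any()

    def test_candidate_labels_only_for_non_members(self, scored):
        t, mods = scored
        members = {acc for m in mods for acc in m.members}
        a = ep.assign_modules(t, mods, 0.1)
        for acc, cat in a.table["category"].items():
            if cat.endswith("_cand"):
                assert acc not in members
            elif cat != "unknown":
                assert acc in members

    def test_curated_label_governs_conflicts(self):
        """A member sitting exactly on the *other* consensus keeps its curated
        semantics: reference only if within threshold of its own module,
        otherwise unknown — never relabelled as the other module."""
        pset = pset_from(
            {"a1": [0.0, 0.2, 1.0], "a2": [0.0, 0.4, 1.0], "b1": [0.9, 1.0, 1.0],
             "rogue": [0.9, 1.0, 1.0]},
            steps=["s1", "s2", "s3"],
        )
        ma = ep.build_consensus(pset, ["a1", "a2", "rogue"], "A")
        mb = ep.build_consensus(pset, ["b1"], "B")
        t = ep.epd_table(pset, [ma, mb])
        assert t.nearest["rogue"] == "B"  # data-driven nearest is visible
        tight = ep.assign_modules(t, [ma, mb], 0.05)
        assert tight.table.at["rogue", "category"] == "unknown"
        loose = ep.assign_modules(t, [ma, mb], float(t.epd.at["rogue", "A"]))
        assert loose.table.at["rogue", "category"] == "A"
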