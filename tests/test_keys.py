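"""Published discriminant scorers and the dichotomous key engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numobat import keys


class TestScorers:
    def test_intercepts_at_zero_vector(self):
        assert keys.D5A.coefficients and keys.D5A.intercept == 2.974
        zero = {t: 0.0 for t in keys.D5A.coefficients}
        # the mm-guard only triggers for small positive values, not zeros
        assert keys.D5A.score(zero) == pytest.approx(2.974, abs=1e-12)
        assert keys.D3.score({t: 0.0 for t in keys.D3.coefficients}) == pytest.approx(-9.973)
        assert keys.D5B.score({t: 0.0 for t in keys.D5B.coefficients}) == pytest.approx(5.703)

    def test_hand_computed_gyne_pair_separator(self):
        score, species, note = keys.score_D5a(CW=600, FR=205, SPWI=238, ML=902, SPST=176)
        assert score == pytest.approx(1.675, abs=1e-9)
        assert species == "adlerzi" and note == "in-range"

    def test_hand_computed_three_trait_gyne_separator(self):
        score, species, _ = keys.score_D3(ELmax=160, SL=420, SPH=190)
        assert score == pytest.approx(-3.353, abs=1e-9)
        assert species == "algerianus"

    def test_hand_computed_worker_separator(self):
        score, species, _ = keys.score_D5b(SL=430, SPBA=215, PPW=280, SPH=185, ELmax=150)
        assert score == pytest.approx(-0.952, abs=1e-9)
        assert species == "ravouxi"

    def test_missing_trait_error_lists_names(self):
        with pytest.raises(ValueError, match="SPST"):
            keys.D5A.score({"CW": 600, "FR": 205, "SPWI": 238, "ML": 902})

    def test_millimetre_inputs_refused(self):
        with pytest.raises(ValueError, match="mm|millimetre"):
            keys.score_D5a(CW=0.6, FR=0.205, SPWI=0.238, ML=0.902, SPST=0.176)

    def test_out_of_range_score_annotated(self):
        # absurdly large head width drives the score far above the
        # published range for either species
        _, _, note = keys.score_D5a(CW=4000, FR=205, SPWI=238, ML=902, SPST=176)
        assert note.startswith("out-of-range")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=10, max_value=2000), min_size=10, max_size=10))
    def test_scorers_are_linear(self, values):
        """score(x+y) − score(x) − score(y) + intercept == 0."""
        for scorer in (keys.D5A, keys.D3, keys.D5B):
            traits = list(scorer.coefficients)
            x = dict(zip(traits, values[: len(traits)]))
            y = dict(zip(traits, values[5 : 5 + len(traits)]))
            xy = {t: x[t] + y[t] for t in traits}
            lhs = scorer.score(xy) - scorer.score(x) - scorer.score(y) + scorer.intercept
            assert lhs == pytest.approx(0.0, abs=1e-6)


class TestGyneKey:
    def test_canary_endemic(self):
        ident = keys.run_key(keys.KeyObservation(caste="gyne", region="canary_islands"))
        assert ident.species == ["birgitae"]

    def test_flat_clypeus_leads_to_stumperi(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="gyne", region="north_spain_to_turkiye",
                funiculus_segments=10, clypeus_margin="flat",
            )
        )
        assert ident.species == ["stumperi"]

    def test_eleven_segmented_funiculus_pontic(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="gyne", funiculus_segments=11, region="pontic_mediterranean"
            )
        )
        assert ident.species == ["microcellatus"]

    def test_shiny_smooth_frons_is_bernardi(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="gyne", funiculus_segments=10, clypeus_margin="convex",
                frons_sculpture="shiny_smooth", region="north_spain_to_turkiye",
            )
        )
        assert ident.species == ["bernardi"]

    def test_long_petiole_hair_is_kraussei(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="gyne", funiculus_segments=10, clypeus_margin="convex",
                frons_sculpture="dull_areolate", petiole_hair_max=150,
                region="north_spain_to_turkiye",
            )
        )
        assert ident.species == ["kraussei"]

    def test_short_hair_dull_frons_pair_deferred_to_scorer(self):
        obs = keys.KeyObservation(
            caste="gyne", funiculus_segments=10, clypeus_margin="convex",
            frons_sculpture="dull_areolate", petiole_hair_max=120,
            region="north_spain_to_turkiye",
            traits={"CW": 600, "FRS": 205, "SPWI": 238, "ML": 902, "SPST": 176},
        )
        ident = keys.run_key(obs)
        assert ident.species == ["adlerzi"]
        assert ident.scores["D5a"]["score"] == pytest.approx(1.675, abs=1e-9)

    def test_pair_without_traits_stays_ambiguous(self):
        obs = keys.KeyObservation(
            caste="gyne", funiculus_segments=10, clypeus_margin="convex",
            frons_sculpture="dull_areolate", petiole_hair_max=120,
            region="north_spain_to_turkiye",
        )
        ident = keys.run_key(obs)
        assert sorted(ident.species) == ["adlerzi", "ravouxi"]

    def test_no_characters_reaches_all_species(self):
        ident = keys.run_key(keys.KeyObservation(caste="gyne"))
        assert len(ident.species) == 10
        assert any("ambiguous" in n for n in ident.notes)

    def test_contradiction_reported_not_crashed(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="gyne", region="canary_islands", funiculus_segments=11
            )
        )
        assert any("contradiction" in n for n in ident.notes)


class TestWorkerKey:
    def test_straight_propodeum_eleven_segments(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="worker", funiculus_segments=11, propodeum_dorsal_contour="straight"
            )
        )
        assert ident.species == ["gordiagini"]

    def test_hair_just_above_threshold_is_kraussei(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="worker", funiculus_segments=10, clypeus_margin="convex",
                frons_sculpture="dull_areolate", petiole_hair_max=130,
                region="north_spain_to_turkiye",
            )
        )
        assert ident.species == ["kraussei"]  # 130 > 125, within [125, 147]
        assert not any("envelope" in n for n in ident.notes)

    def test_hair_exactly_at_threshold_goes_else_with_warning(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="worker", funiculus_segments=10, clypeus_margin="convex",
                frons_sculpture="dull_areolate", petiole_hair_max=125,
                region="north_spain_to_turkiye",
            )
        )
        assert "kraussei" not in ident.species
        assert any("borderline" in n for n in ident.notes)

    def test_kraussei_hair_envelope_annotation(self):
        ident = keys.run_key(
            keys.KeyObservation(
                caste="worker", funiculus_segments=10, clypeus_margin="convex",
                frons_sculpture="dull_areolate", petiole_hair_max=160,
            )
        )
        assert ident.species == ["kraussei"]
        assert any("[125, 147]" in n for n in ident.notes)

    def test_short_hair_region_splits(self):
        south = keys.run_key(
            keys.KeyObservation(
                caste="worker", funiculus_segments=10, clypeus_margin="convex",
                frons_sculpture="dull_areolate", petiole_hair_max=100,
                region="north_africa_south_spain",
            )
        )
        assert south.species == ["algerianus"]
        north = keys.run_key(
            keys.KeyObservation(
                caste="worker", funiculus_segments=10, clypeus_margin="convex",
                frons_sculpture="dull_areolate", petiole_hair_max=100,
                region="north_spain_to_turkiye",
            )
        )
        assert north.species == ["ravouxi"]

    def test_ravouxi_hair_envelope(self):
        # 84 μm is below every published worker envelope for this branch
        ident = keys.run_key(
            keys.KeyObservation(
                caste="worker", funiculus_segments=10, clypeus_margin="convex",
                frons_sculpture="dull_areolate", petiole_hair_max=84,
                region="north_spain_to_turkiye",
            )
        )
        assert ident.species == ["ravouxi"]
        assert any("envelope" in n for n in ident.notes)

    def test_replaying_path_is_deterministic(self):
        obs = keys.KeyObservation(
            caste="worker", funiculus_segments=10, clypeus_margin="convex",
            frons_sculpture="dull_areolate", petiole_hair_max=130,
        )
        a, b = keys.run_key(obs), keys.run_key(obs)
        assert a.path == b.path and a.species == b.species

    def test_caste_required(self):
        with pytest.raises(ValueError):
            keys.KeyObservation(caste="male")
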