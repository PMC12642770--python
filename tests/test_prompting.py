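"""Prompt rendering purity, the temperature schedule, and response cleaning."""

import json

import pytest

from gifms.fragmenter import FragmentRecord, enumerate_fragments
from gifms.pipeline import assign_mz
from gifms.prompting import (
    ResponseFormatError,
    TAG_FRAGMENTS_MZ,
    TAG_FRAGMENT_TASK,
    TAG_INTENSITY_TASK,
    TAG_MOL,
    TAG_NUM_INVALID,
    TAG_SETTINGS,
    TAG_VALID_FRAGMENTS,
    build_fragment_prompt,
    build_fragment_refinement_prompt,
    build_intensity_prompt,
    extract_payload,
    parse_fragment_response,
    parse_intensity_response,
)


@pytest.fixture
def fragments_with_mz(ethanol):
    return assign_mz(list(enumerate_fragments(ethanol, 1)), "[M+H]+")


class TestFragmentPrompt:
    def test_carries_all_tags(self, ethanol, settings):
        bundle = build_fragment_prompt(ethanol, settings)
        for tag in (TAG_FRAGMENT_TASK, TAG_MOL, TAG_SETTINGS):
            assert tag in bundle.user_text
        assert "descending intensity" in bundle.user_text

    def test_rendering_is_pure(self, ethanol, settings):
        assert build_fragment_prompt(ethanol, settings) == build_fragment_prompt(ethanol, settings)

    def test_payloads_decode(self, ethanol, settings):
        bundle = build_fragment_prompt(ethanol, settings)
        assert extract_payload(bundle.user_text, TAG_MOL) == {"smiles": ethanol.smiles}
        payload = extract_payload(bundle.user_text, TAG_SETTINGS)
        assert payload["adduct"] == settings.adduct

    def test_initial_temperature_is_exploratory(self, ethanol, settings):
        assert build_fragment_prompt(ethanol, settings).temperature == 0.9

    def test_system_prompt_states_domain(self, ethanol, settings):
        assert "mass spectrometry" in build_fragment_prompt(ethanol, settings).system_text


class TestRefinementPrompt:
    @pytest.mark.parametrize("iteration, temperature", [(1, 0.9), (2, 0.9), (4, 0.9), (5, 0.1)])
    def test_temperature_schedule(self, ethanol, settings, iteration, temperature):
        bundle = build_fragment_refinement_prompt(
            ethanol, settings, [], n_invalid=0, iteration_index=iteration, n_iterations=5
        )
        assert bundle.temperature == temperature

    def test_embeds_survivors_and_invalid_count(self, ethanol, settings):
        survivors = [FragmentRecord.from_record(ethanol)]
        bundle = build_fragment_refinement_prompt(
            ethanol, settings, survivors, n_invalid=2, iteration_index=1
        )
        assert extract_payload(bundle.user_text, TAG_VALID_FRAGMENTS) == [ethanol.smiles]
        assert extract_payload(bundle.user_text, TAG_NUM_INVALID) == {"n_invalid": 2}

    def test_zero_invalid_stated(self, ethanol, settings):
        bundle = build_fragment_refinement_prompt(
            ethanol, settings, [], n_invalid=0, iteration_index=1
        )
        assert extract_payload(bundle.user_text, TAG_NUM_INVALID) == {"n_invalid": 0}

    def test_iteration_bounds(self, ethanol, settings):
        with pytest.raises(ValueError):
            build_fragment_refinement_prompt(ethanol, settings, [], 0, iteration_index=0)


class TestIntensityPrompt:
    def test_enumerates_every_mz_in_order(self, ethanol, settings, fragments_with_mz):
        bundle = build_intensity_prompt(ethanol, settings, fragments_with_mz)
        payload = extract_payload(bundle.user_text, TAG_FRAGMENTS_MZ)
        assert len(payload) == len(fragments_with_mz)
        assert [e["mz"] for e in payload] == [round(f.mz, 4) for f in fragments_with_mz]

    def test_low_temperature(self, ethanol, settings, fragments_with_mz):
        bundle = build_intensity_prompt(ethanol, settings, fragments_with_mz)
        assert bundle.temperature == 0.1
        assert bundle.task_tag == TAG_INTENSITY_TASK

    def test_requires_assigned_mz(self, ethanol, settings):
        with pytest.raises(ValueError):
            build_intensity_prompt(ethanol, settings, [FragmentRecord.from_record(ethanol)])


class TestParseFragmentResponse:
    def test_clean_payload(self):
        strings, report = parse_fragment_response('["CC", "CO"]')
        assert strings == ["CC", "CO"]
        assert report.rejected_count == 0

    def test_code_fence_stripped(self):
        strings, _ = parse_fragment_response('```json\n["CC"]\n```')
        assert strings == ["CC"]

    def test_leading_prose_tolerated(self):
        strings, _ = parse_fragment_response('Here are the fragments: ["CC", "C"] as requested.')
        assert strings == ["CC", "C"]

    def test_no_array_raises(self):
        with pytest.raises(ResponseFormatError):
            parse_fragment_response("no fragments")

    def test_non_string_entries_malformed(self):
        strings, report = parse_fragment_response('["CC", 42, {"a": 1}]')
        assert strings == ["CC"]
        assert report.rejection_reasons["malformed_entry"] == 2
        assert len(report.accepted) + report.rejected_count == 3


class TestParseIntensityResponse:
    QUERIED = [76.0393, 79.0542, 100.1234]

    def test_clean_entries_accepted(self):
        text = json.dumps([{"mz": 76.0393, "intensity": 5}, {"mz": 79.0542, "intensity": 10}])
        pairs, report = parse_intensity_response(text, self.QUERIED)
        assert pairs == [(76.0393, 5), (79.0542, 10)]
        assert report.rejected_count == 0

    def test_duplicate_mz_first_wins(self):
        text = json.dumps([{"mz": 76.0393, "intensity": 5}, {"mz": 76.0393, "intensity": 7}])
        pairs, report = parse_intensity_response(text, self.QUERIED)
        assert pairs == [(76.0393, 5)]
        assert report.rejection_reasons["duplicate_mz"] == 1

    def test_unqueried_mz_rejected(self):
        text = json.dumps([{"mz": 55.055, "intensity": 5}])
        pairs, report = parse_intensity_response(text, self.QUERIED)
        assert pairs == []
        assert report.rejection_reasons["unqueried_mz"] == 1

    @pytest.mark.parametrize("level", [0, 11, "high", 5.5, None, True])
    def test_invalid_intensity_rejected(self, level):
        text = json.dumps([{"mz": 76.0393, "intensity": level}])
        pairs, report = parse_intensity_response(text, self.QUERIED)
        assert pairs == []
        assert report.rejection_reasons["invalid_intensity"] == 1

    def test_malformed_entries_counted(self):
        text = json.dumps(["nope", {"intensity": 3}, {"mz": "x", "intensity": 3}])
        _, report = parse_intensity_response(text, self.QUERIED)
        assert report.rejection_reasons["malformed_entry"] == 3

    def test_accounting_invariant(self):
        text = json.dumps(
            [
                {"mz": 76.0393, "intensity": 5},
                {"mz": 76.0393, "intensity": 6},
                {"mz": 1.0, "intensity": 5},
                {"mz": 79.0542, "intensity": 99},
                "garbage",
            ]
        )
        pairs, report = parse_intensity_response(text, self.QUERIED)
        assert len(report.accepted) + report.rejected_count == 5
        assert pairs == [(76.0393, 5)]

    def test_requires_queried_values(self):
        with pytest.raises(ValueError):
            parse_intensity_response("[]", [])
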