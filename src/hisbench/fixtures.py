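"""Bundled worked-example fixtures.

``khon_kaen_2019`` is the full 45-indicator, 15-element, 4-dimension
framework with its published HIS ideals, the consensus expert judgment
matrices, the Khon Kaen (Thailand) 2019 observation, and the strategy
overrides.  Indicators whose standard publishes only one side carry the
reconciled substitute for the other side (0, except a floor of 1 for the
two mortality rates VR03 and VR13), recorded separately from the
published values.
"""

from __future__ import annotations

from importlib import resources
from typing import NamedTuple

from .ahp import PairwiseMatrix, pcm_from_block
from .framework import CityObservation, Framework, load_city_observation, load_document

__all__ = ["FixtureBundle", "bundled_fixture", "list_fixtures"]

_FIXTURES = {
    "khon_kaen_2019": ("khon_kaen_2019.yaml", "khon_kaen_2019_observation.csv"),
}


class FixtureBundle(NamedTuple):
    framework: Framework
    observation: CityObservation
    pcms: dict[str, PairwiseMatrix]
    strategy_overrides: dict[str, int]


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def bundled_fixture(name: str = "khon_kaen_2019") -> FixtureBundle:
    """Load a bundled fixture by name."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(list_fixtures())}"
        )
    yaml_name, csv_name = _FIXTURES[name]
    data = resources.files("hisbench.data")
    framework, pcm_blocks, overrides = load_document(
        (data / yaml_name).read_text())
    pcms = {g: pcm_from_block(g, b) for g, b in pcm_blocks.items()}
    observation = load_city_observation((data / csv_name).read_text(), framework)
    return FixtureBundle(framework, observation, pcms, overrides)
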