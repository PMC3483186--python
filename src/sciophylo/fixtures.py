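"""Loaders for the packaged study data (tree + character codings)."""

from __future__ import annotations

from importlib import resources

from .characters import CharacterMatrix, read_character_table
from .trees import Tree, read_newick

__all__ = [
    "load_study_tree",
    "load_study_characters",
    "binary_habitat",
    "dec_habitat_ranges",
    "FEEDING_STATES",
]

#: the 12 feeding-group states, in fixture order
FEEDING_STATES = (
    "aquatic_snail_predator",
    "clam_parasitoid_above",
    "clam_parasitoid_below",
    "millipede_parasitoid",
    "shoreline_saprophage",
    "shoreline_snail_predator",
    "slug_parasitoid",
    "snail_egg_predator",
    "submerged_snail_predator",
    "succineid_parasitoid",
    "terrestrial_snail_predator",
    "yeast_mold",
)


def _data(name: str):
    return resources.files("sciophylo.data").joinpath(name)


def load_study_tree() -> Tree:
    return read_newick(_data("sciomyzidae_tree.nwk").read_text())


def load_study_characters() -> CharacterMatrix:
    with resources.as_file(_data("sciomyzidae_characters.tsv")) as path:
        return read_character_table(path)


def binary_habitat(matrix: CharacterMatrix | None = None) -> dict[str, str]:
    """taxon -> 'aquatic'/'terrestrial'/'?' for the binary habitat analyses.

    The facultative ``both`` coding collapses to aquatic (its primary
    habitat; this matches how the taxon is grouped in the published
    constraint analyses).
    """
    matrix = matrix or load_study_characters()
    out = {}
    for taxon, state in matrix.states("habitat").items():
        out[taxon] = "aquatic" if state == "both" else state
    return out


def dec_habitat_ranges(matrix: CharacterMatrix | None = None) -> dict[str, str]:
    """taxon -> DEC range 'A'/'T'/'AT'; unknown-habitat taxa are omitted
    (the DEC run prunes them)."""
    matrix = matrix or load_study_characters()
    code = {"aquatic": "A", "terrestrial": "T", "both": "AT"}
    return {
        taxon: code[state]
        for taxon, state in matrix.states("habitat").items()
        if state in code
    }
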