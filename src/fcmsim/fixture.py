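"""Curated infantile-onset Pompe disease (IOPD) concept network and literature profiles.

The bundled network is a literature-anchored surrogate for a much larger
proprietary knowledge base: ~57 concepts spanning reprogramming factors, the
pluripotency and skeletal-muscle marker panels, the GAA / lysosomal-glycogen
disease axis, mTORC1 signalling, calcium homeostasis, mitochondrial function
and autophagy/mitophagy.  Every relation carries a provenance note - either a
paraphrased literature anchor or ``curated: closure edge`` for inferred
wiring - so tests can distinguish anchored from inferred structure.

Deliberately absent (not modelled in the source platform version): TRA-1-60,
Park2, FIS1, OPA1, COX4l1, and mitochondrial calcium concentration.
"""

from __future__ import annotations

from importlib import resources

from .network import ConceptNetwork, parse_edge_list
from .stats import LiteratureProfile

__all__ = ["build_iopd_fixture", "load_literature_profile", "literature_profile_names", "EXCLUDED_CONCEPTS"]

#: Concepts the simulated platform version does not implement; the fixture
#: must not contain them.
EXCLUDED_CONCEPTS = ("TRA-1-60", "Park2", "FIS1", "OPA1", "COX4l1", "mitochondrial_calcium")

_PROFILE_FILES = {
    "pluripotency_aipsc_wt": "pluripotency_aipsc_wt.csv",
    "aipsc_iopd": "aipsc_iopd.csv",
    "aiskmc_wt": "aiskmc_wt.csv",
    "aiskmc_iopd": "aiskmc_iopd.csv",
    "calcium_homeostasis": "calcium_homeostasis.csv",
    "mitochondrial_function": "mitochondrial_function.csv",
    "bioenergetics": "bioenergetics.csv",
    "autophagy_mitophagy": "autophagy_mitophagy.csv",
    "mitochondrial_morphology": "mitochondrial_morphology.csv",
}


def _data_path(*parts):
    return resources.files("fcmsim").joinpath("data", *parts)


def build_iopd_fixture() -> ConceptNetwork:
    """Load the curated IOPD network (concept table + signed edge list)."""
    with resources.as_file(_data_path("iopd_edges.csv")) as edges, \
            resources.as_file(_data_path("iopd_concepts.csv")) as concepts:
        return parse_edge_list(edges, strict=True, concept_table=concepts)


def literature_profile_names() -> list[str]:
    return sorted(_PROFILE_FILES)


def load_literature_profile(name: str) -> LiteratureProfile:
    """Load a bundled literature expectation profile by name.

    Each profile lists (concept, expected direction, provenance) rows used by
    the bias-adjusted binomial validation.
    """
    try:
        fname = _PROFILE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {', '.join(literature_profile_names())}"
        ) from None
    with resources.as_file(_data_path("profiles", fname)) as path:
        return LiteratureProfile.from_csv(path, name=name)
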