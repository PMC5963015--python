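"""Bundled sample terminologies and pattern files.

These are desk-scale stand-ins a user replaces with their institution's
terminology exports (e.g. SNOMED-CT-derived organ lists, UMLS disorder
names, a pathologist-curated test-result dictionary).
"""

from importlib import resources
from pathlib import Path


def bundled_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(resources.files(__name__).joinpath(name)))
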