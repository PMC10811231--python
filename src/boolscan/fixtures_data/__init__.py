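"""Versioned golden fixtures (BMA-dialect JSON models + expected TSVs)."""

from importlib import resources

FIXTURE_VERSION = "v1"


def fixture_text(name: str, version: str = FIXTURE_VERSION) -> str:
    """Read a shipped fixture file (e.g. ``toy_scan.tsv``) as text."""
    return (resources.files(__package__) / version / name).read_text()


def fixture_path(name: str, version: str = FIXTURE_VERSION):
    """Filesystem path of a shipped fixture (packages install unzipped)."""
    return resources.files(__package__) / version / name
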