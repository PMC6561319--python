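"""Packaged transcriptions of the printed abundance and kinetics tables.

The fixtures ship with the package so the worked examples and the
presentation-threshold checks run without any download.  Each table is
checksummed (SHA-256 over newline-normalized UTF-8) so an accidental
edit is caught at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["FixtureTable", "load_fixture", "FIXTURE_NAMES"]

_CHECKSUMS = {
    "table1": "7cef528970135ffda8154859afce9bf44f2ee68b0fd0e789ee856e372b34464a",
    "table2": "4a35eaeb9903057f8f0dae0df037c428eea0849c2393adf108b4764f7f3f28c6",
    "table4": "d982a8367b9beecd021a3b4e464f3765c4ce6c1eb270d6bace9ce32de79e5cbb",
}
_LABELS = {
    "table1": "Significantly upregulated proteins (fold increase >= 2.5)",
    "table2": "Significantly downregulated proteins (fold decrease >= 2.5)",
    "table4": "Citrate synthase kinetic parameters (WT + 4 variants)",
}
FIXTURE_NAMES = tuple(_CHECKSUMS)


@dataclass(frozen=True)
class FixtureTable:
    source: str
    label: str
    table: pd.DataFrame
    checksum: str


def load_fixture(name: str) -> FixtureTable:
    """Load a packaged table by name ('table1', 'table2', 'table4')."""
    if name not in _CHECKSUMS:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = resources.files("stresstox.data") / f"{name}.tsv"
    text = ref.read_text(encoding="utf-8").replace("\r\n", "\n")
    digest = hashlib.sha256(text.encode("utf-8")).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(
            f"fixture {name!r} failed its checksum (got {digest}); "
            "the packaged transcription has been modified"
        )
    import io

    table = pd.read_csv(io.StringIO(text), sep="\t")
    return FixtureTable(source=name, label=_LABELS[name], table=table, checksum=digest)
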