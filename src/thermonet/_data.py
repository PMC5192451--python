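"""Access to bundled data files and tolerant TSV reading.

Numeric fields accept both the ASCII hyphen-minus and the typographic
Unicode minus, since published thermodynamic tables frequently use the
latter.
"""

from __future__ import annotations

import io
from importlib import resources

_MINUS_VARIANTS = str.maketrans({"−": "-", "‒": "-", "–": "-"})


def normalize_minus(text: str) -> str:
    return text.translate(_MINUS_VARIANTS)


def _parse_tsv(lines: list[str]) -> list[dict[str, str]]:
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [normalize_minus(f.strip()) for f in line.split("\t")]
        if header is None:
            header = fields
            continue
        if len(fields) > len(header):
            raise ValueError(
                f"line {lineno}: expected {len(header)} tab-separated fields, got {len(fields)}"
            )
        fields += [""] * (len(header) - len(fields))
        rows.append(dict(zip(header, fields)))
    if header is None:
        raise ValueError("file has no header line")
    return rows


def read_tsv(filename: str) -> list[dict[str, str]]:
    """Read a TSV bundled under thermonet/data into a list of row dicts."""
    text = resources.files("thermonet").joinpath("data", filename).read_text("utf-8")
    return _parse_tsv(text.splitlines(keepends=True))


def read_tsv_path(path) -> list[dict[str, str]]:
    """Read a TSV from a filesystem path or text buffer."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    return _parse_tsv(io.StringIO(text).readlines())


def data_text(filename: str) -> str:
    """Raw text of a bundled data file."""
    return resources.files("thermonet").joinpath("data", filename).read_text("utf-8")
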