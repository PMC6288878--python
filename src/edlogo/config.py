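"""key = value configuration files shared by the stabilizer and renderer.

One option per line, ``#`` starts a comment, blank lines ignored.
Stabilizer keys (method, pseudocount, effective_count, prior, seed) and
style keys (width_per_position, plot_height, ...) may be mixed in one
file; consumers pick the keys they know.  CLI flags take precedence over
file values.
"""

from __future__ import annotations

from typing import IO

from .errors import FormatError

__all__ = ["parse_config", "read_config"]


def parse_config(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"config line {lineno}: expected 'key = value', got {line!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out


def read_config(source: IO[str] | str) -> dict[str, str]:
    if hasattr(source, "read"):
        return parse_config(source.read())
    with open(source, "r", encoding="utf-8") as fh:
        return parse_config(fh.read())
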