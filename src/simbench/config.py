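"""Flat key/value config file parsing (``key = value``, ``#`` comments)."""

from __future__ import annotations

from pathlib import Path


def parse_flat_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` text file into a string dict.

    Keys may be dotted (e.g. ``layer1.blob_length_x``) to express nesting in a
    flat file. Values stay strings; callers coerce types.
    """
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if not key:
            raise ValueError(f"{path}:{lineno}: empty key")
        out[key] = value
    return out


def write_flat_config(path: str | Path, items: dict[str, object]) -> None:
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in items.items()))
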