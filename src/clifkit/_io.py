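"""Small shared IO helpers."""

from __future__ import annotations

import json
from pathlib import Path


def load_json_source(source) -> dict:
    """Accept a path to a JSON file, JSON text, or an already-parsed mapping."""
    if isinstance(source, Path):
        return json.loads(source.read_text())
    if isinstance(source, dict):
        return source
    if isinstance(source, (str, bytes)):
        text = source.decode() if isinstance(source, bytes) else source
        stripped = text.lstrip()
        if stripped.startswith("{") or stripped.startswith("["):
            return json.loads(text)
        return json.loads(Path(text).read_text())
    raise TypeError(f"cannot load JSON from {type(source)!r}")
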