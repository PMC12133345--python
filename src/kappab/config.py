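"""Flat key=value configuration files for circuit parameters.

Accepted syntax per line: ``key = value`` or ``key: value`` (YAML-style),
blank lines and ``#`` comments.  Keys must be circuit parameter names;
unknown keys are errors.
"""

from __future__ import annotations

from pathlib import Path

from .circuit import CircuitParams

__all__ = ["read_params_config", "write_params_config"]


def parse_config_text(text: str) -> dict:
    out: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        elif ":" in line:
            key, _, val = line.partition(":")
        else:
            raise ValueError(f"line {lineno}: expected 'key = value' or 'key: value'")
        key = key.strip()
        try:
            out[key] = float(val.strip())
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric value for {key!r}") from exc
    return out


def read_params_config(path: str | Path) -> CircuitParams:
    """Read circuit parameters; keys absent from the file keep defaults."""
    return CircuitParams.from_dict(parse_config_text(Path(path).read_text()))


def write_params_config(p: CircuitParams, path: str | Path) -> None:
    lines = [f"{k} = {v!r}" for k, v in p.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")
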