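"""Tolerant extraction of numeric vector assignments from R data scripts.

The case-study counts ship as an R script of the form::

    y <- c(0, 3, 1, ...)
    e = c(12.4, 0.8, ...)
    pop <- scan(text="...")   # not executed; numbers are harvested

Rather than requiring an R runtime, this module scans the script for
``name <- c(...)`` / ``name = c(...)`` assignments whose arguments are all
numeric literals (possibly spread over several lines, with ``rep(x, n)``
expanded) and returns them as numpy arrays keyed by variable name.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

__all__ = ["parse_r_vectors", "pick_vector"]

_ASSIGN = re.compile(r"^\s*([A-Za-z.][\w.]*)\s*(?:<-|=)\s*c\s*\(", re.MULTILINE)
_NUMBER = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_REP = re.compile(r"^rep\s*\(\s*([^,]+)\s*,\s*(\d+)\s*\)$")


class RScriptError(ValueError):
    pass


def _strip_comments(text: str) -> str:
    # R has no block comments and we only harvest numeric literals, so
    # dropping everything after '#' per line is safe enough here
    return "\n".join(line.split("#")[0] for line in text.splitlines())


def _split_top_level(body: str) -> list[str]:
    """Split on commas outside parentheses (so rep(0, 3) stays whole)."""
    parts, depth, cur = [], 0, []
    for ch in body:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur))
    return parts


def parse_r_vectors(path: str | Path) -> dict[str, np.ndarray]:
    """All ``name <- c(numbers...)`` assignments found in the script."""
    path = Path(path)
    if not path.exists():
        raise RScriptError(f"R data script not found: {path}")
    text = _strip_comments(path.read_text())
    out: dict[str, np.ndarray] = {}
    for m in _ASSIGN.finditer(text):
        name = m.group(1)
        # find matching closing parenthesis for the c( call
        depth, pos = 1, m.end()
        while pos < len(text) and depth:
            if text[pos] == "(":
                depth += 1
            elif text[pos] == ")":
                depth -= 1
            pos += 1
        if depth:
            continue  # unbalanced; not a literal vector
        body = text[m.end() : pos - 1]
        values: list[float] = []
        ok = True
        for tok in _split_top_level(body.replace("\n", " ")):
            tok = tok.strip()
            if not tok:
                continue
            rep = _REP.match(tok)
            if rep and _NUMBER.match(rep.group(1).strip()):
                values.extend([float(rep.group(1))] * int(rep.group(2)))
            elif _NUMBER.match(tok):
                values.append(float(tok))
            else:
                ok = False
                break
        if ok and values:
            out[name] = np.asarray(values)
    return out


def pick_vector(
    vectors: dict[str, np.ndarray],
    length: int,
    prefer: tuple[str, ...],
    integer: bool | None = None,
    exclude: tuple[str, ...] = (),
) -> tuple[str, np.ndarray]:
    """Choose the vector of the required length, preferring familiar names.

    ``integer=True`` keeps only all-integer vectors (counts), ``False`` only
    vectors with at least one non-integer entry (expected counts).  Raises
    when the choice is ambiguous so the caller can demand an explicit name.
    """
    cands = {
        k: v
        for k, v in vectors.items()
        if v.size == length and k not in exclude
    }
    if integer is True:
        cands = {k: v for k, v in cands.items() if np.all(v == np.floor(v))}
    elif integer is False:
        cands = {k: v for k, v in cands.items() if not np.all(v == np.floor(v))}
    if not cands:
        raise RScriptError(
            f"no candidate vector of length {length} "
            f"(integer={integer}) in the script"
        )
    for name in prefer:
        for k in cands:
            if k.lower() == name or k.lower().startswith(name):
                return k, cands[k]
    if len(cands) == 1:
        return next(iter(cands.items()))
    raise RScriptError(
        f"ambiguous vectors of length {length}: {sorted(cands)}; "
        "pass explicit variable names"
    )
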