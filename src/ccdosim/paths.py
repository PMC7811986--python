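"""Current-path labels and their expansion into electrode site sets.

A current path is written ``SOURCE-SINK``: "RH-LH" drives from the right hand
to the left hand.  Composites: BH = both hands {RH, LH}, BF = both feet
{RF, LF}; the wildcard tokens expand a label into several paths:
xF -> {LF, RF, BF}, xH -> {LH, RH, BH}, xT -> {PT, AT}.  "PS" (posterior
seat) is the SEAT electrode.  The 16 standard paths used for heart-current-
factor tables are in :data:`DEFAULT_PATHS`; "LH-BF" is the reference path.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CurrentPath", "expand_paths", "DEFAULT_PATHS", "REFERENCE_PATH", "PathError"]


class PathError(ValueError):
    pass


_SIMPLE = {
    "RH": ("RH",), "LH": ("LH",), "RF": ("RF",), "LF": ("LF",),
    "PT": ("PT",), "AT": ("AT",), "PS": ("SEAT",), "SEAT": ("SEAT",),
    "BH": ("RH", "LH"), "BF": ("RF", "LF"),
}
_WILDCARD = {
    "XF": ("LF", "RF", "BF"),
    "XH": ("LH", "RH", "BH"),
    "XT": ("PT", "AT"),
}


@dataclass(frozen=True)
class CurrentPath:
    """One concrete source/sink electrode configuration."""

    label: str
    source_sites: frozenset[str]
    sink_sites: frozenset[str]

    def __post_init__(self) -> None:
        if not self.source_sites or not self.sink_sites:
            raise PathError(f"{self.label}: empty electrode set")
        if self.source_sites & self.sink_sites:
            raise PathError(
                f"{self.label}: source and sink electrode sets overlap "
                f"({sorted(self.source_sites & self.sink_sites)})")


#: The 16 standard paths: ten longitudinal (xH-xF and PS-xH) and six
#: transversal (hand-to-hand, thorax-to-hand, foot-to-foot).
DEFAULT_PATHS: tuple[str, ...] = (
    "LH-BF", "LH-LF", "LH-RF", "BH-BF", "RH-BF", "RH-LF", "RH-RF",
    "PS-LH", "PS-RH", "PS-BH",
    "LH-RH", "PT-RH", "PT-LH", "AT-RH", "AT-LH", "RF-LF",
)

#: All heart-current factors are normalised to this path.
REFERENCE_PATH = "LH-BF"


def _expand_token(token: str, label: str, position: int) -> list[tuple[str, tuple[str, ...]]]:
    """Return [(concrete token text, site tuple), ...] for one side token."""
    up = token.upper()
    if up in _WILDCARD:
        return [(t, _SIMPLE[t]) for t in _WILDCARD[up]]
    if up in _SIMPLE:
        return [(token, _SIMPLE[up])]
    raise PathError(
        f"unknown token {token!r} at position {position} in path label {label!r}; "
        f"valid tokens: {sorted(set(_SIMPLE) | set(_WILDCARD))}")


def parse_path(label: str) -> list[CurrentPath]:
    """Parse one path label, expanding wildcards, and validate each result."""
    parts = label.split("-")
    if len(parts) != 2:
        raise PathError(f"path label {label!r} must be 'SOURCE-SINK'")
    src_tok, sink_tok = parts[0].strip(), parts[1].strip()
    out = []
    for stext, ssites in _expand_token(src_tok, label, 0):
        for ktext, ksites in _expand_token(sink_tok, label, len(parts[0]) + 1):
            out.append(CurrentPath(
                label=f"{stext}-{ktext}",
                source_sites=frozenset(ssites),
                sink_sites=frozenset(ksites)))
    return out


def expand_paths(labels) -> list[CurrentPath]:
    """Expand a list of path labels into concrete paths, de-duplicated in order."""
    seen: set[str] = set()
    out: list[CurrentPath] = []
    for label in labels:
        for path in parse_path(label):
            if path.label not in seen:
                seen.add(path.label)
                out.append(path)
    return out
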