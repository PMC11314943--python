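"""Sleep-posture label taxonomies.

Nine fine-grained postures: supine (S); left/right lateral log (legs
extended), half-stomach (bottom leg extended, top leg flexed) and fetal
(both legs flexed); prone with head turned left or right.  The coarse
four-class scheme groups these by trunk orientation.
"""

from __future__ import annotations

__all__ = ["FINE_LABELS", "COARSE_LABELS", "FINE_TO_COARSE", "coarse_map"]

FINE_LABELS = ("S", "L.Log", "L.Sto", "L.Fet", "R.Log", "R.Sto", "R.Fet", "L.Pr", "R.Pr")
COARSE_LABELS = ("Supine", "Left", "Right", "Prone")

FINE_TO_COARSE = {
    "S": "Supine",
    "L.Log": "Left",
    "L.Sto": "Left",
    "L.Fet": "Left",
    "R.Log": "Right",
    "R.Sto": "Right",
    "R.Fet": "Right",
    "L.Pr": "Prone",
    "R.Pr": "Prone",
}


def coarse_map(fine_label: str) -> str:
    """Map a fine-grained posture label to its coarse class."""
    try:
        return FINE_TO_COARSE[fine_label]
    except KeyError:
        raise KeyError(f"unknown posture label {fine_label!r}; expected one of {FINE_LABELS}") from None
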