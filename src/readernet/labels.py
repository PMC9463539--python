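"""The five-way WHO-style radiograph classification scheme.

The canonical integer order of the classes is fixed here and used
everywhere else in the package: confusion-matrix axes, softmax output
order, CSV serialization, and argmax tie-breaking all follow it.
"""

from __future__ import annotations

from enum import IntEnum


class ClassLabel(IntEnum):
    """WHO-style paediatric chest-radiograph categories."""

    CONSOLIDATION = 0
    OTHER_INFILTRATE = 1
    BOTH = 2
    NORMAL = 3
    UNINTERPRETABLE = 4


#: Canonical class names in canonical order (used in CSV headers and parsing).
CLASS_NAMES: tuple[str, ...] = tuple(c.name for c in ClassLabel)

N_CLASSES: int = len(ClassLabel)


def parse_label(text: str) -> ClassLabel:
    """Parse a canonical class name (case-insensitive) to a :class:`ClassLabel`.

    Raises
    ------
    ValueError
        If the text is not one of the five canonical class names.
    """
    key = text.strip().upper()
    try:
        return ClassLabel[key]
    except KeyError:
        raise ValueError(
            f"unknown class label {text!r}; expected one of {CLASS_NAMES}"
        ) from None
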