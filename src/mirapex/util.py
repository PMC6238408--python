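"""Small shared sequence helpers."""

from __future__ import annotations

_COMP = str.maketrans("ACGTU", "TGCAA")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U read as T)."""
    return seq.translate(_COMP)[::-1]
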