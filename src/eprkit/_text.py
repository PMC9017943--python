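"""Text normalization shared by codification and catalog lookup."""

from __future__ import annotations

import re
import unicodedata

_WS = re.compile(r"\s+")


def normalize_text(value: str | None) -> str | None:
    """Lowercase, strip diacritics and collapse internal whitespace.

    ``"  Métastatique "`` -> ``"metastatique"``. Hyphens are kept (spelling
    variants like ``"T-DM1"`` are handled by the alias table instead).
    Returns None for None/empty input.
    """
    if value is None:
        return None
    s = str(value).strip()
    if not s:
        return None
    s = unicodedata.normalize("NFKD", s)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    s = s.lower()
    s = _WS.sub(" ", s)
    return s or None
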