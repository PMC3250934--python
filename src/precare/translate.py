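"""Lay-language translation of clinical shorthand.

Two mechanisms: a phrase dictionary for clinical terms patients should not
have to decode ("fecal occult blood test"), and a small grammar for
prescription sigs of the form ``<count> PO <frequency>`` ("2 PO BID").
Anything the dictionary and grammar do not recognize passes through
unchanged with ``translated=False`` — the engine never guesses at meaning.

Translation is idempotent: lay output contains no dictionary keys and never
matches the sig grammar, so translating twice is a no-op.
"""

from __future__ import annotations

import re
from typing import NamedTuple

#: Clinical phrase -> lay phrase. Keys are matched case-insensitively on the
#: whole (stripped) input. Values must not themselves be keys.
LAY_DICTIONARY: dict[str, str] = {
    "fecal occult blood test": "stool test for colon cancer screening",
    "fobt": "stool test for colon cancer screening",
    "dxa scan": "bone density scan",
    "pap smear": "test for cervical cancer",
    "psa": "prostate cancer blood test",
    "hypertension": "high blood pressure",
    "hyperlipidemia": "high cholesterol",
    "myocardial infarction": "heart attack",
    "cerebrovascular accident": "stroke",
    "influenza vaccine": "flu shot",
    "pneumococcal vaccine": "pneumonia shot",
    "td booster": "tetanus booster shot",
    "hdl": "good (HDL) cholesterol",
    "ldl": "bad (LDL) cholesterol",
    "hba1c": "average blood sugar (A1c)",
    "total_cholesterol": "total cholesterol",
    "systolic_bp": "systolic (top-number) blood pressure",
    "diastolic_bp": "diastolic (bottom-number) blood pressure",
    "fasting_glucose": "fasting blood sugar",
}

_FREQUENCIES = {
    "QD": "once daily",
    "BID": "twice daily",
    "TID": "three times daily",
    "QID": "four times daily",
}

# count + PO route + frequency; other sig shapes fall through untranslated.
_SIG_RE = re.compile(r"^\s*(\d+)\s+PO\s+(QD|BID|TID|QID)\s*$", re.IGNORECASE)


class Translation(NamedTuple):
    text: str
    translated: bool


def translate_term(clinical_text: str) -> Translation:
    """Translate one clinical phrase or sig into lay language.

    >>> translate_term("2 PO BID").text
    'take 2 pills twice daily by mouth'
    """
    key = clinical_text.strip().lower()
    if key in LAY_DICTIONARY:
        return Translation(LAY_DICTIONARY[key], True)
    m = _SIG_RE.match(clinical_text)
    if m:
        count = int(m.group(1))
        unit = "pill" if count == 1 else "pills"
        freq = _FREQUENCIES[m.group(2).upper()]
        return Translation(f"take {count} {unit} {freq} by mouth", True)
    return Translation(clinical_text, False)
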