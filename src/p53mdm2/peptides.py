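"""Registry of the p53 transactivation-domain (Glu17-Asn29) peptide set.

All peptides span residues 17-29 of full-length p53
(ETFSDLWKLLPEN), N-terminally acetylated and C-terminally amidated.
Sequence strings use the compact notation of the study tables: upper case
= wild-type residue, lower case = substitution, ``pt``/``ps`` = phospho-
threonine/-serine. Residue numbering follows full-length p53.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["Residue", "parse_sequence", "PEPTIDES", "WT_SEQUENCE",
           "FIRST_RESIDUE_INDEX"]

#: p53 numbering of the first residue of the peptide (Glu17)
FIRST_RESIDUE_INDEX = 17

WT_SEQUENCE = "ETFSDLWKLLPEN"


@dataclass(frozen=True)
class Residue:
    """One residue of a peptide in full-length p53 numbering."""

    index: int
    code: str          # upper-case one-letter code
    phospho: bool
    substituted: bool  # differs from the wild-type residue


_TOKEN = re.compile(r"p[st]|[A-Za-z]")


def parse_sequence(notation: str,
                   first_index: int = FIRST_RESIDUE_INDEX,
                   wild_type: str = WT_SEQUENCE) -> list[Residue]:
    """Parse compact peptide notation into residues.

    ``"Ac-EptFpsDLWKLLPEN-NH2"`` -> phospho-Thr18, phospho-Ser20, rest
    wild type. Upper case = wild-type residue, lower case = substitution,
    ``pt``/``ps`` = phosphorylated Thr/Ser (counted as wild type).
    """
    body = notation
    for cap in ("Ac-", "AC-"):
        if body.startswith(cap):
            body = body[len(cap):]
    for cap in ("-NH2", "-nh2"):
        if body.endswith(cap):
            body = body[: -len(cap)]
    residues: list[Residue] = []
    pos = 0
    for m in _TOKEN.finditer(body):
        tok = m.group(0)
        idx = first_index + pos
        wt = wild_type[pos] if pos < len(wild_type) else None
        if tok in ("ps", "pt"):
            residues.append(Residue(index=idx, code=tok[1].upper(),
                                    phospho=True, substituted=False))
        elif tok.isupper():
            residues.append(Residue(index=idx, code=tok, phospho=False,
                                    substituted=False))
        else:
            residues.append(Residue(index=idx, code=tok.upper(),
                                    phospho=False,
                                    substituted=(wt is None
                                                 or tok.upper() != wt)))
        pos += 1
    return residues


#: peptide name -> compact sequence notation
PEPTIDES: dict[str, str] = {
    "P53-WT": "Ac-ETFSDLWKLLPEN-NH2",
    "P53-pTpS": "Ac-EptFpsDLWKLLPEN-NH2",
    "P53-pT": "Ac-EptFSDLWKLLPEN-NH2",
    "P53-pS": "Ac-ETFpsDLWKLLPEN-NH2",
    "P53-E18": "Ac-EeFSDLWKLLPEN-NH2",
    "P53-D20": "Ac-ETFdDLWKLLPEN-NH2",
    "P53-E18-D20": "Ac-EeFdDLWKLLPEN-NH2",
    "P53-E18-D20-E24-E25": "Ac-EeFdDLWeeLPEN-NH2",
    "P53-E18-E20": "Ac-EeFeDLWKLLPEN-NH2",
    "P53-D18": "Ac-EdFSDLWKLLPEN-NH2",
    "P53-E20": "Ac-ETFeDLWKLLPEN-NH2",
    "P53-D18-E20": "Ac-EdFeDLWKLLPEN-NH2",
    "P53-D18-D20": "Ac-EdFdDLWKLLPEN-NH2",
}
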