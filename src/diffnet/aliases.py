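"""Protein-symbol normalization.

Interactomes and drug-target catalogs mix HGNC symbols with historical or
informal names ("c-KIT", "BCR-ABL", "PDGFR"). All graph operations in this
package run on normalized symbols: upper-cased and mapped through a small
alias table; the raw spelling is preserved alongside wherever it matters
for provenance.
"""

from __future__ import annotations

# Informal / legacy name -> HGNC symbol. "LYK" is an informal Src-family
# name that in drug-target catalogs refers to LCK.
SYMBOL_ALIASES: dict[str, str] = {
    "LYK": "LCK",
    "PDGFR": "PDGFRB",
    "PDGFR-B": "PDGFRB",
    "PDGFRB-BETA": "PDGFRB",
    "BCR-ABL": "ABL1",
    "YES": "YES1",
    "C-KIT": "KIT",
    "C-SRC": "SRC",
}


def normalize_symbol(symbol: str, apply_aliases: bool = True) -> str:
    """Upper-case a protein symbol and resolve known aliases."""
    s = symbol.strip().upper()
    if apply_aliases:
        s = SYMBOL_ALIASES.get(s, s)
    return s


def normalize_symbols(symbols, apply_aliases: bool = True) -> list[str]:
    return [normalize_symbol(s, apply_aliases) for s in symbols]
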