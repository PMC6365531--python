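"""Bundled reference peptide data.

The seven putative AMP precursors (HP2-HP9; there is no HP7) identified in
the premetamorphic bullfrog (*Rana catesbeiana*) tadpole transcriptome.
Each precursor carries an N-terminal prepro region ending in the dibasic
Lys-Arg convertase motif followed by the C-terminal mature peptide; the
sequences below are the full precursors, to be split with
:func:`ampseine.precursor_physchem.split_precursor`.
"""

from __future__ import annotations

#: Full precursor sequences (prepro + mature) of the seven tadpole AMP
#: candidates, keyed by peptide id.
TADPOLE_PRECURSORS: dict[str, str] = {
    "HP2": "MFTMKKSLLLLFFLGTISLSLCEQERNADDDQGEVIEQKVKR"
           "AFLSTVKNTLTNVAGTMIDTFKCKITGVC",
    "HP3": "VLLYLIITVSFPRRDANDEDGGEVTKEVVKR"
           "SLSGCWTKSFPRKPCLRNR",
    "HP4": "MSSFCEITNVALTISLSSPRRGADEEEGNGEKEIKR"
           "SMLSVLKNLGKVGLGFVACKINKQC",
    "HP5": "MTQSTQKWFKTKYWRVRNRPAMSPDLNPIEHLWRDLKKVVGKR"
           "NPSNLRALEELVKEECSEIPVERCKKLIYGYRK",
    "HP6": "MRKRMTMRRMMKKKKSEKERRERGKR"
           "MMRVMRRKTKVIWEKKDFIGLYSID",
    "HP8": "MFFMSSPRRDADEVKEVKR"
           "GFLDIIKNLGKTFAGHMLDKIKCTIGTCPPSP",
    "HP9": "MITVSSPRRDADGDEGEVEEVKR"
           "GFLDIIKDTGKEFAVKILNNLKCKLAGGCPP",
}

#: Best-known mature-peptide matches reported for the candidates
#: (HP5 had no match in the curated AMP references).
BEST_KNOWN_MATCH: dict[str, str | None] = {
    "HP2": "Ranatuerin-2PRc",
    "HP3": "Ranacyclin-Ca",
    "HP4": "Ranatuerin-1",
    "HP5": None,
    "HP6": "Catesbeianin-1",
    "HP8": "Ranatuerin-3RC",
    "HP9": "Palustrin-Ca",
}
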