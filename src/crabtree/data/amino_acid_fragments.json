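{
  "comment": "Default proteinogenic amino-acid precursor fragment map. Each fragment lists the precursor EMUs whose condensation forms its carbon skeleton; positions are 1-based carbons of the central-carbon network pools. Editable: replace or extend to match the measured fragment set.",
  "fragments": [
    {"label": "Ala", "parts": [["PYRc", [1, 2, 3]]]},
    {"label": "Ser", "parts": [["PEP", [1, 2, 3]]]},
    {"label": "Gly", "parts": [["PEP", [1, 2]]]},
    {"label": "Asp", "parts": [["OAAc", [1, 2, 3, 4]]]},
    {"label": "Thr", "parts": [["OAAc", [1, 2, 3, 4]]]},
    {"label": "Glu", "parts": [["AKG", [1, 2, 3, 4, 5]]]},
    {"label": "Pro", "parts": [["AKG", [1, 2, 3, 4, 5]]]},
    {"label": "His", "parts": [["R5P", [1, 2, 3, 4, 5]]]},
    {"label": "Phe", "parts": [["PEP", [1, 2, 3]], ["PEP", [2, 3]], ["E4P", [1, 2, 3, 4]]]},
    {"label": "Tyr", "parts": [["PEP", [1, 2, 3]], ["PEP", [2, 3]], ["E4P", [1, 2, 3, 4]]]},
    {"label": "Val", "parts": [["PYRm", [1, 2, 3]], ["PYRm", [2, 3]]]},
    {"label": "Ile", "parts": [["OAAc", [1, 2, 3, 4]], ["PYRm", [2, 3]]]},
    {"label": "Leu", "parts": [["AcCoAm", [1, 2]], ["PYRm", [2, 3]], ["PYRm", [2, 3]]]}
  ]
}
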