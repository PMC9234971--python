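{
  "name": "MOTERA",
  "genes": [
    {"id": "CHST8", "membership": "estrogen_response"},
    {"id": "MAPT", "membership": "estrogen_response"},
    {"id": "OLFM1", "membership": "estrogen_response"},
    {"id": "PDZK1", "membership": "estrogen_response"},
    {"id": "RASGRP1", "membership": "estrogen_response"},
    {"id": "MPPED2", "membership": "estrogen_response"},
    {"id": "GREB1", "membership": "estrogen_response"},
    {"id": "MYB", "membership": "estrogen_response"},
    {"id": "GFRA1", "membership": "estrogen_response"},
    {"id": "PGR", "membership": "estrogen_response"},
    {"id": "ELOVL2", "membership": "estrogen_response"},
    {"id": "ADCY1", "membership": "estrogen_response"},
    {"id": "NPY1R", "membership": "estrogen_response"},
    {"id": "TFF1", "membership": "estrogen_response"},
    {"id": "ACOX2", "membership": "estrogen_response"},
    {"id": "SGK1", "membership": "estrogen_response"},
    {"id": "STC2", "membership": "estrogen_response"},
    {"id": "CALCR", "membership": "estrogen_response"},
    {"id": "KRT13", "membership": "estrogen_response"},
    {"id": "VCAN", "membership": "emt"},
    {"id": "COL3A1", "membership": "emt"},
    {"id": "CXCL12", "membership": "both"},
    {"id": "GJA1", "membership": "both"},
    {"id": "TGM2", "membership": "both"}
  ],
  "source_sets": [
    "HALLMARK_ESTROGEN_RESPONSE_EARLY",
    "HALLMARK_ESTROGEN_RESPONSE_LATE",
    "HALLMARK_EPITHELIAL_MESENCHYMAL_TRANSITION"
  ]
}
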