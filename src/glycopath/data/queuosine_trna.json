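{
 "name": "queuosine_trna",
 "description": "Queuosine glycosylation of tRNAs: tRNA-guanine transglycosylase (QTRT1/QTRT2 complex) installs queuosine, which is galactosylated by QTGAL or mannosylated by QTMAN; salvage of the free base is included as a stub.",
 "structures": [
  {
   "id": "PREQ1_TRNA",
   "name": "preQ1-tRNA",
   "composition": {
    "Que": 1
   },
   "is_root": true,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "Q_TRNA",
   "name": "queuosine-tRNA",
   "composition": {
    "Que": 1
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GALQ_TRNA",
   "name": "galactosyl-queuosine-tRNA",
   "composition": {
    "Que": 1,
    "Gal": 1
   },
   "is_root": false,
   "is_terminal": true,
   "category": "core"
  },
  {
   "id": "MANQ_TRNA",
   "name": "mannosyl-queuosine-tRNA",
   "composition": {
    "Que": 1,
    "Man": 1
   },
   "is_root": false,
   "is_terminal": true,
   "category": "core"
  },
  {
   "id": "Q_FREE",
   "name": "free queuosine",
   "composition": {
    "Que": 1
   },
   "is_root": false,
   "is_terminal": false,
   "category": "degradation_intermediate"
  },
  {
   "id": "QUEUINE",
   "name": "queuine (salvaged base)",
   "composition": {
    "Que": 1
   },
   "is_root": false,
   "is_terminal": true,
   "category": "degradation_intermediate"
  }
 ],
 "reactions": [
  {
   "id": "q1",
   "substrate": "PREQ1_TRNA",
   "product": "Q_TRNA",
   "requirement": "QTRT1&QTRT2",
   "step_label": null
  },
  {
   "id": "q2",
   "substrate": "Q_TRNA",
   "product": "GALQ_TRNA",
   "requirement": "QTGAL",
   "step_label": null
  },
  {
   "id": "q3",
   "substrate": "Q_TRNA",
   "product": "MANQ_TRNA",
   "requirement": "QTMAN",
   "step_label": null
  },
  {
   "id": "q4",
   "substrate": "Q_TRNA",
   "product": "Q_FREE",
   "requirement": "QNG1",
   "step_label": null
  },
  {
   "id": "q5",
   "substrate": "Q_FREE",
   "product": "QUEUINE",
   "requirement": null,
   "step_label": null
  }
 ]
}
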