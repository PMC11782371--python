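{
 "name": "n_glycan_toy",
 "description": "Compact N-glycan processing map: glucose trimming, mannose trimming, GlcNAc branching (including the bisecting GlcNAc step catalyzed by MGAT3), core fucosylation, galactosylation and sialylation. Branch/merge, isoenzyme (OR) and complex (AND) requirements are all represented.",
 "structures": [
  {
   "id": "G3M9",
   "name": "Glc3Man9GlcNAc2",
   "composition": {
    "Glc": 3,
    "Man": 9,
    "GlcNAc": 2
   },
   "is_root": true,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "G2M9",
   "name": "Glc2Man9GlcNAc2",
   "composition": {
    "Glc": 2,
    "Man": 9,
    "GlcNAc": 2
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "G1M9",
   "name": "Glc1Man9GlcNAc2",
   "composition": {
    "Glc": 1,
    "Man": 9,
    "GlcNAc": 2
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "M9",
   "name": "Man9GlcNAc2",
   "composition": {
    "Man": 9,
    "GlcNAc": 2
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "M8",
   "name": "Man8GlcNAc2",
   "composition": {
    "Man": 8,
    "GlcNAc": 2
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "M5",
   "name": "Man5GlcNAc2",
   "composition": {
    "Man": 5,
    "GlcNAc": 2
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "M5GN",
   "name": "GlcNAcMan5GlcNAc2 (hybrid)",
   "composition": {
    "Man": 5,
    "GlcNAc": 3
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "M3GN",
   "name": "GlcNAcMan3GlcNAc2",
   "composition": {
    "Man": 3,
    "GlcNAc": 3
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GNGN",
   "name": "biantennary GlcNAc2Man3GlcNAc2",
   "composition": {
    "Man": 3,
    "GlcNAc": 4
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GNGN_BIS",
   "name": "bisected biantennary",
   "composition": {
    "Man": 3,
    "GlcNAc": 5
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GNGN_F",
   "name": "core-fucosylated biantennary",
   "composition": {
    "Man": 3,
    "GlcNAc": 4,
    "Fuc": 1
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GN3_B4",
   "name": "triantennary (beta1,4 branch)",
   "composition": {
    "Man": 3,
    "GlcNAc": 5
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GN3_B6",
   "name": "triantennary (beta1,6 branch)",
   "composition": {
    "Man": 3,
    "GlcNAc": 5
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GAL_F",
   "name": "galactosylated core-fucosylated",
   "composition": {
    "Man": 3,
    "GlcNAc": 4,
    "Gal": 2,
    "Fuc": 1
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GAL_BIS",
   "name": "galactosylated bisected",
   "composition": {
    "Man": 3,
    "GlcNAc": 5,
    "Gal": 2
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GAL3_B4",
   "name": "galactosylated triantennary (b1,4)",
   "composition": {
    "Man": 3,
    "GlcNAc": 5,
    "Gal": 3
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "GAL3_B6",
   "name": "galactosylated triantennary (b1,6)",
   "composition": {
    "Man": 3,
    "GlcNAc": 5,
    "Gal": 3
   },
   "is_root": false,
   "is_terminal": false,
   "category": "core"
  },
  {
   "id": "SIA_F",
   "name": "sialylated core-fucosylated",
   "composition": {
    "Man": 3,
    "GlcNAc": 4,
    "Gal": 2,
    "Fuc": 1,
    "Neu5Ac": 2
   },
   "is_root": false,
   "is_terminal": true,
   "category": "core"
  },
  {
   "id": "SIA_BIS",
   "name": "sialylated bisected",
   "composition": {
    "Man": 3,
    "GlcNAc": 5,
    "Gal": 2,
    "Neu5Ac": 2
   },
   "is_root": false,
   "is_terminal": true,
   "category": "core"
  },
  {
   "id": "SIA3_B4",
   "name": "sialylated triantennary (b1,4)",
   "composition": {
    "Man": 3,
    "GlcNAc": 5,
    "Gal": 3,
    "Neu5Ac": 3
   },
   "is_root": false,
   "is_terminal": true,
   "category": "core"
  },
  {
   "id": "SIA3_B6",
   "name": "sialylated triantennary (b1,6)",
   "composition": {
    "Man": 3,
    "GlcNAc": 5,
    "Gal": 3,
    "Neu5Ac": 3
   },
   "is_root": false,
   "is_terminal": true,
   "category": "core"
  }
 ],
 "reactions": [
  {
   "id": "r01",
   "substrate": "G3M9",
   "product": "G2M9",
   "requirement": "MOGS",
   "step_label": "Step 1"
  },
  {
   "id": "r02",
   "substrate": "G2M9",
   "product": "G1M9",
   "requirement": "GANAB&PRKCSH",
   "step_label": "Step 2"
  },
  {
   "id": "r03",
   "substrate": "G1M9",
   "product": "M9",
   "requirement": "GANAB&PRKCSH",
   "step_label": "Step 3"
  },
  {
   "id": "r04",
   "substrate": "M9",
   "product": "M8",
   "requirement": "MAN1B1",
   "step_label": "Step 4"
  },
  {
   "id": "r05",
   "substrate": "M8",
   "product": "M5",
   "requirement": "MAN1A1|MAN1A2|MAN1C1",
   "step_label": "Step 5"
  },
  {
   "id": "r06",
   "substrate": "M5",
   "product": "M5GN",
   "requirement": "MGAT1",
   "step_label": "Step 6"
  },
  {
   "id": "r07",
   "substrate": "M5GN",
   "product": "M3GN",
   "requirement": "MAN2A1|MAN2A2",
   "step_label": "Step 7"
  },
  {
   "id": "r08",
   "substrate": "M3GN",
   "product": "GNGN",
   "requirement": "MGAT2",
   "step_label": "Step 8"
  },
  {
   "id": "r09",
   "substrate": "GNGN",
   "product": "GNGN_BIS",
   "requirement": "MGAT3",
   "step_label": "Step 15"
  },
  {
   "id": "r10",
   "substrate": "GNGN",
   "product": "GNGN_F",
   "requirement": "FUT8",
   "step_label": "Step 16"
  },
  {
   "id": "r11",
   "substrate": "GNGN",
   "product": "GN3_B4",
   "requirement": "MGAT4A|MGAT4B",
   "step_label": "Step 17"
  },
  {
   "id": "r12",
   "substrate": "GNGN",
   "product": "GN3_B6",
   "requirement": "MGAT5|MGAT5B",
   "step_label": "Step 18"
  },
  {
   "id": "r13",
   "substrate": "GNGN_F",
   "product": "GAL_F",
   "requirement": "B4GALT1|B4GALT2|B4GALT3",
   "step_label": "Step 19"
  },
  {
   "id": "r14",
   "substrate": "GNGN_BIS",
   "product": "GAL_BIS",
   "requirement": "B4GALT1|B4GALT2|B4GALT3",
   "step_label": "Step 20"
  },
  {
   "id": "r15",
   "substrate": "GN3_B4",
   "product": "GAL3_B4",
   "requirement": "B4GALT1|B4GALT2|B4GALT3",
   "step_label": "Step 21"
  },
  {
   "id": "r16",
   "substrate": "GN3_B6",
   "product": "GAL3_B6",
   "requirement": "B4GALT1|B4GALT2|B4GALT3",
   "step_label": "Step 22"
  },
  {
   "id": "r17",
   "substrate": "GAL_F",
   "product": "SIA_F",
   "requirement": "ST6GAL1|ST3GAL4",
   "step_label": "Step 23"
  },
  {
   "id": "r18",
   "substrate": "GAL_BIS",
   "product": "SIA_BIS",
   "requirement": "ST6GAL1|ST3GAL4",
   "step_label": "Step 24"
  },
  {
   "id": "r19",
   "substrate": "GAL3_B4",
   "product": "SIA3_B4",
   "requirement": "ST6GAL1|ST3GAL4",
   "step_label": "Step 25"
  },
  {
   "id": "r20",
   "substrate": "GAL3_B6",
   "product": "SIA3_B6",
   "requirement": "ST6GAL1|ST3GAL4",
   "step_label": "Step 26"
  }
 ]
}
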