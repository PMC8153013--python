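[
  {"name": "HLA-A", "class": "MHC", "weight": 1, "genes": ["HLA-A"]},
  {"name": "HLA-B", "class": "MHC", "weight": 1, "genes": ["HLA-B"]},
  {"name": "HLA-C", "class": "MHC", "weight": 1, "genes": ["HLA-C"]},
  {"name": "HLA-DPA1", "class": "MHC", "weight": 1, "genes": ["HLA-DPA1"]},
  {"name": "HLA-DPB1", "class": "MHC", "weight": 1, "genes": ["HLA-DPB1"]},
  {"name": "HLA-E", "class": "MHC", "weight": 1, "genes": ["HLA-E"]},
  {"name": "HLA-F", "class": "MHC", "weight": 1, "genes": ["HLA-F"]},
  {"name": "B2M", "class": "MHC", "weight": 1, "genes": ["B2M"]},
  {"name": "TAP1", "class": "MHC", "weight": 1, "genes": ["TAP1"]},
  {"name": "TAP2", "class": "MHC", "weight": 1, "genes": ["TAP2"]},
  {"name": "PDCD1", "class": "immunoinhibitor", "weight": -1, "genes": ["PDCD1"]},
  {"name": "CTLA4", "class": "immunoinhibitor", "weight": -1, "genes": ["CTLA4"]},
  {"name": "LAG3", "class": "immunoinhibitor", "weight": -1, "genes": ["LAG3"]},
  {"name": "HAVCR2", "class": "immunoinhibitor", "weight": -1, "genes": ["HAVCR2"]},
  {"name": "TIGIT", "class": "immunoinhibitor", "weight": -1, "genes": ["TIGIT"]},
  {"name": "CD27", "class": "immunostimulator", "weight": 1, "genes": ["CD27"]},
  {"name": "CD28", "class": "immunostimulator", "weight": 1, "genes": ["CD28"]},
  {"name": "ICOS", "class": "immunostimulator", "weight": 1, "genes": ["ICOS"]},
  {"name": "TNFRSF9", "class": "immunostimulator", "weight": 1, "genes": ["TNFRSF9"]},
  {"name": "CD40LG", "class": "immunostimulator", "weight": 1, "genes": ["CD40LG"]},
  {"name": "activated_CD8_T", "class": "cell_type", "weight": 1,
   "genes": ["CD8A", "CD8B", "GZMA", "GZMB", "PRF1", "IFNG"]},
  {"name": "activated_CD4_T", "class": "cell_type", "weight": 1,
   "genes": ["CD4", "IL2", "CD69", "CD38", "TNF"]},
  {"name": "effector_memory_CD8_T", "class": "cell_type", "weight": 1,
   "genes": ["EOMES", "KLRG1", "CX3CR1", "GZMK", "KLRD1"]},
  {"name": "effector_memory_CD4_T", "class": "cell_type", "weight": 1,
   "genes": ["CCR5", "IL7R", "KLRB1", "GPR183"]},
  {"name": "Treg", "class": "cell_type", "weight": -1,
   "genes": ["FOXP3", "IL2RA", "IKZF2", "CCR8"]},
  {"name": "MDSC", "class": "cell_type", "weight": -1,
   "genes": ["ITGAM", "CD14", "ARG1", "S100A8", "S100A9", "FUT4"]}
]
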