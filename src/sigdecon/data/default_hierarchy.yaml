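root:
  epithelial: {}
  endothelial: {}
  fibroblast: {}
  immune:
    t_cell:
      t_cd4_helper: {}
      t_cd8_memory: {}
    nk_cell:
      nk_resting: {}
      nk_il2_expanded: {}
      nk_activated: {}
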