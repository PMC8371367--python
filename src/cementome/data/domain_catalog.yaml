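# Default conserved-domain catalog: tag -> category / family key.
# Tags are CDD-style identifiers (lowercased on load).  The catalog drives
# the pheromone / enzyme-or-inhibitor / homologous split of proteins that
# have homologues outside thoracican barnacles; it is user-extensible via
# the pipeline config (extra entries are merged over these defaults).
pheromone:
  alpha_macroglobulin_SIPC_like:
    - cl08267     # A2M_2 / Isopren_C2_like thiol-ester domain
    - pfam00207   # A2M
    - pfam07677   # A2M_recep receptor-binding domain
    - pfam07703   # A2M_N_2 bait region
    - pfam01835   # A2M_N
    - pfam17791   # MG3
    - pfam17789   # MG4
  WSP:
    - cl40423     # cupin_RmlC-like super family (waterborne settlement pheromone)
enzyme_or_inhibitor:
  peroxidase:
    - pfam03098   # An_peroxidase
  lysyl oxidase:
    - cl03127     # Lysyl_oxidase
    - smart00202  # SR
  serine protease:
    - cd00190     # Tryp_SPc
    - pfam18322   # CLIP_1
    - cl21584     # Tryp_SPc super family
  cyclophilin:
    - cl00197     # cyclophilin super family
  cellulase:
    - pfam03067   # LPMO_10
  chitin deacetylase:
    - cd10974     # CE4_CDA_like_1
    - cd00112     # LDLa
  chitinase:
    - pfam01607   # CBM_14
    - cl10447     # GH18_chitinase-like super family
  serpin:
    - cd00172     # serpin
    - cl38926     # serpin super family
    - cl37951     # Asp super family
    - cd19594     # serpin_crustaceans
  pacifastin serpin:
    - pfam05375   # Pacifastin_I
  Kunitz serine protease inhibitor:
    - cl00101     # KU super family
  peptidase inhibitor:
    - pfam00095   # WAP
  cysteine protease inhibitor:
    - pfam00086   # Thyroglobulin_1
    - cd00191     # TY
    - cl00150     # TY super family
homologous:
  C-type lectin:
    - cd00037     # CLECT
  fasciclin:
    - pfam02469   # fasciclin
  annexin:
    - pfam00191   # annexin
  CAP:
    - cd05380     # CAP domain
    - cl27660     # MAM super family
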