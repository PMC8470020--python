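# Functional marker-gene catalog for energy-metabolism profiling, and the
# gene groups interrogated by the reverse-methanogenesis (ANME) check.
# A marker is "present" when any alias appears in the annotation table,
# except markers with `require_all: true` (multi-subunit complexes that are
# only scored when the complete complement is annotated).
markers:
  mcrA:   {aliases: [mcrA, K00399]}
  pMMO:   {aliases: [pmoA, K10944]}
  dsrAB:  {aliases: [dsrA, dsrB, K11180, K11181]}
  napA:   {aliases: [napA, K02567]}
  narG:   {aliases: [narG, K00370]}
  nosZ:   {aliases: [nosZ, K00376]}
  soxB:   {aliases: [soxB, K17224]}
  soxYZ:  {aliases: [soxY, soxZ, K17226, K17227]}
  soeA:   {aliases: [soeA, K21307]}
  sqr:    {aliases: [sqr, K17218]}
  coxA:   {aliases: [coxA, K02274]}
  ccoN:   {aliases: [ccoN, K00404]}
  coxL:   {aliases: [coxL, coxM, coxS, K03520, K03519, K03518]}
  cooS:   {aliases: [cooS, K00198]}
  cooF:   {aliases: [cooF, K00196]}
  Fe-hyd: {aliases: [hydA, feFe_hyd, K00533]}
  hyaB:   {aliases: [hyaB, K06281]}
  hybC:   {aliases: [hybC, K05586]}
  GH1:    {aliases: [GH1, bglB, K01223, K05350]}
  bzd:    {aliases: [bzdN, bzdO, bzdP, bzdQ], require_all: true}
  PhzF:   {aliases: [phzF, K06998]}

methanogenesis:
  core_steps:
    fmd: [fmdA, fmdB, fmdC, K00200, K00201, K00202]
    ftr: [ftr, K00672]
    mch: [mch, K01499]
    mtd: [mtd, K00319]
    mer: [mer, K00320]
    mtr: [mtrA, mtrB, mtrC, mtrD, mtrE, mtrF, mtrG, mtrH, K00577, K00578, K00584]
    mcr: [mcrA, mcrB, mcrG, K00399, K00401, K00402]
  hydrogenases:
    Ech: [echA, echB, echC]
    Vho: [vhoA, vhoG]
    Mvh: [mvhA, mvhD, K14126]
    Frh: [frhA, frhB, K00440]
  methyltransferases:
    methanol: [mtaB, mtaC]
    monomethylamine: [mtmB]
    dimethylamine: [mtbB]
    trimethylamine: [mttB]
    methanol_dehydrogenase: [mxaF, K14028]
  nitrate_reduction:
    nar: [narG, K00370]
    nap: [napA, K02567]
    nrf: [nrfA, K03385]
    nir: [nirS, nirK, K15864, K00368]
    nor: [norB, K04561]
    nos: [nosZ, K00376]
  sulfate_reduction:
    dsrAB: [dsrA, dsrB, K11180, K11181]
    dsrC: [dsrC, K11179]
    qmoA: [qmoA]
    aprAB: [aprA, aprB, K00394, K00395]
    sat: [sat, K00958]
  electron_transfer:
    Fpo: [fpoA, fpoF, fpoL]
    HdrABC: [hdrA, hdrB, hdrC]
    HdrDE: [hdrD, hdrE]
    Rnf: [rnfA, rnfB, rnfC]
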