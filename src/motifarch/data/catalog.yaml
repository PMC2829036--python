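# Microdomain catalog: residue classes and one detection recipe per motif.
# Pattern notation: fixed residue, wildcard `x`, alternation `(X/Y)`,
# large-hydrophobic class symbol `Ψ`.  Positions are enforced by the
# annotator: n_terminal/c_terminal windows are residue counts from the
# respective end; `between` ties a motif to the gap separating two others.
classes:
  ACIDIC: DE
  NEUTRAL_POLAR: ST
  PSI: FILMVWY
  BULKY: WAFILMV
  BASIC: KR

motifs:
  SUMO:
    mode: pattern
    patterns:
      canonical: "ΨKxE"
  NLS:
    mode: pattern
    patterns:
      canonical: "K(K/R)x(K/R)"
  NLS_VARIANT:
    mode: pattern
    patterns:
      kxxr: "KxxR"
  DDW:
    mode: pattern
    patterns:
      canonical: "(D/E)(D/E)W"
  ABOX:
    mode: pattern
    position: {kind: c_terminal, window: 40}
    patterns:
      A1: "NGxSPSxxSSYDxxYSP"
      A2: "NGYSSP(M/L)SSGSYDPYSP"
      A3: "NGxPSPTMSSMSYDPYSP"
      A4: "NGYASPMS(T/S)GSYDPYSP"
      A5: "NGYASPMSAGSYDPYSPNG"
  SRICH:
    mode: hybrid
    composition: {classes: [ACIDIC, NEUTRAL_POLAR], window: 8, min_fraction: 0.6}
    cores:
      canonical: "EV(T/S)SS"
      qvsss: "QVSSS"
    consensi:
      B1-1: "GDExSxEVSSSS"
      B1-2: "GxESSPEVTSSS"
      B1-2p: "EDxxxQVSSS"
      B1-3: "EESSSEVTSSS"
      B1-4: "ESSPEVSSS"
      B1-5: "ESSPEVSSS"
      B1-6: "EESSSEVTSSS"
  SP:
    mode: pattern
    position: {kind: between, left: SRICH, right: DLRICH}
    patterns:
      canonical: "SP"
  DLRICH:
    mode: composition
    composition: {classes: [ACIDIC, BULKY], window: 10, min_fraction: 0.8, min_run: 8}
    fallback_patterns:
      modified: "(D/E)Y(C/G)(E/D)LWxxxxD"
    consensi:
      B1-1: "DIGEVDLDFWDLDL"
      B1-2: "DIGEVDLEFWDLDL"
      B1-2p: "EVDLELWDLGL"
      B1-3: "DIGDVDLEFWDLDL"
      B1-4: "EDLQLWDLDL"
      B1-5: "EDLQLWDLDL"
  KRRW:
    mode: pattern
    position: {kind: n_terminal, window: 10, anchor_after: PRVPVAGV, anchor_gap: 3}
    patterns:
      canonical: "(K/R)RRW"
  TXXPSIW:
    mode: pattern
    position: {kind: n_terminal, window: 10}
    patterns:
      canonical: "TxxΨW"
  DLKHE:
    mode: pattern
    position: {kind: n_terminal, window: 25}
    patterns:
      canonical: "DLKHE"
  PSIAYRG:
    mode: pattern
    position: {kind: n_terminal, window: 25}
    patterns:
      canonical: "ΨAYRG"
  DTS_REPEATS:
    mode: pattern
    position: {kind: n_terminal, window: 25}
    min_repeats: 2
    patterns:
      unit: "D(T/S)S"
  YRLN:
    mode: pattern
    position: {kind: n_terminal, window: 10}
    patterns:
      canonical: "YRLN"
  PRVPVAGV:
    mode: pattern
    position: {kind: n_terminal, window: 25}
    patterns:
      long: "LQTVPRVPVAGV"
      short: "LAVPRVPVAGV"
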