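# BRD4 region annotations (residue numbers, 1-based inclusive, isoform A numbering).
# Domain boundaries follow the standard BET-protein annotations; the
# hdx_protected intervals are the regions reported to lose deuterium uptake
# upon CK2 phosphorylation of the 1-722 construct.
domains:
  - {label: BD1,     start: 58,  end: 169}
  - {label: BD2,     start: 349, end: 461}
  - {label: NPS,     start: 484, end: 504}
  - {label: motif_B, start: 506, end: 530}
  - {label: BID,     start: 531, end: 579}
  - {label: ET,      start: 600, end: 678}
  - {label: CPS,     start: 695, end: 720}
  - {label: PDD,     start: 484, end: 579}
hdx_protected:
  - {label: BD1_helixZ,   start: 65,  end: 71}
  - {label: BD1_linker,   start: 184, end: 190}
  - {label: BD2_ZA,       start: 362, end: 386}
  - {label: coiled_coil,  start: 506, end: 527}
  - {label: ET_a,         start: 621, end: 644}
  - {label: ET_b,         start: 657, end: 675}
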