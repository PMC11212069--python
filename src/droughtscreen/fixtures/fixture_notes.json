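{
  "table1": {
    "transcription_notes": [
      "CIAT16514 NT under WD is printed as the run-together token '6.20.37'; stored as mean 6.2, SEM 0.37 (spacing-loss typo; keeps NT plausible).",
      "K12 PH under WD SEM is printed as 9.20 (implausibly large for a mean of 7.7); stored as printed.",
      "K18 NL under WD SEM printed as '025'; stored as 0.25."
    ]
  },
  "table2": {
    "transcription_notes": [
      "K4 RWC under WD printed as '16.61 \u00b1 61'; stored as SEM 0.61.",
      "K17 FvFm under WS SEM printed as '004'; stored as 0.04.",
      "K12 PhiNPQ under WD SEM printed as 0.30; stored as printed."
    ]
  },
  "cluster_sizes": {
    "notes": [
      "The source text reports cluster III as 37.1% of ecotypes while listing 8 of 35 members (22.9%), and cluster II (10+9=19) as 54.3%. Sizes are stored as listed; percentages computed from sizes will not reproduce the 37.1% figure."
    ]
  }
}
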