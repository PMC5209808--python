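{
  "table2_model.json": "0019f76d6bcea47fb8993deff3c7e350008da7674736cd07838387e3451c49a4",
  "table3_model.json": "fd30b5a0823eee11587b76e9c6b12961195f93b855c8faedb45a2de3ba58588a",
  "table4_overall.csv": "ac1389a4340d829796cea0a6794efb91c4c4835425645b50584d63cde8f61f76",
  "table5_by_category.csv": "db447cdb21015e807a6adff13f2950d412669d10d12129b44dcbc4ca5dda37f2",
  "table6_gaps.csv": "9214b8d70d1e4092e91d0f3e8e2798e02dcfc6c09b1b7912db595aa989b5c5a5"
}
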