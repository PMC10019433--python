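locale: en
negation:
  - {phrase: "no", position: pre}
  - {phrase: "not", position: pre}
  - {phrase: "without", position: pre}
  - {phrase: "free of", position: pre}
  - {phrase: "no evidence of", position: pre}
  - {phrase: "negative for", position: pre}
  - {phrase: "absent", position: post}
  - {phrase: "is excluded", position: post}
  - {phrase: "ruled out", position: post}
speculation:
  - {phrase: "suspected", position: pre}
  - {phrase: "possible", position: pre}
  - {phrase: "questionable", position: pre}
  - {phrase: "suspicion of", position: pre}
  - {phrase: "probable", position: pre}
  - {phrase: "cannot be excluded", position: post}
  - {phrase: "is suspected", position: post}
  - {phrase: "possibly", position: pre}
pseudo:
  - "no change"
  - "no comparison"
  - "not otherwise specified"
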