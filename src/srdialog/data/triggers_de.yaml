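locale: de
negation:
  - {phrase: "kein", position: pre}
  - {phrase: "keine", position: pre}
  - {phrase: "keinem", position: pre}
  - {phrase: "keiner", position: pre}
  - {phrase: "ohne", position: pre}
  - {phrase: "nicht", position: pre}
  - {phrase: "ausgeschlossen", position: post}
speculation:
  - {phrase: "verdacht auf", position: pre}
  - {phrase: "fraglich", position: pre}
  - {phrase: "fragliche", position: pre}
  - {phrase: "möglicherweise", position: pre}
  - {phrase: "nicht auszuschließen", position: post}
  - {phrase: "nicht sicher auszuschließen", position: post}
pseudo:
  - "keine änderung"
  - "kein vergleich"
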