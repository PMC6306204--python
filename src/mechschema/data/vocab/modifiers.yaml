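# The closed modifier vocabulary, in its documented fixed order.
# An SSP may also carry no modifier at all (the absent case).
modifiers:
  - increased
  - decreased
  - "no"
  - altered
  - sooner
  - later
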